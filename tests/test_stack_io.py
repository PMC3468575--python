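"""Pose-stack reading, merging, deduplication and RMSD."""

import numpy as np
import pytest

from gapscreen import (ContractError, FormatError, Pose, build_stack,
                       deduplicate, heavy_atom_rmsd, merge_runs,
                       read_stack_csv, read_stack_sdf, write_stacks_csv,
                       write_stacks_sdf)

from conftest import random_stack


def _pose(pid, score, xyz):
    return Pose(pid, score, coords=np.asarray(xyz, dtype=float))


# ---------------------------------------------------------------------------
# heavy_atom_rmsd
# ---------------------------------------------------------------------------

class TestHeavyAtomRMSD:
    def test_identity_is_zero(self):
        a = _pose("a", -1.0, [[0, 0, 0], [1, 1, 1]])
        assert heavy_atom_rmsd(a, a) == 0.0

    def test_single_atom_closed_form(self):
        a = _pose("a", -1.0, [[0.0, 0.0, 0.0]])
        b = _pose("b", -1.0, [[3.0, 4.0, 0.0]])
        assert heavy_atom_rmsd(a, b) == pytest.approx(5.0)

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=(10, 3))
        y = rng.normal(size=(10, 3))
        expected = np.sqrt(sum((xi - yi) @ (xi - yi) for xi, yi in zip(x, y)) / 10)
        got = heavy_atom_rmsd(_pose("a", 0.0, x), _pose("b", 0.0, y))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(50):
            a, b, c = (_pose(k, 0.0, rng.normal(size=(7, 3))) for k in "abc")
            ab, ba = heavy_atom_rmsd(a, b), heavy_atom_rmsd(b, a)
            assert ab == ba
            assert ab <= heavy_atom_rmsd(a, c) + heavy_atom_rmsd(c, b) + 1e-12

    def test_atom_count_mismatch(self):
        a = _pose("a", 0.0, [[0, 0, 0]])
        b = _pose("b", 0.0, [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ContractError):
            heavy_atom_rmsd(a, b)


# ---------------------------------------------------------------------------
# deduplicate
# ---------------------------------------------------------------------------

class TestDeduplicate:
    def test_close_pair_keeps_lower_score(self):
        a = _pose("hi", -4.0, [[0, 0, 0]])
        b = _pose("lo", -9.0, [[0.1, 0, 0]])
        kept = deduplicate([a, b], tol=0.5)
        assert [p.pose_id for p in kept] == ["lo"]

    def test_distant_pair_both_kept(self):
        a = _pose("a", -4.0, [[0, 0, 0]])
        b = _pose("b", -9.0, [[3.0, 0, 0]])
        assert len(deduplicate([a, b], tol=0.5)) == 2

    def test_n_duplicates_one_survivor(self, rng):
        xyz = rng.normal(size=(6, 3))
        poses = [_pose(f"d{i}", -10.0 + i, xyz) for i in range(8)]
        kept = deduplicate(poses, tol=0.5)
        assert len(kept) == 1 and kept[0].pose_id == "d0"

    def test_matches_brute_force_clustering(self, rng):
        """Greedy dedup equals exhaustive pairwise clustering when clusters
        are compact (< tol/2 spread) and well separated (> 2 tol)."""
        tol = 0.5
        for _ in range(20):
            n_clusters = int(rng.integers(2, 6))
            centers = rng.normal(scale=50.0, size=(n_clusters, 1, 3))
            poses = []
            assignment = []
            for ci in range(n_clusters):
                for _ in range(int(rng.integers(1, 6))):
                    jitter = rng.normal(scale=tol / 20, size=(4, 3))
                    poses.append(_pose(f"p{len(poses):03d}",
                                       float(rng.normal(-10, 3)),
                                       centers[ci] + np.zeros((4, 3)) + jitter))
                    assignment.append(ci)
            # oracle: connected components of the rmsd <= tol graph,
            # represented by their (score, pose_id)-lowest member
            n = len(poses)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    if heavy_atom_rmsd(poses[i], poses[j]) <= tol:
                        parent[find(i)] = find(j)
            reps = {}
            for i, p in enumerate(poses):
                key = find(i)
                if key not in reps or (p.score, p.pose_id) < reps[key]:
                    reps[key] = (p.score, p.pose_id)
            expected = sorted(reps.values())
            got = sorted((p.score, p.pose_id) for p in deduplicate(poses, tol))
            assert got == expected

    def test_idempotent(self, rng):
        poses = [_pose(f"p{i}", float(rng.normal()), rng.normal(size=(3, 3)))
                 for i in range(20)]
        once = deduplicate(poses, tol=1.0)
        assert deduplicate(once, tol=1.0) == once

    def test_score_only_fallback_keys_on_exact_score(self):
        poses = [Pose("a", -5.0), Pose("b", -5.0), Pose("c", -4.0)]
        kept = deduplicate(poses, tol=0.5)
        assert [p.pose_id for p in kept] == ["a", "c"]

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            deduplicate([Pose("a", -5.0)], tol=0.0)


# ---------------------------------------------------------------------------
# merge_runs
# ---------------------------------------------------------------------------

class TestMergeRuns:
    def test_three_runs_of_200(self, rng):
        runs = []
        for r in range(3):
            poses = [Pose(f"r{r}p{i:03d}", float(rng.normal(-15, 3)), run_id=r)
                     for i in range(200)]
            runs.append(build_stack("lig", "rec", poses))
        merged = merge_runs(runs)
        assert 1 <= len(merged) <= 600
        assert list(merged.scores) == sorted(merged.scores)

    def test_merge_with_self_is_dedup(self, rng):
        s = random_stack(rng)
        merged = merge_runs([s, s])
        assert merged.poses == s.poses

    def test_disjoint_runs_sum(self):
        a = build_stack("l", "r", [_pose("a1", -9.0, [[0, 0, 0]]),
                                   _pose("a2", -8.0, [[5, 0, 0]])])
        b = build_stack("l", "r", [_pose("b1", -7.0, [[10, 0, 0]]),
                                   _pose("b2", -6.0, [[15, 0, 0]])])
        assert len(merge_runs([a, b])) == 4

    def test_size_bounds(self, rng):
        a, b = random_stack(rng, 30), random_stack(rng, 20)
        m = merge_runs([a, b])
        assert max(len(a), len(b)) <= len(m) <= len(a) + len(b)

    def test_mixed_ids_rejected(self, rng):
        a = random_stack(rng, 5, ligand="L1")
        b = random_stack(rng, 5, ligand="L2")
        with pytest.raises(ContractError):
            merge_runs([a, b])


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

class TestCSV:
    def test_grouping(self, tmp_path):
        p = tmp_path / "poses.csv"
        p.write_text("ligand_id,receptor_id,score\n"
                     "L1,R1,-10\nL1,R1,-4\nL2,R1,-8\nL2,R1,-2\n")
        stacks = read_stack_csv(p)
        assert [(s.ligand_id, len(s)) for s in stacks] == [("L1", 2), ("L2", 2)]
        assert stacks[0].e_min == -10.0

    def test_schema_remap(self, tmp_path):
        p = tmp_path / "poses.csv"
        p.write_text("ligand_id,receptor_id,energy\nL1,R1,-10\nL1,R1,-4\n")
        stacks = read_stack_csv(p, schema={"score": "energy"})
        assert stacks[0].scores.tolist() == [-10.0, -4.0]

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "poses.csv"
        p.write_text("ligand_id,score\nL1,-10\n")
        with pytest.raises(FormatError, match="receptor_id"):
            read_stack_csv(p)

    def test_non_numeric_score_cites_row(self, tmp_path):
        p = tmp_path / "poses.csv"
        p.write_text("ligand_id,receptor_id,score\nL1,R1,-10\nL1,R1,NA\n")
        with pytest.raises(FormatError, match="row 2"):
            read_stack_csv(p)

    def test_tsv_extension(self, tmp_path):
        p = tmp_path / "poses.tsv"
        p.write_text("ligand_id\treceptor_id\tscore\nL1\tR1\t-10\nL1\tR1\t-4\n")
        assert len(read_stack_csv(p)[0]) == 2

    def test_write_read_roundtrip_byte_identical(self, tmp_path, rng):
        stacks = [random_stack(rng, ligand=f"L{i}") for i in range(3)]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_stacks_csv(stacks, p1)
        back = read_stack_csv(p1)
        assert back == stacks
        write_stacks_csv(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_dropped_rows_skipped_on_read(self, tmp_path):
        stack = build_stack("L", "R", [
            _pose("keep", -9.0, [[0, 0, 0]]), _pose("drop", -4.0, [[0.1, 0, 0]])])
        p = tmp_path / "audit.csv"
        write_stacks_csv([stack], p, include_dropped=True)
        text = p.read_text()
        assert "drop" in text and "False" in text
        assert [q.pose_id for q in read_stack_csv(p)[0].poses] == ["keep"]


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

def _write_sdf_records(path, records, score_tag="Score"):
    """records: list of (props: dict, atoms: list of (symbol, xyz))."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    for props, atoms in records:
        mol = Chem.RWMol()
        for sym, _ in atoms:
            mol.AddAtom(Chem.Atom(sym))
        conf = Chem.Conformer(len(atoms))
        for i, (_, xyz) in enumerate(atoms):
            conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
        mol.AddConformer(conf)
        for k, v in props.items():
            mol.SetProp(k, str(v))
        writer.write(mol)
    writer.close()


class TestSDF:
    def test_single_ligand_sorted(self, tmp_path):
        p = tmp_path / "poses.sdf"
        base = {"LigandID": "L1", "ReceptorID": "R1"}
        _write_sdf_records(p, [
            ({**base, "Score": -4}, [("C", (0, 0, 0)), ("N", (9, 0, 0))]),
            ({**base, "Score": -10}, [("C", (1, 1, 1)), ("N", (8, 0, 0))]),
            ({**base, "Score": -2}, [("C", (2, 2, 2)), ("N", (7, 0, 0))]),
        ])
        stacks = read_stack_sdf(p)
        assert len(stacks) == 1
        assert stacks[0].scores.tolist() == [-10.0, -4.0, -2.0]
        assert stacks[0].poses[0].coords.shape == (2, 3)

    def test_hydrogens_dropped(self, tmp_path):
        p = tmp_path / "poses.sdf"
        base = {"LigandID": "L1", "ReceptorID": "R1"}
        _write_sdf_records(p, [
            ({**base, "Score": -4}, [("C", (0, 0, 0)), ("H", (1, 0, 0))]),
            ({**base, "Score": -10}, [("C", (5, 0, 0))]),
        ])
        stacks = read_stack_sdf(p)
        assert len(stacks[0]) == 2
        assert all(q.coords.shape == (1, 3) for q in stacks[0].poses)

    def test_missing_score_tag_names_record(self, tmp_path):
        p = tmp_path / "poses.sdf"
        _write_sdf_records(p, [
            ({"LigandID": "L1", "ReceptorID": "R1", "Score": -4},
             [("C", (0, 0, 0))]),
            ({"LigandID": "L1", "ReceptorID": "R1"}, [("C", (1, 0, 0))]),
        ])
        with pytest.raises(FormatError, match="record 1"):
            read_stack_sdf(p)

    def test_inconsistent_heavy_atom_count(self, tmp_path):
        p = tmp_path / "poses.sdf"
        base = {"LigandID": "L1", "ReceptorID": "R1", "Score": -4}
        _write_sdf_records(p, [
            (base, [("C", (0, 0, 0))]),
            (base, [("C", (9, 0, 0)), ("C", (8, 0, 0))]),
        ])
        with pytest.raises(FormatError, match="heavy-atom count"):
            read_stack_sdf(p)

    def test_write_read_roundtrip(self, tmp_path, rng):
        poses = [Pose(f"p{i:02d}", float(rng.normal(-10, 3)),
                      coords=rng.normal(scale=20, size=(4, 3)),
                      rmsd_to_ref=float(rng.uniform(0, 5)), run_id=i % 2)
                 for i in range(10)]
        stack = build_stack("L1", "R1", poses)
        p = tmp_path / "poses.sdf"
        write_stacks_sdf([stack], p)
        back = read_stack_sdf(p)[0]
        assert back.scores.tolist() == stack.scores.tolist()
        assert [q.pose_id for q in back.poses] == [q.pose_id for q in stack.poses]
        for mine, theirs in zip(stack.poses, back.poses):
            assert np.allclose(mine.coords, theirs.coords, atol=1e-3)
            assert theirs.rmsd_to_ref == mine.rmsd_to_ref
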