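"""Reading, merging, deduplicating and serializing docking pose stacks.

A *pose stack* is the sample of the binding energy landscape produced by
docking one ligand into one receptor conformation: every scored pose from
every run, merged, reduced to geometrically unique solutions and sorted from
the best (lowest) score upward.  All downstream descriptors (energy gap,
native-phase statistics) are arithmetic over this object, so the invariants
enforced here — stable score order, no geometric duplicates, lowest-score
representative per geometric cluster — are what make those descriptors
well defined.

Scores are docking energies in kcal/mol, lower is better.  RMSDs are
heavy-atom RMSDs in Å computed in the common receptor frame *without*
superposition, the standard convention for docked poses that share one
receptor grid.  Hydrogens never enter any geometric computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError

#: Default heavy-atom RMSD (Å) below which two poses count as the same solution.
DEFAULT_DEDUP_TOLERANCE = 0.5

_CSV_COLUMNS = ["ligand_id", "receptor_id", "run", "pose_id", "score",
                "rmsd_to_ref", "dedup_kept"]


@dataclass(eq=True)
class Pose:
    """One scored docking solution.

    Parameters
    ----------
    pose_id:
        Identifier, unique within its stack; used for deterministic tie-breaks.
    score:
        Docking score in kcal/mol (lower = better binding). Must be finite.
    coords:
        Optional ``(n_atoms, 3)`` array of heavy-atom positions in Å. All
        poses of one ligand share a single atom ordering.
    rmsd_to_ref:
        Optional heavy-atom RMSD (Å, no superposition) to a reference pose,
        typically the crystallographic geometry.
    run_id:
        Optional index of the docking run that produced the pose.
    """

    pose_id: str
    score: float
    coords: np.ndarray | None = None
    rmsd_to_ref: float | None = None
    run_id: int | None = None

    def __post_init__(self) -> None:
        self.score = float(self.score)
        if not math.isfinite(self.score):
            raise ContractError(f"pose {self.pose_id!r}: score must be finite")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) < 1:
                raise ContractError(
                    f"pose {self.pose_id!r}: coords must be a non-empty (n, 3) array")
        if self.rmsd_to_ref is not None:
            self.rmsd_to_ref = float(self.rmsd_to_ref)
            if self.rmsd_to_ref < 0:
                raise ContractError(f"pose {self.pose_id!r}: rmsd_to_ref must be >= 0")

    def __eq__(self, other: object) -> bool:  # coords need array-aware equality
        if not isinstance(other, Pose):
            return NotImplemented
        if (self.coords is None) != (other.coords is None):
            return False
        coords_equal = (self.coords is None
                        or np.array_equal(self.coords, other.coords))
        return (self.pose_id == other.pose_id
                and self.score == other.score
                and self.rmsd_to_ref == other.rmsd_to_ref
                and self.run_id == other.run_id
                and coords_equal)


@dataclass
class PoseStack:
    """Deduplicated, score-sorted landscape sample for one (ligand, receptor) pair.

    ``poses`` are sorted ascending by ``(score, pose_id)``; no two poses lie
    within ``dedup_tolerance`` Å heavy-atom RMSD of each other.  ``dropped``
    retains the poses removed by deduplication (for audit serialization only;
    it never participates in equality or any descriptor).
    """

    ligand_id: str
    receptor_id: str
    poses: list[Pose]
    dedup_tolerance: float = DEFAULT_DEDUP_TOLERANCE
    dropped: list[Pose] = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.poses) < 1:
            raise ContractError("a pose stack must contain at least one pose")

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def scores(self) -> np.ndarray:
        """Scores in stack (ascending) order, kcal/mol."""
        return np.array([p.score for p in self.poses], dtype=float)

    @property
    def e_min(self) -> float:
        """Best (lowest) docking score in the stack, kcal/mol."""
        return self.poses[0].score

    @property
    def has_coords(self) -> bool:
        return all(p.coords is not None for p in self.poses)

    @property
    def has_rmsd(self) -> bool:
        return all(p.rmsd_to_ref is not None for p in self.poses)


def heavy_atom_rmsd(a: Pose, b: Pose) -> float:
    """Heavy-atom RMSD between two poses in the shared receptor frame (Å).

    No superposition is applied: docked poses of one ligand already live in
    the common frame of the receptor, so rigid-body alignment would hide
    genuine displacement between binding modes.
    """
    if a.coords is None or b.coords is None:
        raise ContractError("heavy_atom_rmsd requires coordinates on both poses")
    if a.coords.shape != b.coords.shape:
        raise ContractError(
            f"atom-count mismatch: {a.coords.shape[0]} vs {b.coords.shape[0]}")
    diff = a.coords - b.coords
    return float(np.sqrt((diff * diff).sum(axis=1).mean()))


def _sort_key(p: Pose) -> tuple[float, str]:
    return (p.score, p.pose_id)


def deduplicate(poses: Sequence[Pose], tol: float = DEFAULT_DEDUP_TOLERANCE,
                ) -> list[Pose]:
    """Reduce a pose list to geometrically unique solutions.

    Greedy pass in ascending ``(score, pose_id)`` order: a pose is kept iff
    its heavy-atom RMSD to every already-kept pose exceeds ``tol``, so each
    geometric cluster is represented by its lowest-score member and the
    stack minimum is preserved exactly.  Idempotent.

    When poses carry no coordinates the geometric criterion degenerates to
    exact score equality (documented fallback for score-table-only
    workflows): of several poses with identical scores only the first by
    ``pose_id`` survives.
    """
    kept, _ = _deduplicate_split(poses, tol)
    return kept


def _deduplicate_split(poses: Sequence[Pose], tol: float,
                       ) -> tuple[list[Pose], list[Pose]]:
    if tol <= 0:
        raise ValueError(f"dedup tolerance must be > 0, got {tol}")
    ordered = sorted(poses, key=_sort_key)
    if not ordered:
        return [], []
    geometric = all(p.coords is not None for p in ordered)
    kept: list[Pose] = []
    dropped: list[Pose] = []
    if geometric:
        n_atoms = {p.coords.shape[0] for p in ordered}
        if len(n_atoms) > 1:
            raise ContractError(
                f"inconsistent heavy-atom counts within one ligand: {sorted(n_atoms)}")
        kept_coords: list[np.ndarray] = []
        for p in ordered:
            if kept_coords:
                stack = np.stack(kept_coords)          # (k, A, 3)
                d = p.coords[None] - stack
                rmsds = np.sqrt((d * d).sum(axis=2).mean(axis=1))
                if rmsds.min() <= tol:
                    dropped.append(p)
                    continue
            kept.append(p)
            kept_coords.append(p.coords)
    else:
        seen: set[float] = set()
        for p in ordered:
            if p.score in seen:
                dropped.append(p)
            else:
                seen.add(p.score)
                kept.append(p)
    return kept, dropped


def build_stack(ligand_id: str, receptor_id: str, poses: Iterable[Pose],
                dedup_tolerance: float = DEFAULT_DEDUP_TOLERANCE) -> PoseStack:
    """Sort, deduplicate and wrap raw poses into a :class:`PoseStack`."""
    kept, dropped = _deduplicate_split(list(poses), dedup_tolerance)
    if not kept:
        raise ContractError(
            f"stack ({ligand_id}, {receptor_id}) has no poses after deduplication")
    return PoseStack(ligand_id=ligand_id, receptor_id=receptor_id, poses=kept,
                     dedup_tolerance=dedup_tolerance, dropped=dropped)


def merge_runs(stacks: Sequence[PoseStack]) -> PoseStack:
    """Merge multiple runs' stacks for one (ligand, receptor) pair.

    The union of poses is deduplicated and re-sorted, so repeated solutions
    found by independent runs collapse to their lowest-score representative.
    """
    if not stacks:
        raise ContractError("merge_runs requires at least one stack")
    ids = {(s.ligand_id, s.receptor_id) for s in stacks}
    if len(ids) > 1:
        raise ContractError(f"cannot merge stacks with mixed identities: {sorted(ids)}")
    tol = stacks[0].dedup_tolerance
    pooled = [p for s in stacks for p in s.poses]
    return build_stack(stacks[0].ligand_id, stacks[0].receptor_id, pooled, tol)


# ---------------------------------------------------------------------------
# CSV / TSV
# ---------------------------------------------------------------------------

def read_stack_csv(path: str | Path,
                   schema: Mapping[str, str] | None = None,
                   dedup_tolerance: float = DEFAULT_DEDUP_TOLERANCE,
                   ) -> list[PoseStack]:
    """Read pose stacks from a CSV/TSV table.

    Required columns (after applying ``schema``, a mapping from canonical
    name to the file's column name, e.g. ``{"score": "energy"}``):
    ``ligand_id``, ``receptor_id``, ``score``.  Optional: ``run``,
    ``pose_id``, ``rmsd_to_ref``, and a ``dedup_kept`` audit flag (rows
    flagged false are skipped on input).  One stack is built per
    (ligand, receptor) group via merge + dedup; groups are returned sorted
    by (ligand_id, receptor_id).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items()}
    df = df.rename(columns=rename)
    for col in ("ligand_id", "receptor_id", "score"):
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path.name}")
    if "dedup_kept" in df.columns:
        df = df[df["dedup_kept"].str.lower() != "false"]
    def _parse_score(item: tuple[int, str]) -> float:
        row, text = item
        try:
            value = float(text)
        except ValueError:
            raise FormatError(
                f"non-numeric score {text!r} at data row {row + 1} "
                f"of {path.name}") from None
        if not math.isfinite(value):
            raise FormatError(
                f"non-finite score {text!r} at data row {row + 1} of {path.name}")
        return value

    # builtin float() round-trips repr() exactly; pandas' fast parser does not
    df = df.assign(score=[_parse_score(kv) for kv in df["score"].items()])

    stacks: list[PoseStack] = []
    for (lig, rec), grp in sorted(df.groupby(["ligand_id", "receptor_id"], sort=True),
                                  key=lambda kv: kv[0]):
        poses = []
        for i, (_, row) in enumerate(grp.iterrows()):
            run = row.get("run", "")
            rmsd = row.get("rmsd_to_ref", "")
            pose_id = row.get("pose_id", "") or f"{lig}:{rec}:{i:04d}"
            poses.append(Pose(
                pose_id=pose_id,
                score=float(row["score"]),
                rmsd_to_ref=float(rmsd) if rmsd not in ("", None) else None,
                run_id=int(run) if run not in ("", None) else None,
            ))
        stacks.append(build_stack(lig, rec, poses, dedup_tolerance))
    return stacks


def write_stacks_csv(stacks: Sequence[PoseStack], path: str | Path,
                     include_dropped: bool = False) -> None:
    """Serialize stacks to CSV with a kept/dropped dedup audit flag.

    Floats are written with Python's shortest round-trip representation, so
    read → write → read is exact.
    """
    rows = []
    for s in stacks:
        pool = [(p, True) for p in s.poses]
        if include_dropped:
            pool += [(p, False) for p in s.dropped]
        for p, keep in pool:
            rows.append({
                "ligand_id": s.ligand_id,
                "receptor_id": s.receptor_id,
                "run": "" if p.run_id is None else p.run_id,
                "pose_id": p.pose_id,
                "score": repr(p.score),
                "rmsd_to_ref": "" if p.rmsd_to_ref is None else repr(p.rmsd_to_ref),
                "dedup_kept": keep,
            })
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

def read_stack_sdf(path: str | Path,
                   score_tag: str = "Score",
                   ligand_tag: str = "LigandID",
                   receptor_tag: str = "ReceptorID",
                   dedup_tolerance: float = DEFAULT_DEDUP_TOLERANCE,
                   ) -> list[PoseStack]:
    """Read pose stacks from an SDF file.

    Each record must carry the docking score in the ``score_tag`` property
    and ligand/receptor identification tags. Heavy-atom coordinates are taken
    from the structure block (hydrogens dropped, so records whose protonation
    differs but whose heavy atoms match are accepted). Optional tags:
    ``PoseID``, ``RunID``, ``RMSDToRef``.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    grouped: dict[tuple[str, str], list[Pose]] = {}
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise FormatError(f"unparseable SDF record at index {idx}")
        props = mol.GetPropsAsDict()
        if score_tag not in props:
            raise FormatError(f"SDF record {idx} lacks score tag {score_tag!r}")
        for tag in (ligand_tag, receptor_tag):
            if tag not in props:
                raise FormatError(f"SDF record {idx} lacks identification tag {tag!r}")
        try:
            score = float(props[score_tag])
        except (TypeError, ValueError):
            raise FormatError(
                f"SDF record {idx}: score tag {score_tag!r} is not numeric "
                f"({props[score_tag]!r})") from None
        conf = mol.GetConformer()
        heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
        if not heavy:
            raise FormatError(f"SDF record {idx} has no heavy atoms")
        coords = np.array([list(conf.GetAtomPosition(i)) for i in heavy], dtype=float)
        lig, rec = str(props[ligand_tag]), str(props[receptor_tag])
        rmsd = props.get("RMSDToRef")
        run = props.get("RunID")
        pose_id = str(props.get("PoseID", f"{lig}:{rec}:{idx:04d}"))
        existing = grouped.setdefault((lig, rec), [])
        if existing and existing[0].coords.shape[0] != coords.shape[0]:
            raise FormatError(
                f"SDF record {idx}: heavy-atom count {coords.shape[0]} differs from "
                f"{existing[0].coords.shape[0]} seen earlier for ligand {lig!r}")
        existing.append(Pose(pose_id=pose_id, score=score, coords=coords,
                             rmsd_to_ref=None if rmsd is None else float(rmsd),
                             run_id=None if run is None else int(run)))
    return [build_stack(lig, rec, poses, dedup_tolerance)
            for (lig, rec), poses in sorted(grouped.items())]


def write_stacks_sdf(stacks: Sequence[PoseStack], path: str | Path,
                     score_tag: str = "Score",
                     ligand_tag: str = "LigandID",
                     receptor_tag: str = "ReceptorID") -> None:
    """Serialize stacks with coordinates to an SDF file.

    Atoms are written as carbons without bonds (pose geometry is all the
    downstream analyses consume); scores and identifiers travel in property
    tags at full precision.
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    try:
        for s in stacks:
            for p in s.poses:
                if p.coords is None:
                    raise ContractError(
                        f"pose {p.pose_id!r} has no coordinates; SDF output needs them")
                mol = Chem.RWMol()
                for _ in range(p.coords.shape[0]):
                    mol.AddAtom(Chem.Atom(6))
                conf = Chem.Conformer(p.coords.shape[0])
                for i, (x, y, z) in enumerate(p.coords):
                    conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
                mol.AddConformer(conf)
                mol.SetProp("_Name", p.pose_id)
                mol.SetProp(score_tag, repr(p.score))
                mol.SetProp(ligand_tag, s.ligand_id)
                mol.SetProp(receptor_tag, s.receptor_id)
                mol.SetProp("PoseID", p.pose_id)
                if p.run_id is not None:
                    mol.SetProp("RunID", str(p.run_id))
                if p.rmsd_to_ref is not None:
                    mol.SetProp("RMSDToRef", repr(p.rmsd_to_ref))
                writer.write(mol)
    finally:
        writer.close()
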