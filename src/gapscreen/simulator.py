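"""Synthetic binding-landscape simulator with planted ground truth.

Generates pose stacks that mimic what a docking engine produces: several
independent runs of a few hundred scored poses each (default 3 × 200),
merged and deduplicated.  Two landscape kinds are modeled:

* ``funnel`` (specific binder): a Gaussian background band of non-native
  solutions plus a compact native well — extra poses drawn ``funnel_depth``
  kcal/mol below the background with a quarter of its spread.
* ``rugged`` (decoy): the background band alone; the apparent gap of such a
  stack is just the extreme-value offset of the band minimum.

Each pose receives an RMSD to the (virtual) crystallographic reference via
a linear energy–RMSD coupling with noise, so low-energy poses lie near the
reference geometry; funnel poses are near native (< 2 Å) with a configured
probability and the generator records exactly which poses ended up near
native, so phase/success statistics can be checked against construction.

Real docking scores also carry systematic per-ligand biases (ligand size is
the classic one: bigger ligands score better regardless of affinity).  The
benchmark generator therefore adds a per-ligand score offset
``~ N(0, ligand_bias_std)`` to every pose of that ligand's stacks.  The
offset cancels exactly in the energy gap (a difference of means over one
stack) but corrupts the raw best score — the mechanism by which gap ranking
beats best-score ranking in screening.

Everything is reproducible under an integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ContractError
from .native_phase import NEAR_NATIVE_THRESHOLD
from .stack_io import DEFAULT_DEDUP_TOLERANCE, Pose, PoseStack, build_stack
from .vs_eval import ScreeningSet

#: Fixed 5-atom heavy-atom template used when synthesizing coordinates.
#: Poses are rigid translations of this template, so the no-superposition
#: heavy-atom RMSD between any pose and the reference equals the planted
#: displacement length exactly.
_TEMPLATE = np.array([
    [0.0, 0.0, 0.0],
    [1.5, 0.0, 0.0],
    [0.0, 1.5, 0.0],
    [0.0, 0.0, 1.5],
    [1.5, 1.5, 0.0],
])

#: Spread of the per-receptor additive score offset in benchmarks (kcal/mol).
RECEPTOR_OFFSET_STD = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Generation parameters for one landscape kind.

    Defaults reproduce the study conditions the package is tested under:
    3 runs × 200 poses, a background band at −15 ± 3 kcal/mol, a native
    well 10 kcal/mol deep sampled by 20 poses, linear energy–RMSD coupling
    of 0.3 Å per kcal/mol with 0.5 Å noise, and a 2 kcal/mol per-ligand
    systematic score bias.
    """

    n_runs: int = 3
    poses_per_run: int = 200
    background_mean: float = -15.0      # kcal/mol
    background_std: float = 3.0         # kcal/mol
    funnel_depth: float = 10.0          # kcal/mol below background; 0 = decoy
    n_funnel_poses: int = 20
    rmsd_at_minimum: float = 1.0        # Å
    rmsd_slope: float = 0.3             # Å per kcal/mol above the minimum
    rmsd_noise_std: float = 0.5         # Å
    rmsd_max: float = 12.0              # Å
    near_native_fraction: float = 0.8   # P(funnel pose < 2 Å from reference)
    ligand_bias_std: float = 2.0        # kcal/mol, per-ligand systematic offset
    dedup_tolerance: float = DEFAULT_DEDUP_TOLERANCE
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.poses_per_run < 1 or self.n_funnel_poses < 1:
            raise ValueError("counts must be >= 1")
        for name in ("background_std", "rmsd_noise_std", "ligand_bias_std"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.funnel_depth < 0:
            raise ValueError("funnel_depth must be >= 0")
        if not 0.0 <= self.near_native_fraction <= 1.0:
            raise ValueError("near_native_fraction must lie in [0, 1]")
        if self.rmsd_max <= 0 or self.rmsd_at_minimum < 0:
            raise ValueError("rmsd_max must be > 0 and rmsd_at_minimum >= 0")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SimConfig":
        """Build a config from string key=value pairs (CLI config files)."""
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, value in mapping.items():
            if key not in types:
                raise ValueError(f"unknown simulator parameter {key!r}")
            if key in ("n_runs", "poses_per_run", "n_funnel_poses", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Parse a key=value config file (one pair per line, # comments)."""
        mapping = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            mapping[key.strip()] = value.strip()
        return cls.from_mapping(mapping)


@dataclass(frozen=True)
class StackTruth:
    """Planted ground truth for one generated stack (post-deduplication)."""

    ligand_id: str
    receptor_id: str
    kind: str
    seed: int | None
    score_offset: float
    funnel_pose_ids: frozenset[str]
    near_native_pose_ids: frozenset[str]
    has_near_native: bool
    reference: Pose | None = None


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_stack(config: SimConfig, kind: str, seed: int | None = None,
                   ligand_id: str = "LIG", receptor_id: str = "REC",
                   with_coords: bool = False, score_offset: float = 0.0,
                   ) -> tuple[PoseStack, StackTruth]:
    """Generate one pose stack of the requested landscape kind.

    ``score_offset`` is an additive shift applied to every score (used by
    :func:`simulate_benchmark` for ligand-bias and receptor-ensemble
    offsets).  With ``with_coords=True`` each pose additionally carries
    synthesized heavy-atom coordinates whose RMSD to the returned reference
    pose equals the planted ``rmsd_to_ref`` exactly.
    """
    if kind not in ("funnel", "rugged"):
        raise ValueError(f"kind must be 'funnel' or 'rugged', got {kind!r}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    scores: list[float] = []
    runs: list[int] = []
    is_funnel: list[bool] = []
    for run in range(config.n_runs):
        bg = rng.normal(config.background_mean, config.background_std,
                        config.poses_per_run)
        scores.extend(bg)
        runs.extend([run] * config.poses_per_run)
        is_funnel.extend([False] * config.poses_per_run)
    if kind == "funnel":
        well = rng.normal(config.background_mean - config.funnel_depth,
                          config.background_std / 4.0, config.n_funnel_poses)
        scores.extend(well)
        runs.extend([i % config.n_runs for i in range(config.n_funnel_poses)])
        is_funnel.extend([True] * config.n_funnel_poses)

    scores_arr = np.asarray(scores) + score_offset
    e_min = scores_arr.min()

    # Linear energy-RMSD coupling; funnel poses are pinned to the correct
    # side of the near-native threshold so planted bookkeeping is exact.
    model = (config.rmsd_at_minimum
             + config.rmsd_slope * (scores_arr - e_min)
             + rng.normal(0.0, config.rmsd_noise_std, scores_arr.size))
    nn_draw = rng.random(scores_arr.size) < config.near_native_fraction
    rmsds = np.clip(model, 0.0, config.rmsd_max)
    for i in range(scores_arr.size):
        if is_funnel[i]:
            if nn_draw[i]:
                rmsds[i] = min(rmsds[i], 0.95 * NEAR_NATIVE_THRESHOLD)
            else:
                rmsds[i] = max(rmsds[i], 1.05 * NEAR_NATIVE_THRESHOLD)

    directions = _unit_vectors(rng, scores_arr.size) if with_coords else None

    poses = []
    funnel_ids = set()
    for i in range(scores_arr.size):
        pid = f"{kind[0]}{runs[i]}-{i:04d}"
        coords = None
        if directions is not None:
            coords = _TEMPLATE + rmsds[i] * directions[i]
        poses.append(Pose(pose_id=pid, score=float(scores_arr[i]), coords=coords,
                          rmsd_to_ref=float(rmsds[i]), run_id=runs[i]))
        if is_funnel[i]:
            funnel_ids.add(pid)

    stack = build_stack(ligand_id, receptor_id, poses, config.dedup_tolerance)
    near_native_ids = frozenset(
        p.pose_id for p in stack.poses
        if p.rmsd_to_ref < NEAR_NATIVE_THRESHOLD)
    reference = Pose(pose_id=f"{ligand_id}:ref", score=0.0,
                     coords=_TEMPLATE.copy()) if with_coords else None
    truth = StackTruth(
        ligand_id=ligand_id, receptor_id=receptor_id, kind=kind, seed=seed,
        score_offset=score_offset,
        funnel_pose_ids=frozenset(funnel_ids),
        near_native_pose_ids=near_native_ids,
        has_near_native=bool(near_native_ids),
        reference=reference,
    )
    return stack, truth


@dataclass
class BenchmarkResult:
    """A labeled synthetic screening benchmark with full planted truth."""

    screening_set: ScreeningSet
    stacks: dict[tuple[str, str], PoseStack]
    truths: dict[tuple[str, str], StackTruth]
    labels: dict[str, str]
    ligand_bias: dict[str, float] = field(default_factory=dict)
    receptor_offset: dict[str, float] = field(default_factory=dict)

    def pose_benchmark(self, label: str = "binder",
                       ) -> list[tuple[PoseStack, Pose | None]]:
        """(stack, reference) pairs for native-phase analysis, one label class."""
        out = []
        for (lig, rec), stack in sorted(self.stacks.items()):
            if self.labels[lig] == label:
                out.append((stack, self.truths[(lig, rec)].reference))
        return out

    def truth_json(self) -> str:
        """Planted truth as a JSON string (for CLI emission)."""
        payload = {
            "labels": self.labels,
            "ligand_bias": self.ligand_bias,
            "receptor_offset": self.receptor_offset,
            "stacks": {
                f"{lig}|{rec}": {
                    "kind": t.kind,
                    "seed": t.seed,
                    "score_offset": t.score_offset,
                    "n_funnel_poses": len(t.funnel_pose_ids),
                    "near_native_pose_ids": sorted(t.near_native_pose_ids),
                    "has_near_native": t.has_near_native,
                }
                for (lig, rec), t in sorted(self.truths.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def simulate_benchmark(config_binder: SimConfig, config_decoy: SimConfig,
                       n_binders: int, n_decoys_per_binder: int = 20,
                       n_receptors: int = 1, seed: int | None = None,
                       with_coords: bool = False) -> BenchmarkResult:
    """Generate a labeled binder/decoy screening benchmark.

    ``n_binders`` funnel ligands and ``n_binders × n_decoys_per_binder``
    rugged ligands are docked (synthetically) against ``n_receptors``
    receptor conformations.  Receptor-ensemble variation enters as additive
    per-receptor score offsets ``~ N(0, 1)`` kcal/mol; per-ligand systematic
    biases ``~ N(0, ligand_bias_std)`` are shared across the ensemble.
    """
    if n_binders < 1 or n_decoys_per_binder < 1 or n_receptors < 1:
        raise ContractError("n_binders, n_decoys_per_binder, n_receptors must be >= 1")
    rng = np.random.default_rng(seed)
    binders = [f"B{i:04d}" for i in range(n_binders)]
    decoys = [f"D{i:04d}" for i in range(n_binders * n_decoys_per_binder)]
    receptors = [f"R{j:02d}" for j in range(n_receptors)]
    labels = {**{b: "binder" for b in binders}, **{d: "decoy" for d in decoys}}

    ligand_bias = {
        lig: float(rng.normal(0.0, (config_binder if labels[lig] == "binder"
                                    else config_decoy).ligand_bias_std))
        for lig in binders + decoys
    }
    receptor_offset = {rec: float(rng.normal(0.0, RECEPTOR_OFFSET_STD))
                       for rec in receptors}

    stacks: dict[tuple[str, str], PoseStack] = {}
    truths: dict[tuple[str, str], StackTruth] = {}
    for lig in binders + decoys:
        cfg = config_binder if labels[lig] == "binder" else config_decoy
        kind = "funnel" if labels[lig] == "binder" else "rugged"
        for rec in receptors:
            sub_seed = int(rng.integers(0, 2 ** 31))
            stack, truth = simulate_stack(
                cfg, kind, seed=sub_seed, ligand_id=lig, receptor_id=rec,
                with_coords=with_coords,
                score_offset=ligand_bias[lig] + receptor_offset[rec])
            stacks[(lig, rec)] = stack
            truths[(lig, rec)] = truth

    sset = ScreeningSet.from_stacks(
        [stacks[key] for key in sorted(stacks)], labels)
    return BenchmarkResult(screening_set=sset, stacks=stacks, truths=truths,
                           labels=labels, ligand_bias=ligand_bias,
                           receptor_offset=receptor_offset)
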