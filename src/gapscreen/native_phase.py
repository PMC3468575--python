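"""Native-binding-phase analyses of docking pose stacks.

The binding energy landscape has two phases: a non-native unbinding phase
(the broad band of background poses) and a native binding phase — the
cluster of near-native conformations within a fixed energy cutoff above the
best-scored pose.  On diverse benchmarks that phase extends roughly
7 kcal/mol above the minimum and about 6 Å (heavy-atom RMSD) wide, and the
correct X-ray binding mode is much more often found among the phase members
than at the single best-scored pose.

Operations here take either real coordinates plus a reference pose, or
per-pose precomputed ``rmsd_to_ref`` values (score-table-only workflows).
A pose is *near native* when its heavy-atom RMSD to the crystallographic
pose is strictly under 2.0 Å.

All operations return per-stack values; benchmark-level aggregates (mean
width, success-rate curves, rank fractions) are separate reductions so the
units stay auditable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateStackError, EvaluationError, GeometryError
from .landscape import NATIVE_PHASE_HEIGHT, clustered_gap, energy_gap
from .stack_io import Pose, PoseStack, heavy_atom_rmsd

#: Heavy-atom RMSD (Å) below which a pose counts as near native (strict).
NEAR_NATIVE_THRESHOLD = 2.0

#: Default energy-cutoff sweep grid (kcal/mol above the best score).
DEFAULT_CUTOFFS = (0.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0)

Benchmark = Sequence[tuple[PoseStack, Pose | None]]


def rmsds_to_reference(stack: PoseStack, reference: Pose | None = None,
                       ) -> np.ndarray:
    """Per-pose heavy-atom RMSD to the reference, in stack order (Å).

    Computed from coordinates when a reference pose is supplied and the
    stack carries them; otherwise read from each pose's precomputed
    ``rmsd_to_ref``.  Raises :class:`GeometryError` when neither source of
    geometric information is available.
    """
    if reference is not None and stack.has_coords:
        return np.array([heavy_atom_rmsd(p, reference) for p in stack.poses])
    if stack.has_rmsd:
        return np.array([p.rmsd_to_ref for p in stack.poses], dtype=float)
    raise GeometryError(
        f"stack ({stack.ligand_id}, {stack.receptor_id}) has neither "
        "coordinates+reference nor precomputed rmsd_to_ref values")


def phase_members(stack: PoseStack, cutoff: float) -> list[Pose]:
    """Poses within the energy cutoff of the best score (best pose included)."""
    if cutoff < 0:
        raise ValueError(f"energy cutoff must be >= 0, got {cutoff}")
    limit = stack.e_min + cutoff
    return [p for p in stack.poses if p.score <= limit]


def min_rmsd_in_phase(stack: PoseStack, reference: Pose | None,
                      cutoff: float) -> tuple[float, str]:
    """Closest approach to the reference among phase members.

    Returns ``(min RMSD, pose_id)``; ties in RMSD break by pose_id for
    determinism.
    """
    if cutoff < 0:
        raise ValueError(f"energy cutoff must be >= 0, got {cutoff}")
    rmsds = rmsds_to_reference(stack, reference)
    limit = stack.e_min + cutoff
    best: tuple[float, str] | None = None
    for p, r in zip(stack.poses, rmsds):
        if p.score <= limit:
            cand = (float(r), p.pose_id)
            if best is None or cand < best:
                best = cand
    return best  # phase always contains the best pose


def near_native_success(min_rmsd: float,
                        threshold: float = NEAR_NATIVE_THRESHOLD) -> bool:
    """True iff the closest pose is strictly under the near-native threshold."""
    if min_rmsd < 0:
        raise ValueError(f"min_rmsd must be >= 0, got {min_rmsd}")
    return min_rmsd < threshold


def success_rate_curve(benchmark: Benchmark,
                       cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
                       threshold: float = NEAR_NATIVE_THRESHOLD) -> np.ndarray:
    """Fraction of ligands with a near-native pose inside the phase, per cutoff.

    Non-decreasing in the cutoff: enlarging the phase can only bring the
    closest member closer to the reference.
    """
    if not benchmark:
        raise EvaluationError("empty benchmark")
    out = np.zeros(len(cutoffs))
    for stack, ref in benchmark:
        rmsds = rmsds_to_reference(stack, ref)
        scores = stack.scores
        for j, c in enumerate(cutoffs):
            m = rmsds[scores <= scores[0] + c].min()
            if near_native_success(float(m), threshold):
                out[j] += 1
    return out / len(benchmark)


def first_near_native_rank(stack: PoseStack, reference: Pose | None = None,
                           threshold: float = NEAR_NATIVE_THRESHOLD,
                           ) -> int | None:
    """1-based rank (in score order) of the first near-native pose, or None."""
    rmsds = rmsds_to_reference(stack, reference)
    for i, r in enumerate(rmsds):
        if r < threshold:
            return i + 1
    return None


def phase_width(stack: PoseStack, cutoff: float,
                ) -> float:
    """Maximum heavy-atom RMSD from the best pose to any phase member (Å).

    With coordinates this is exact.  Without coordinates but with per-pose
    ``rmsd_to_ref`` values, the pose-to-pose distance is geometrically
    underdetermined and the reverse triangle inequality lower bound
    ``max |r_i − r_best|`` is returned instead (still monotone in the
    cutoff); this mode is flagged for score-table-only workflows.
    """
    members = phase_members(stack, cutoff)
    best = stack.poses[0]
    if stack.has_coords:
        return max(heavy_atom_rmsd(best, m) for m in members)
    if stack.has_rmsd:
        r0 = best.rmsd_to_ref
        return max(abs(m.rmsd_to_ref - r0) for m in members)
    raise GeometryError(
        f"stack ({stack.ligand_id}, {stack.receptor_id}) carries no geometric data")


def energy_to_first_near_native(stack: PoseStack, reference: Pose | None = None,
                                threshold: float = NEAR_NATIVE_THRESHOLD,
                                ) -> float | None:
    """Score of the first near-native pose minus the best score (kcal/mol).

    0 when the best pose is itself near native; None when no near-native
    pose exists.  Always ≥ 0 by stack ordering.
    """
    rank = first_near_native_rank(stack, reference, threshold)
    if rank is None:
        return None
    return float(stack.poses[rank - 1].score - stack.e_min)


def phase_profile(stack: PoseStack, reference: Pose | None = None,
                  cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
                  threshold: float = NEAR_NATIVE_THRESHOLD) -> pd.DataFrame:
    """Full cutoff sweep for one stack.

    One row per cutoff: n_members, clustered_gap (NaN where the phase
    swallows the stack or the stack is too small), min_rmsd, success,
    phase_width, plus the per-stack first_nn_rank and energy_to_first_nn
    repeated on every row for a flat CSV layout.
    """
    rank = first_near_native_rank(stack, reference, threshold)
    e_first = energy_to_first_near_native(stack, reference, threshold)
    rows = []
    for c in cutoffs:
        try:
            g = clustered_gap(stack, c).gap if c > 0 else energy_gap(stack).gap
        except DegenerateStackError:
            g = float("nan")
        mr, _ = min_rmsd_in_phase(stack, reference, c)
        rows.append({
            "ligand_id": stack.ligand_id, "receptor_id": stack.receptor_id,
            "cutoff": c, "n_members": len(phase_members(stack, c)),
            "clustered_gap": g, "min_rmsd": mr,
            "success": near_native_success(mr, threshold),
            "phase_width": phase_width(stack, c),
            "first_nn_rank": rank, "energy_to_first_nn": e_first,
        })
    return pd.DataFrame(rows)


def write_phase_csv(benchmark: Benchmark, path: str | Path,
                    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
                    threshold: float = NEAR_NATIVE_THRESHOLD) -> None:
    """Write concatenated phase profiles for a benchmark to CSV."""
    frames = [phase_profile(s, r, cutoffs, threshold) for s, r in benchmark]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Benchmark-level reductions
# ---------------------------------------------------------------------------

def mean_phase_width(benchmark: Benchmark,
                     cutoff: float = NATIVE_PHASE_HEIGHT) -> float:
    """Mean over the benchmark of the per-stack phase width at one cutoff (Å)."""
    if not benchmark:
        raise EvaluationError("empty benchmark")
    return float(np.mean([phase_width(s, cutoff) for s, _ in benchmark]))


def first_rank_fraction(benchmark: Benchmark, within: int,
                        threshold: float = NEAR_NATIVE_THRESHOLD) -> float:
    """Fraction of ligands whose first near-native pose ranks within ``within``.

    Ligands with no near-native pose at all are excluded from the
    denominator (the statistic describes where the first hit falls, given
    one exists).
    """
    ranks = [first_near_native_rank(s, r, threshold) for s, r in benchmark]
    ranks = [k for k in ranks if k is not None]
    if not ranks:
        raise EvaluationError("no stack in the benchmark has a near-native pose")
    return float(np.mean([k <= within for k in ranks]))


def mean_energy_to_first_near_native(benchmark: Benchmark,
                                     threshold: float = NEAR_NATIVE_THRESHOLD,
                                     ) -> float:
    """Mean energy climb from the best pose to the first near-native pose.

    Averaged over stacks that contain a near-native pose, kcal/mol.
    """
    vals = [energy_to_first_near_native(s, r, threshold) for s, r in benchmark]
    vals = [v for v in vals if v is not None]
    if not vals:
        raise EvaluationError("no stack in the benchmark has a near-native pose")
    return float(np.mean(vals))
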