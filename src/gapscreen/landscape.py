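"""Energy-gap descriptors of the binding energy landscape.

A docking pose stack samples the ligand's binding energy landscape on one
receptor conformation.  A specific binder sees a funnel: one deep, isolated
minimum well below a band of background solutions.  A decoy sees a rugged
band with no such minimum.  The *energy gap*

    gap = E_min − ⟨E_rest⟩

(the lowest score minus the mean of all other geometrically unique scores)
is a one-number proxy for funnel sharpness: strongly negative for funnels,
near the background extreme-value offset for rugged landscapes.  The
clustered variant replaces E_min with the mean of the native-phase cluster
(all poses within a fixed energy cutoff of the minimum), probing how high
above the best pose the native binding phase extends.

Sign convention: gaps are reported signed, negative for funnel-like stacks;
screening ranks ascending, most negative first.  "Larger gap" in the
screening sense means larger magnitude of a negative gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateStackError
from .stack_io import PoseStack

#: Native-binding-phase height (kcal/mol) above the best score: the energy
#: cutoff below which clustered-gap screening performance remains good on
#: benchmark ensembles.
NATIVE_PHASE_HEIGHT = 7.0


@dataclass(frozen=True)
class GapResult:
    """Energy-gap descriptor value with validity status and components.

    ``gap = (cluster mean) − (rest mean)`` exactly; in default mode the
    cluster is the single best pose, so ``gap = e_min − mean_rest``.
    ``valid`` is False whenever ``e_min > 0`` or ``mean_rest > 0`` —
    positive energies indicate clashes or strained geometries and such
    complexes are excluded from screening datasets.
    """

    e_min: float
    mean_rest: float
    gap: float
    n_cluster: int
    n_rest: int
    valid: bool


def _require_poses(stack: PoseStack, n: int, what: str) -> np.ndarray:
    scores = stack.scores
    if scores.size < n:
        raise DegenerateStackError(
            f"{what} needs at least {n} poses; stack "
            f"({stack.ligand_id}, {stack.receptor_id}) has {scores.size}")
    return scores


def energy_gap(stack: PoseStack) -> GapResult:
    """Energy gap between the best pose and the mean of all other poses.

    Raises :class:`DegenerateStackError` on single-pose stacks, where the
    rest-mean is undefined.
    """
    scores = _require_poses(stack, 2, "energy_gap")
    e_min = float(scores[0])
    mean_rest = float(scores[1:].mean())
    return GapResult(
        e_min=e_min,
        mean_rest=mean_rest,
        gap=e_min - mean_rest,
        n_cluster=1,
        n_rest=scores.size - 1,
        valid=e_min <= 0 and mean_rest <= 0,
    )


def clustered_gap(stack: PoseStack, cutoff: float) -> GapResult:
    """Energy gap with the native-phase cluster in place of the single best pose.

    The cluster is every pose with score ≤ e_min + cutoff (the best pose
    always included); the gap is the cluster mean minus the mean of the
    remaining poses.  ``cutoff = 0`` reduces exactly to :func:`energy_gap`
    whenever the minimum is unique.

    Raises :class:`DegenerateStackError` when the cluster swallows the whole
    stack (no rest poses left to average).
    """
    if cutoff < 0:
        raise ValueError(f"energy cutoff must be >= 0, got {cutoff}")
    scores = _require_poses(stack, 2, "clustered_gap")
    e_min = float(scores[0])
    in_cluster = scores <= e_min + cutoff
    if in_cluster.all():
        raise DegenerateStackError(
            f"cutoff {cutoff} kcal/mol swallows all {scores.size} poses of "
            f"({stack.ligand_id}, {stack.receptor_id}); no rest poses remain")
    cluster = scores[in_cluster]
    rest = scores[~in_cluster]
    mean_rest = float(rest.mean())
    return GapResult(
        e_min=e_min,
        mean_rest=mean_rest,
        gap=float(cluster.mean()) - mean_rest,
        n_cluster=int(cluster.size),
        n_rest=int(rest.size),
        valid=e_min <= 0 and mean_rest <= 0,
    )


def validity_filter(stack: PoseStack) -> bool:
    """True iff the stack passes the screening validity filter.

    A stack is valid when both the lowest score and the mean of all other
    scores are ≤ 0.  Positive values flag protein–ligand clashes or high
    conformational strain; such complexes are dropped from screening
    datasets (and counted) rather than scored.
    """
    scores = _require_poses(stack, 2, "validity_filter")
    return bool(scores[0] <= 0 and scores[1:].mean() <= 0)


def isr(stack: PoseStack, spread: str = "std") -> float:
    """Intrinsic specificity ratio: |gap| over the spread of the weak binders.

    The numerator is the magnitude of the energy gap; the denominator is the
    spread of all non-best pose scores — the population standard deviation
    by default (``spread="std"``), or the population variance
    (``spread="variance"``).  Dimensionless for the std form.
    """
    if spread not in ("std", "variance"):
        raise ValueError(f"spread must be 'std' or 'variance', got {spread!r}")
    scores = _require_poses(stack, 3, "isr")
    rest = scores[1:]
    var = float(rest.var(ddof=0))
    if var == 0.0:
        raise DegenerateStackError(
            "ISR undefined: zero spread among non-best pose scores")
    gap = float(scores[0] - rest.mean())
    denom = var if spread == "variance" else float(np.sqrt(var))
    return abs(gap) / denom


def gap_table(stacks: Sequence[PoseStack], cutoff: float = 0.0) -> pd.DataFrame:
    """Tabulate gap descriptors for many stacks.

    One row per stack: ligand_id, receptor_id, e_min, mean_rest, gap,
    n_cluster, n_rest, valid.  ``cutoff > 0`` switches to the clustered gap.
    """
    rows = []
    for s in stacks:
        r = clustered_gap(s, cutoff) if cutoff > 0 else energy_gap(s)
        rows.append({"ligand_id": s.ligand_id, "receptor_id": s.receptor_id,
                     "e_min": r.e_min, "mean_rest": r.mean_rest, "gap": r.gap,
                     "n_cluster": r.n_cluster, "n_rest": r.n_rest,
                     "valid": r.valid})
    return pd.DataFrame(rows, columns=["ligand_id", "receptor_id", "e_min",
                                       "mean_rest", "gap", "n_cluster",
                                       "n_rest", "valid"])


def write_gap_csv(stacks: Sequence[PoseStack], path: str | Path,
                  cutoff: float = 0.0) -> None:
    """Write :func:`gap_table` output to CSV."""
    gap_table(stacks, cutoff).to_csv(path, index=False)
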