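"""Virtual-screening evaluation: ROC AUC, permutation σ, P-values, early recognition.

Evaluates how well a per-ligand score (best docking score, energy gap, ...)
separates true binders from decoys.  AUC is computed as the Mann–Whitney
pair statistic — the fraction of (binder, decoy) pairs in which the binder
outranks the decoy, ties counting one half — which equals the area under
the ROC curve.  Statistical significance follows the rank-reshuffle recipe:
σ is the RMS deviation about 0.5 of AUCs computed on random label
permutations of the fixed rank order, and the P-value is the two-sided
Gaussian tail erfc(|AUC − 0.5| / (σ√2)).

Both single-receptor-conformation (SRC) screens and multiple-receptor-
conformation (MRC) ensembles are supported; MRC reduces each ligand's
records over the receptor ensemble to a single (best_score, gap) pair
before evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc
from scipy.stats import rankdata

from .errors import EvaluationError

#: Reshuffle count used for the significance σ.
DEFAULT_N_SHUFFLES = 20

#: Threshold grid for AUC-distribution summaries.
AUC_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)

_RECORD_COLUMNS = ["ligand_id", "receptor_id", "label", "best_score", "gap", "valid"]


def _as_binary_labels(labels: Sequence) -> np.ndarray:
    """Normalize labels to a boolean array (True = binder)."""
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            low = lab.strip().lower()
            if low == "binder":
                out[i] = True
            elif low == "decoy":
                out[i] = False
            else:
                raise EvaluationError(f"unrecognized label {lab!r}")
        else:
            out[i] = bool(lab)
    return out


def _directed(scores: np.ndarray, direction: str) -> np.ndarray:
    """Map scores so that larger means better-ranked."""
    if direction == "lower":
        return -scores
    if direction == "higher":
        return scores
    raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")


def roc_auc(scores: Sequence[float], labels: Sequence,
            direction: str = "lower") -> float:
    """ROC AUC of a score for binder/decoy discrimination.

    Mann–Whitney form: the fraction of (binder, decoy) pairs in which the
    binder is better ranked, ties counting 0.5.  ``direction`` states
    whether lower or higher scores are better (docking scores and energy
    gaps are both lower-is-better).  1 = perfect separation, 0.5 = random.
    """
    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise EvaluationError("scores and labels must have equal length")
    if not np.isfinite(s).all():
        raise EvaluationError("scores must be finite")
    n1 = int(y.sum())
    n2 = int((~y).sum())
    if n1 == 0 or n2 == 0:
        raise EvaluationError(
            f"need at least one binder and one decoy (got {n1} binders, {n2} decoys)")
    ranks = rankdata(_directed(s, direction))  # average ranks → 0.5 per tied pair
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n2))


def reshuffle_sigma(labels: Sequence, n_shuffles: int = DEFAULT_N_SHUFFLES,
                    seed: int | None = None) -> float:
    """Null-width σ of the AUC from label reshuffles.

    Randomly permutes the binder/decoy assignment over the fixed rank order
    ``n_shuffles`` times, computes each permutation's AUC, and returns the
    root-mean-square deviation of those AUCs about 0.5 (the null mean).
    Reproducible under a fixed ``seed``.
    """
    if n_shuffles < 2:
        raise ValueError(f"n_shuffles must be >= 2, got {n_shuffles}")
    y = _as_binary_labels(labels)
    n = y.size
    n1 = int(y.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise EvaluationError("degenerate label vector: need both classes")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, n + 1, dtype=float)
    devs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(n)
        binder_ranks = ranks[perm[:n1]]
        auc = (binder_ranks.sum() - n1 * (n1 + 1) / 2) / (n1 * n2)
        devs[i] = auc - 0.5
    return float(np.sqrt((devs ** 2).mean()))


def pvalue(auc: float, sigma: float) -> float:
    """Probability of reaching the observed AUC by random coincidence.

    Two-sided tail of a Gaussian null centered at 0.5 with width σ:
    ``P = erfc(|auc − 0.5| / (σ·√2))``.  P(0.5) = 1; P decreases
    monotonically as the AUC moves away from 0.5.  P < 0.05 is read as a
    statistically significant screen.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return float(erfc(abs(auc - 0.5) / (sigma * math.sqrt(2.0))))


def early_recognition(scores: Sequence[float], labels: Sequence,
                      direction: str = "lower",
                      ids: Sequence[str] | None = None) -> float:
    """Fraction of true binders recovered within the top-N ranked ligands.

    N is the number of true binders.  Ties in score are broken by ligand id
    for determinism.
    """
    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise EvaluationError("empty input")
    n1 = int(y.sum())
    if n1 == 0:
        raise EvaluationError("need at least one binder")
    if ids is None:
        ids = [f"{i:08d}" for i in range(s.size)]
    order = sorted(range(s.size), key=lambda i: (-_directed(s, direction)[i], ids[i]))
    top = order[:n1]
    return float(y[top].sum() / n1)


@dataclass
class ScreeningSet:
    """Labeled per-(ligand, receptor) descriptor records for one screen.

    ``records`` columns: ligand_id, receptor_id, label ("binder"/"decoy"),
    best_score, gap, valid.  Each (ligand, receptor) pair appears at most
    once; labels are normalized to lower case.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise EvaluationError(f"screening set missing columns: {missing}")
        df["label"] = [
            "binder" if b else "decoy" for b in _as_binary_labels(df["label"])
        ]
        df["valid"] = df["valid"].astype(bool)
        dup = df.duplicated(subset=["ligand_id", "receptor_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["ligand_id", "receptor_id"]].tolist()
            raise EvaluationError(f"duplicate (ligand, receptor) record: {pair}")
        self.records = df.reset_index(drop=True)

    @property
    def n_receptors(self) -> int:
        return int(self.records["receptor_id"].nunique())

    @classmethod
    def from_stacks(cls, stacks, labels: Mapping[str, str]) -> "ScreeningSet":
        """Build a screening set from pose stacks and per-ligand labels."""
        from .landscape import energy_gap

        rows = []
        for s in stacks:
            r = energy_gap(s)
            rows.append({"ligand_id": s.ligand_id, "receptor_id": s.receptor_id,
                         "label": labels[s.ligand_id], "best_score": r.e_min,
                         "gap": r.gap, "valid": r.valid})
        return cls(pd.DataFrame(rows, columns=_RECORD_COLUMNS))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScreeningSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def mrc_aggregate(sset: ScreeningSet, method: str = "best-score-linked",
                  ) -> tuple[pd.DataFrame, int]:
    """Reduce a multi-receptor screen to one record per ligand.

    Invalid records are excluded first; ligands left with no valid record
    are dropped and counted in the returned ``n_excluded``.

    ``best-score-linked`` (default): per ligand, pick the receptor
    conformation with the lowest best_score and report that conformation's
    best_score *and its* gap.  ``best-gap``: pick the lowest best_score and,
    independently, the most negative gap over the ensemble.  Either way every
    reported value is a member of the input set.
    """
    if method not in ("best-score-linked", "best-gap"):
        raise ValueError(f"unknown aggregation method {method!r}")
    df = sset.records
    valid = df[df["valid"]]
    n_excluded = int(df["ligand_id"].nunique() - valid["ligand_id"].nunique())
    rows = []
    for lig, grp in valid.groupby("ligand_id", sort=True):
        grp = grp.sort_values(["best_score", "receptor_id"], kind="mergesort")
        best = grp.iloc[0]
        gap = best["gap"] if method == "best-score-linked" else grp["gap"].min()
        rows.append({"ligand_id": lig, "label": best["label"],
                     "best_score": float(best["best_score"]), "gap": float(gap)})
    out = pd.DataFrame(rows, columns=["ligand_id", "label", "best_score", "gap"])
    return out, n_excluded


@dataclass(frozen=True)
class EvalResult:
    """Evaluation of one screen for one descriptor."""

    auc: float
    sigma: float
    pvalue: float
    early_recognition: float
    n_binders: int
    n_decoys: int
    n_excluded: int


@dataclass(frozen=True)
class ScreenEvaluation:
    """Paired evaluation of a screen: best docking score vs energy gap."""

    best_score: EvalResult
    gap: EvalResult


def evaluate_screen(sset: ScreeningSet,
                    n_shuffles: int = DEFAULT_N_SHUFFLES,
                    seed: int | None = None,
                    mrc_method: str = "best-score-linked") -> ScreenEvaluation:
    """Evaluate one screen with both descriptors.

    Single-receptor sets are evaluated directly (invalid records dropped and
    counted); multi-receptor sets are first reduced per ligand via
    :func:`mrc_aggregate`.  The reshuffle σ is computed once per screen from
    the label vector and shared by both descriptors.
    """
    if sset.n_receptors > 1:
        table, n_excluded = mrc_aggregate(sset, method=mrc_method)
    else:
        df = sset.records
        table = df[df["valid"]][["ligand_id", "label", "best_score", "gap"]]
        n_excluded = int((~df["valid"]).sum())
    labels = table["label"].tolist()
    if not labels:
        raise EvaluationError("no valid records to evaluate")
    sigma = reshuffle_sigma(labels, n_shuffles=n_shuffles, seed=seed)
    ids = table["ligand_id"].tolist()
    results = {}
    for name in ("best_score", "gap"):
        scores = table[name].to_numpy(dtype=float)
        auc = roc_auc(scores, labels, direction="lower")
        results[name] = EvalResult(
            auc=auc,
            sigma=sigma,
            pvalue=pvalue(auc, sigma),
            early_recognition=early_recognition(scores, labels,
                                                direction="lower", ids=ids),
            n_binders=int(sum(1 for l in labels if l == "binder")),
            n_decoys=int(sum(1 for l in labels if l == "decoy")),
            n_excluded=n_excluded,
        )
    return ScreenEvaluation(best_score=results["best_score"], gap=results["gap"])


def auc_distribution_summary(aucs: Sequence[float],
                             thresholds: Sequence[float] = AUC_THRESHOLDS,
                             ) -> dict[float, float]:
    """Fraction of screens with AUC strictly greater than each threshold."""
    a = np.asarray(aucs, dtype=float)
    if a.size == 0:
        raise EvaluationError("empty AUC list")
    return {float(t): float((a > t).mean()) for t in thresholds}


def roc_points(scores: Sequence[float], labels: Sequence,
               direction: str = "lower") -> pd.DataFrame:
    """ROC curve points (fpr, tpr) at every score threshold."""
    y = _as_binary_labels(labels)
    s = _directed(np.asarray(scores, dtype=float), direction)
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    n1 = y.sum()
    n2 = (~y).sum()
    if n1 == 0 or n2 == 0:
        raise EvaluationError("need both classes for a ROC curve")
    tpr = np.concatenate([[0.0], np.cumsum(y) / n1])
    fpr = np.concatenate([[0.0], np.cumsum(~y) / n2])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def write_eval_csv(evaluations: Mapping[str, ScreenEvaluation],
                   path: str | Path) -> None:
    """Write per-screen evaluations (one row per screen) to CSV."""
    rows = []
    for screen_id, ev in evaluations.items():
        rows.append({
            "screen_id": screen_id,
            "auc_score": ev.best_score.auc, "auc_gap": ev.gap.auc,
            "sigma": ev.gap.sigma,
            "pvalue_score": ev.best_score.pvalue, "pvalue_gap": ev.gap.pvalue,
            "early_score": ev.best_score.early_recognition,
            "early_gap": ev.gap.early_recognition,
            "n_binders": ev.gap.n_binders, "n_decoys": ev.gap.n_decoys,
            "n_excluded": ev.gap.n_excluded,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
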