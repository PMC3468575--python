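# gapscreen

Energy-gap analysis of protein–ligand binding energy landscapes for
virtual screening.

## The problem

Structure-based virtual screening ranks a chemical library by docking each
ligand into a receptor and sorting by the best docking score.  The best
score alone, however, sees only the final bound state: a decoy can show
excellent *in silico* complementarity in one pose and still be biologically
irrelevant because it binds many places equally badly.  What distinguishes
a specific binder is the *shape* of its binding energy landscape — a
funnel with a deep, isolated native minimum — rather than the depth of a
single point.

`gapscreen` implements the one-number descriptor of that shape, the
**energy gap**

$$\mathrm{gap} = E_{\min} - \langle E_{\mathrm{rest}}\rangle ,$$

the lowest pose score of a docking pose stack minus the mean score of all
other geometrically unique poses (kcal/mol; strongly negative for
funnels).  Because the gap is a within-stack difference it cancels the
systematic per-ligand score offsets that corrupt raw docking scores, and
it rescores a screen at zero additional docking cost: every number it
needs is already in the pose stack.  The package is docking-engine
agnostic — it consumes scored pose stacks as CSV/TSV tables or SDF files
and never evaluates a scoring function itself.

It is intended for computational chemists who post-process docking runs:
rescoring screens (single receptor or receptor ensembles), quantifying
binder/decoy discrimination (ROC AUC with permutation significance and
early-recognition fractions), analysing the *native binding phase* (the
cluster of poses within an energy cutoff of the minimum, ~7 kcal/mol high
in benchmark studies), and selecting near-native poses (< 2 Å heavy-atom
RMSD to a reference) far more reliably than the top-scored pose alone.  A
landscape simulator with planted ground truth makes the whole pipeline
testable without any docking software.

## Worked example

```python
from gapscreen import SimConfig, simulate_benchmark, evaluate_screen, energy_gap

cfg = SimConfig()  # 3 runs x 200 poses, background -15 +/- 3, funnel 10 kcal/mol deep
bench = simulate_benchmark(cfg, cfg.replace(funnel_depth=0.0),
                           n_binders=8, n_decoys_per_binder=20, seed=7)

stack = bench.stacks[("B0000", "R00")]
r = energy_gap(stack)
print(f"binder stack: {len(stack)} unique poses, "
      f"E_min = {r.e_min:.1f} kcal/mol, gap = {r.gap:.1f} kcal/mol")

ev = evaluate_screen(bench.screening_set, seed=7)
print(f"AUC(best score) = {ev.best_score.auc:.3f}")
print(f"AUC(energy gap) = {ev.gap.auc:.3f}  (P = {ev.gap.pvalue:.1e})")
print(f"early recognition: score {ev.best_score.early_recognition:.2f}, "
      f"gap {ev.gap.early_recognition:.2f}")
```

prints

```
binder stack: 620 unique poses, E_min = -26.4 kcal/mol, gap = -11.0 kcal/mol
AUC(best score) = 0.815
AUC(energy gap) = 0.933  (P = 7.5e-06)
early recognition: score 0.25, gap 0.12
```

The binder's funnel gives it a −11.0 kcal/mol gap while rugged decoy
stacks plateau near the extreme-value floor (≈ −9.3 kcal/mol for 600
Gaussian poses with 3 kcal/mol spread), so ranking by gap separates the 8
binders from the 160 decoys with AUC 0.93 — versus 0.82 for the raw best
score, which is blurred by per-ligand score bias.  The P-value is the
two-sided Gaussian tail `erfc(|AUC−0.5|/(σ√2))` with σ estimated from 20
label reshuffles.  Early-recognition fractions count binders in the top-8
ranks and are correspondingly coarse (steps of 0.125) at this screen size.

The same operations run from the shell on your own pose tables:

```bash
gapscreen simulate --seed 11 --n-binders 8 --out-prefix demo   # or bring your own CSV/SDF
gapscreen gap    demo_stacks.csv --out gaps.csv
gapscreen screen demo_stacks.csv demo_labels.csv --seed 0
gapscreen phase  demo_stacks.csv --out phase.csv --cutoffs 0,3,7
```

Input tables need columns `ligand_id, receptor_id, score` (plus optional
`run, pose_id, rmsd_to_ref`); SDF input carries the score in a property
tag (default `Score`).

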