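# Methods

## The descriptor

Docking one ligand into one receptor conformation yields a *pose stack*: a
few hundred scored binding poses (gapscreen defaults to the common protocol
of 3 independent runs × 200 poses), merged across runs, reduced to
geometrically unique solutions and sorted by score.  The stack is a sample
of the protein–ligand binding energy landscape.  For a specific binder that
landscape is funnel-shaped — a deep, isolated native minimum below a band
of non-native solutions — while for a non-binder it is a rugged band with
no dominant minimum.

The **energy gap** condenses this shape into one number:

    gap = E_min − ⟨E_rest⟩

where `E_min` is the best (lowest) score and `⟨E_rest⟩` the arithmetic mean
of every other unique pose score.  It is strongly negative for funnels and
sits near the background extreme-value offset for rugged stacks.  Two
properties matter in practice:

* **Translation invariance.**  Adding a constant to every score of a stack
  leaves the gap unchanged.  Raw docking scores carry systematic per-ligand
  offsets (ligand size being the classic one); the gap cancels them, the
  best score does not.  This is the mechanism behind the gap's screening
  advantage, and the simulator models it explicitly (below).
* **Extreme-value floor.**  Even a pure-noise stack of m Gaussian scores
  with spread σ shows an apparent gap near −σ·√(2 ln m) (about −9.7
  kcal/mol for m = 600, σ = 3).  The gap therefore separates classes only
  through the *excess* depth of the native well over this floor; it is a
  relative, not an absolute, descriptor.

The **clustered gap** replaces `E_min` with the mean of the *native-phase
cluster* — all poses within an energy cutoff c of the minimum — and
compares it to the mean of the remainder.  At c = 0 it reduces to the plain
gap (exactly, whenever the minimum is unique; with tied minima the cluster
keeps all tied poses, a case that never arises for continuous scores).
Sweeping c while monitoring screening performance probes how high the
native binding phase extends; the package default for the phase height is
7.0 kcal/mol.

The **ISR** (intrinsic specificity ratio) divides |gap| by the spread of
the non-best scores.  Whether that spread is a standard deviation or a
variance is ambiguous in the literature this descriptor comes from; both
are exposed (`spread="std"`, population form with divisor n, is the
default).

**Validity filter.**  A stack whose minimum or rest-mean is positive
indicates clashes or severe strain; such ligand–receptor records are
excluded from screening datasets and counted (`n_excluded`), never scored.

## Stack processing

* Poses are sorted ascending by `(score, pose_id)`; the id tie-break makes
  every downstream statistic deterministic.
* Deduplication is a greedy pass in that order: a pose is kept iff its
  heavy-atom RMSD to every already-kept pose exceeds the tolerance, so each
  geometric cluster is represented by its lowest-score member and `E_min`
  survives exactly.  The tolerance default is 0.5 Å — a package choice; no
  community-standard value exists for "geometrically unique".  Without
  coordinates the criterion degenerates to exact score equality (documented
  fallback for score-table workflows).
* RMSDs are heavy-atom, computed in the shared receptor frame *without*
  superposition (docked poses already live in one frame; aligning them
  would hide genuine displacement between binding modes).  Hydrogens never
  enter.  No molecular-symmetry (automorphism) correction is applied; plain
  RMSD is the conservative default and a correction can be layered on the
  coordinate arrays before stack construction if needed.
* Merging retains all unique poses; no cap is imposed on the merged stack
  size.

## Screening evaluation

AUC is the Mann–Whitney pair statistic (ties credit 0.5), computed from
rank sums — identical to, and cross-checked in the tests against, both an
O(n²) pair-count oracle and scikit-learn's `roc_auc_score`.  Significance
follows a permutation recipe: σ is the RMS deviation about 0.5 of AUCs
obtained by reshuffling the binder/decoy assignment over the fixed rank
order (default 20 reshuffles, seeded), and

    P = erfc(|AUC − 0.5| / (σ·√2)),

the two-sided tail of a Gaussian null centred at 0.5.  For balanced labels
σ estimates the analytic null width √((n₁+n₂+1)/(12 n₁ n₂)).  Early
recognition is the fraction of binders in the top N ranks, N = number of
binders, ties broken by ligand id.

Multi-receptor (MRC) screens are reduced to one record per ligand before
evaluation.  The default linkage picks the receptor conformation with the
lowest best score and reports *that conformation's* gap ("best-score-linked");
the alternative ("best-gap") selects the most negative gap independently.
The linkage rule is genuinely underdetermined in the ensemble-docking
literature; both are implemented and the linked form is the default because
it keeps the two descriptors referring to one physical complex.

## Native-phase analysis

`phase_members` takes all poses within c kcal/mol of the minimum
(inclusive).  Per-stack operations return per-stack values; benchmark
aggregates (success-rate curve, mean phase width, first-rank fractions,
mean energy climb to the first near-native pose) are separate reductions.
"Near native" means heavy-atom RMSD to the reference strictly under 2.0 Å.
All operations accept either coordinates plus a reference pose or per-pose
precomputed `rmsd_to_ref` values.  One caveat in the precomputed mode: the
phase *width* (max RMSD from the best pose to a phase member) is
geometrically underdetermined by RMSD-to-reference scalars alone, so the
reverse-triangle-inequality lower bound max|rᵢ − r_best| is returned; it
remains monotone in the cutoff.  Exact widths require coordinates.

## The simulator

`simulate_stack` generates the two landscape kinds:

* background band: scores ~ N(background_mean, background_std), defaults
  −15 ± 3 kcal/mol, 3 runs × 200 poses;
* funnel stacks additionally draw `n_funnel_poses` (default 20) scores from
  N(background_mean − funnel_depth, background_std/4) — a compact native
  well, default depth 10 kcal/mol.

Each pose gets an RMSD to a virtual crystallographic reference through a
linear energy–RMSD coupling (1.0 Å at the minimum + 0.3 Å per kcal/mol,
0.5 Å noise, clipped to [0, 12] Å), so low-energy poses lie near the
reference.  Funnel poses are pinned to the correct side of the 2 Å
near-native threshold with probability `near_native_fraction` (default
0.8), and the truth record registers, *on the final deduplicated stack*,
which poses are funnel-planted and which ended up near native — making
planted-fraction identities exact regardless of deduplication.

Benchmarks add two systematic score offsets, both ~Gaussian:

* a per-ligand bias (default σ = 2 kcal/mol, shared across the receptor
  ensemble) modelling ligand-dependent score inflation; invisible to the
  gap, damaging to the raw best score — this is what makes the benchmark's
  best scores "noise-matched" between classes while the funnel remains the
  true discriminant;
* a per-receptor offset (σ = 1 kcal/mol) providing the ensemble variation
  that exercises MRC aggregation.

With `with_coords=True` the generator also synthesizes geometry: a fixed
5-atom template rigidly translated by (planted RMSD) × (random unit
vector), so the no-superposition heavy-atom RMSD to the reference equals
the planted value exactly.  This powers the SDF round-trip and the exact
phase-width oracles.  The synthetic geometry is deliberately minimal: no
conformational degrees of freedom, no symmetry, no clash structure.

**What passing tests show, and what they do not.**  The generator captures
the funnel-vs-rugged dichotomy, extreme-value behaviour of stack minima,
energy–RMSD coupling, class-matched score noise and ensemble offsets.  It
does not capture score-function pathologies (correlated errors between
similar ligands), pocket-specific pose multiplicity, or real conformer
geometry; green tests certify the arithmetic and statistics of the
toolkit under a controlled landscape model, not screening performance on
any real target.

A structural limitation worth knowing: stacks are sampled *independently*
across receptor conformations.  Real cross-docking scores of one ligand
are strongly correlated across conformations; under independence, pooling
an ensemble of N stacks of m poses lets every ligand shop for a background
fluctuation as deep as ≈ background_std·√(2 ln(Nm)) (≈ 12.6 kcal/mol for
N = 12, m = 600).  An ensemble experiment is therefore only informative in
the deep-funnel regime funnel_depth ≳ that bound; the reproduction script
runs its MRC experiment at depth 14 kcal/mol for exactly this reason, and
single-structure (SRC) experiments at the default depth 10.

## Problem sizes and numerical choices

The test-suite and reproduction-script problem sizes (12-conformation
ensembles, 8 binders × 160 decoys, 50-seed replications, 60-ligand pose
benchmarks) were chosen so every stochastic property is decided by a
comfortable margin at desk scale.  Floats serialize via Python's
shortest round-trip `repr`, making CSV write→read→write byte-stable; SDF
coordinates carry the format's fixed 4-decimal precision, so geometric
round-trips are exact to 10⁻⁴ Å while scores (stored in property tags)
round-trip exactly.  Degenerate inputs fail loudly with typed exceptions:
single-pose stacks (gap undefined), phases swallowing a whole stack
(rest-mean undefined), zero rest-spread (ISR undefined), single-class
label vectors, and geometric operations on stacks without geometry.
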