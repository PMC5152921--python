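# Methods

This note documents the models, parameter choices and numerical policies
behind `vdrassay`, and what the synthetic-data tests do and do not show
about real assay data.

## Competition binding

One fixed concentration L of radiolabelled hormone (default 4 nM) is
displaced by a cold competitor over a log-spaced series (default 0 plus
half-decade steps over 10 nM–1 mM). Specific binding is
`mean(total) − mean(nonspecific)` per concentration; negative values are
retained, because clamping at zero would bias the bottom plateau upward
at high competitor concentrations.

The fitted model is pure one-site competition with Hill slope fixed at
−1:

    S(c) = bottom + (top − bottom) / (1 + c / IC50)

Rationale for the fixed slope: the Cheng–Prusoff conversion used
downstream presumes single-site competitive binding, and freeing the
slope on 12-point curves mostly fits noise. The fit is a joint
least-squares over every replicate tube (each total replicate minus the
mean nonspecific count at its concentration), not a mean-of-fits —
at desk scale (3 experiments × 2 replicates) the joint fit uses the
information better and the per-experiment spread is still visible in the
residuals. IC50 is optimized as log10(IC50) (initialized at the
geometric mean of the nonzero concentration range, relative tolerance
1e-8); c = 0 tubes are evaluated in linear space, where the model
reduces to `top`, so they pin the top plateau without a log(0) issue.
The reported 95% CI is asymptotic in log space (symmetric on the log
axis, hence asymmetric in µM, which matches how log-spaced designs
constrain IC50). Non-convergence sets a flag rather than raising; a
completely flat response is rejected as degenerate.

Ki is then `IC50 / (1 + L/Kd)` with Kd an external per-receptor input
(measured in saturation experiments elsewhere; this package never fits
it). All units are reconciled to molar internally, so any consistent
unit choice gives the same Ki.

## Dual-luciferase normalization

Every well's firefly signal is divided by its Renilla internal control
to cancel transfection efficiency. Fold effects are ratios of mean
normalized signal between a sample condition and a reference condition;
the reference differs by question (empty vector for basal
transactivation, receptor-alone for coregulator effects, bait-free prey
for two-hybrid interactions) but the arithmetic is identical, so one
function serves all three with the caller choosing the reference rows.

Experiments, not wells, are the replication unit: folds are computed per
experiment and then averaged (mean ± SEM, default n = 3 experiments of
4 wells). Assembly into the assays × species matrix takes the mean of
per-experiment folds per cell; a missing (assay, species) cell is a hard
error unless an explicit fill value (1.0 = no activation) is requested,
because silent filling would fabricate responses.

The coregulator annotation treats the AF2-truncated RXR as its own flag
rather than "RXR present": the truncation converts RXR from a
coactivation partner into a dominant-negative, functionally a different
reagent.

## Row normalization and clustering

Assays differ in dynamic range by orders of magnitude, so each row is
normalized across species before clustering. The default is a z-score
with sample SD (n−1); min–max scaling to [0, 1] and no normalization are
available (`row_norm: zscore|minmax|none`), and the planted-pattern
analyses are checked under both zscore and minmax to show the
conclusions do not hinge on the transform. Constant rows map to
all-zeros under either transform (0/0 guard).

Species are clustered on Manhattan (L1) distance between their
normalized assay profiles with complete linkage (inter-cluster distance
= maximum member-pair distance), implemented via the Lance–Williams max
update. Tie-breaking is an explicit contract: leaves are numbered in
column order, each new cluster takes the next id, and among equidistant
pairs the lexicographically smallest (id, id) pair merges first. This
makes dendrograms deterministic and platform-independent. Complete
linkage on a metric never inverts, so merge heights are non-decreasing
and the tree is ultrametric; the k-cluster partition is obtained by
undoing the last k−1 merges.

Newick export places each internal node at elevation height/2 (leaves at
0), so branch length = (parent height − child height)/2 and every
root-to-leaf path equals half the root height. Children are serialized
smallest-leaf-first for a canonical string.

## Bootstrap recapitulation and driver importance

The stability question: if the assay panel had been sampled differently,
would the same species clusters appear? Assays (rows) are resampled with
replacement to the original row count B times (default B = 10,000);
each resample is re-clustered and scored against the reference pattern.
"Recapitulated" means the k-cut equals the reference partition as
unordered sets AND every named subcluster is a clade, jointly; the
per-criterion rates are reported alongside so either convention can be
read out.

Two resampling readings of "over the assays according to
presence/absence of each of the co-regulators" are implemented:

* **plain** — rows resampled freely;
* **stratified** — rows resampled within strata of identical
  coregulator presence/absence signatures, preserving stratum sizes, so
  every pseudo-panel keeps the original design balance of
  coregulator-containing assays.

The stability headline (the recapitulation rate of the reference
pattern) uses the stratified scheme, which is this package's reading of
signature-respecting resampling: a free bootstrap confounds pattern
instability with accidental loss of entire assay classes from the
pseudo-panel, which stratification removes by design. The plain mode
remains the basis of the enumeration-oracle checks and of importance
scoring, where deleting assay classes is exactly the point.

Driver importance is leave-one-coregulator-out: remove every assay
containing coregulator g, re-run the plain bootstrap on the remaining
rows, and report `importance(g) = r_full − r_g` (per-subcluster drops
are reported too). Larger drops mean g's assays were carrying the
pattern. A coregulator absent from every assay gets importance 0 with a
warning; removal that leaves fewer than two rows is an error.
Importances lie in [−1, 1]; slightly negative values are normal
Monte-Carlo behavior for uninformative coregulators (removing noise rows
can stabilize the pattern).

Resampling operates on the normalized matrix. Row-wise transforms
commute with row resampling, so this equals normalize-then-resample; a
`renormalize_per_draw` flag exists for sensitivity analysis (it matters
only for transforms that are not per-row, or after row duplication under
minmax — not for the default z-score). One seeded generator drives each
bootstrap (draw order: B blocks of row indices); leave-out runs spawn
child seeds deterministically from the top-level seed.

## Synthetic-data generator

The generator emulates the study design: 8 receptors in two groups —
C1 = {lVDR, bVDR, sVDR, zfVDRb, mVDRb}, C2 = {zfVDRa, mVDRa, hVDR} — and
a 14-assay roster of 7 (assay class, coregulator set) combinations × 2
ligands (LCA and 1,25D3), covering transactivation alone, with RXR_WT,
with RXR_AF2, with RXR_WT+SRC1, and two-hybrid against SRC1, GRIP1 and
ACTR baits, so every coregulator flag occurs at least once.

* **Assay matrix.** Driver-annotated assays (default drivers RXR_WT and
  SRC1) separate the group means by `effect_size × noise_sd`
  (default 6 × 1); in the noiseless limit `noise_sd = 0` the noise-SD
  unit is taken as 1 so the separation is `effect_size` itself.
  Non-driver assays have equal group means. Cell noise is additive
  Gaussian — matrix entries are already normalized fold responses, where
  additive error on a common scale is the natural model.
* **Binding curves.** IC50 is derived from the planted Ki by inverting
  Cheng–Prusoff (`IC50 = Ki(1 + L/Kd)`; defaults Ki = 5 µM, Kd = 1 nM,
  L = 4 nM, inside the 4.2–9.5 µM affinity band typical of VDR–bile-acid
  binding). Counts get multiplicative Gaussian noise with CV 0.05, the
  scale-dependent error characteristic of scintillation counting. The
  nonspecific floor is flat at 20% of the c = 0 total.
* **Luciferase wells.** Firefly = baseline × fold × ε, control =
  baseline × ε′, with ε unit-mean lognormal (default CV 0.2, a typical
  plate-to-plate luminescence spread; the generator's CV is a design
  choice, not a measured quantity). Default planted folds 3.6 (hVDR) and
  1.8 (zfVDRa) echo the strong-human / weak-zebrafish-alpha LCA response
  magnitudes.

What passing tests show: the estimators recover planted parameters under
the stated noise models, the clustering recovers a planted partition
whose signal sits only in driver assays, and the bootstrap machinery is
exact against enumeration. What they do not show: robustness to
plate-layout artifacts, transfection-efficiency covariates, correlated
assay errors, or non-lognormal luminescence tails — none of which the
generator emulates.

## Problem sizes used in the checks

Parameter-recovery studies use 100 replicate designs; bootstrap
recapitulation is checked at B = 1,000 (stratified) on the default
matrix and B = 10,000 in the analysis scripts; leave-out importance
studies use B = 200 per leave-out across 100 replicate designs; the
enumeration oracle uses 3-assay panels (27 ordered resamples) against
B = 50,000 Monte-Carlo draws. These sizes give Monte-Carlo standard
errors comfortably below the margins being asserted.

## Known limitations

* Only Manhattan/complete-linkage clustering is implemented; the config
  names exist as validation guards, not escape hatches.
* The bootstrap reports recapitulation rates, not approximately-unbiased
  p-values; no multiscale correction is applied.
* Hypothesis tests on fold effects (ANOVA-family) are out of scope; the
  matrix carries effect sizes only.
* Kd estimation (saturation binding) is not implemented; Ki is only as
  good as the supplied Kd.
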