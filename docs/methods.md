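# Methods

This note documents the models implemented in `ancrebind`, the choices made
where the design was genuinely open, what the synthetic-data generators do
and do not emulate, and the numerical details that matter for reproducing
results.

## Ancestral sequence reconstruction (`asr`, `model`, `containers`)

**Model.** Amino-acid evolution follows the LG empirical replacement model
with its model-defined stationary frequencies. The rate matrix is
`Q_ij = S_ij * pi_j` off the diagonal, rows summing to zero, rescaled so the
stationary expected rate is one substitution per site — branch lengths are
expected substitutions/site. Among-site rate variation uses a discrete gamma
with `K = 4` equal-probability categories, each category represented by its
conditional mean rate (renormalized to average exactly 1); this is the
classic mean-category discretization and matches the rates produced by R
phangorn's `discrete.gamma` to 12 digits. The shape `alpha` (> 0,
dimensionless) is estimated by maximum likelihood; default start 1.0.

**Likelihood.** Felsenstein pruning over a rooted tree, vectorized across
sites, with per-node log-scale rescaling against underflow. Gaps and
unrecognized residues are missing data: the tip's conditional-likelihood
vector is all ones (no site removal). Transition matrices come from the
eigendecomposition of the reversible `Q` in the `pi^(1/2)`-symmetrized basis;
rows are clipped at zero and renormalized, which matters only at the
10^-16 level. The implementation agrees with brute-force enumeration over
internal states to < 1e-9 relative on all tested tree shapes, and with an
independent implementation (phangorn `pml`) to 10 decimal places on a frozen
fixture.

**Optimization.** The topology is fixed (it encodes prior knowledge of
species relationships); branch lengths are optimized coordinate-wise with
bounded scalar searches in [1e-8, 20], then `alpha` in [0.05, 50], sweeping
until the log-likelihood improves by < 1e-6 (max 30 sweeps, warning on
non-convergence). Coordinate descent is slow but robust for the ~60-site,
~30-taxon problems this package targets (seconds to a couple of minutes on
one core).

**Marginal posteriors.** Empirical-Bayes per-site state posteriors at a
named internal node combine inside (pruning) and outside vectors per rate
category; summing the per-category joints and normalizing per site weights
the categories by their site-specific posterior mass. Posteriors are
computed on the rooted tree as given — relabeling the root moves the
question, not the math.

**ML, AltAll, and diagnostics.** The ML sequence takes the argmax state per
site, ties broken alphabetically and reported. A site is *ambiguously
reconstructed* when any non-ML state has posterior strictly > 0.20 (the
threshold is configurable); the AltAll sequence substitutes the second-best
state at *all* such sites simultaneously, giving the far edge of the
plausible-ancestor cloud. Summary statistics: mean posterior of the ML
sequence, and the expected number of wrongly reconstructed sites
`sum_sites (1 - PP_ML)`. A substitution between two ancestors is
*phylogenetically diagnostic* for a clade when every extant member of that
clade carries the derived state at that column (a gap breaks conservation).
Substitution labels follow the lowercase-ancestral/uppercase-derived
convention (`q50K`), with a configurable offset mapping alignment columns to
conventional homeodomain numbering.

## PBM analysis (`pbm`)

**E-scores.** For each k-mer (k = 8 by default), probes containing the k-mer
on either strand are foreground, all others background. The score is a
truncated Wilcoxon–Mann–Whitney statistic: the most-enriched half of each
set (ceil(n/2)) is compared and the pair-count rescaled to [-0.5, +0.5].
+0.5 means every selected foreground probe outranks every selected
background probe. Scores are rank-based, hence invariant to strictly
monotone intensity transforms, and a k-mer and its reverse complement are
collapsed to one canonical record (lexicographic minimum). An untruncated
variant is available (`truncated=False`); intensity ties are resolved by
stable probe order, which is itself monotone-invariant. 6-mer scores are
the arithmetic mean over all scored 8-mers containing the 6-mer on either
strand (containment counted once per 8-mer).

**Clustering and logos.** 8-mers reaching E >= 0.45 in at least one
construct are clustered with Manhattan distance and complete linkage.
Per-cluster logos are weighted position-frequency matrices: members align
to a seed by best shift/strand match (shift range ±3). With a random probe
library, "hitchhiker" 8-mers — k-mers that co-occur on a few strong probes
without themselves binding — tie with genuine binders at E = 0.5 and would
dilute an unweighted logo. Genuine binders are distinguished by their
8-mer *median* intensity, so logo weights are the library-normalized median
intensity minus one (clipped at ~0), and the seed is the strongest member
containing the cluster's modal hexamer. On a de Bruijn-complete array this
weighting would be nearly inert; on sparse random libraries it is what makes
the logos readable.

**Energy model.** Binding is additive over motif positions: window energy
`E_j = sum_i eps[i, base_j+i]` in RT units, occupancy
`1/(1 + exp(E_j - mu))`, both strands, all windows; predicted intensity is
`background + beta * sum_j occupancy_j`. `mu` is a chemical potential
absorbing protein concentration; adding a constant to one position's
energies and shifting `mu` is a gauge transformation, so reported models are
mean-centered per position with the shift absorbed into `mu`. Fitting is
nonlinear least squares over `(background, log beta, mu, eps)` with a small
quadratic penalty on position means to pin the gauge during optimization
(the penalty vanishes at the reported, exactly centered solution). Energy
logos plot the centered energies (RT units): letter height is the absolute
value, sign gives above/below-axis placement. Model quality is summarized
as the R² between predicted and observed 8-mer median intensities on a
held-out replicate; both sides are median-normalized first so a
replicate-wide scale difference (routine between arrays) is not scored as
sequence-level error. The matching reproducibility ceiling
(`replicate_r2`) uses one replicate's medians to predict the other's.

## Binding fits (`binding`)

**Equilibrium.** Bound fraction versus total protein at fixed labeled-DNA
concentration follows the quadratic (ligand-depletion) isotherm
`F = b0 + (bM - b0) * [D + P + 1/KA - sqrt((D + P + 1/KA)^2 - 4 P D)]/(2 D)`
(molar units; `KA` in M^-1, `Kd = 1/KA`). The discriminant is floored at 0
against round-off near stoichiometric binding. As `D -> 0` this reduces to
the Langmuir form `F = b0 + (bM - b0) P/(P + Kd)` (verified numerically).
`KA` is fit on a log10 scale (clipped to [1e-6, 1e20] M^-1) to preserve
positivity and conditioning; `b0`/`bM` start from the data extremes and
`Kd` from the half-maximum crossing. Standard errors come from the Jacobian;
the 95% CI for `KA` is built on the log10 scale. If the fitted curve's
observed points never leave the baseline (or never leave saturation), the
fit is flagged "poorly constrained KA". Replicates can be fit independently
with mean ± SEM reporting, or pooled.

**Kinetics.** The association phase of a 1:1 interaction is
`R(t) = kon c0 Rmax/(kon c0 + koff) * [1 - exp(-(kon c0 + koff) t)]
+ R_RI + cD t` (RU; `R_RI` a refractive-index offset, `cD` baseline drift).
The global fit shares `kon`, `koff`, `Rmax` and drift across concentrations
with a per-curve `R_RI`; rates are parameterized as log10. Initialization is
a two-stage kobs linearization: each curve is fit to a simple exponential
approach, then `kobs = kon c0 + koff` is regressed on `c0`. The dissociation
phase — whose functional form is the standard single-exponential companion
of the 1:1 model, with optional linear drift — yields an independent `koff`;
a non-decaying signal is an error, not a fit. Derived quantities:
`KD = koff/kon`, residence time `tau = 1/koff` (seconds).

**Preference comparison.** Per protein, motif preference is
`KA(BM)/KA(ZM)`; the evolutionary shift is `preference(B)/preference(A)`.
Kinetic fits contribute `1/KD`; mixing equilibrium and kinetic affinities
is refused unless explicitly allowed, because the two assays sit on
different absolute scales. With four kinetic fits, off-rate/residence
ratios per motif are also reported.

## Synthetic data (`simulate`)

All generators draw from seeded PCG64 generators; identical seeds give
bit-identical output. Forward models call the same evaluation code the
fitters use (`eval_isotherm`, `eval_association`, `EnergyModel.predict`),
so simulator and fitter cannot drift apart.

- **Alignments** evolve down a given tree under LG + discrete gamma: root
  from the stationary distribution, one rate category per site, transitions
  via `P(t r)`; true internal sequences are recorded. The bundled two-clade
  tree (`demo_tree`) emulates a gene-duplication history: a slowly evolving
  Zen-like clade and a Bcd-like clade behind a long stem branch
  (0.4 subst/site), with the pre- and post-duplication ancestors labeled
  AncZB and AncBcd. It is a synthetic stand-in, not the curated alignment.
- **PBM libraries** are uniform-random 36-mers (default 8,000 probes, two
  replicates), intensity `background + beta * occupancy * exp(eta)`,
  `eta ~ N(0, 0.2)` — multiplicative log-normal noise because intensities
  are positive and ratio-scaled — plus an optional replicate-wide scale
  factor (default 0.6) emulating unequal array signal. The two demo
  "proteins" prefer TAATTA (Zen motif) and TAATCC (Bicoid motif) with a
  4 RT consensus depth; `mu` sits ~2 RT below the best windows so strong
  probes partially saturate, which is both realistic and what makes
  `mu`/`beta` separately identifiable. Not emulated: de Bruijn coverage,
  spatial artifacts, scanner saturation, the normalization stack. Passing
  tests therefore demonstrate correctness of the statistics, not robustness
  to array artifacts.
- **Titrations** add Gaussian noise to the quadratic isotherm. The demo
  scenario fixes `D = 2.5 nM`, `b0 = 0.02`, `bM = 0.95`, and affinities
  (M^-1) A/BM 1e7, A/ZM 2.5e8, B/BM 2.5e8, B/ZM 2.5e7 — a 25-fold BM gain
  and 10-fold ZM loss, hence a planted 250-fold preference shift. Each
  condition is measured in triplicate on a 20-point design (12 points
  log-spaced over 0.1 nM–10 uM plus 8 points bracketing the expected
  transition within one decade of Kd) at bound-fraction noise
  sigma = 0.005. This design was chosen so the demo's reported shift is
  within 5% of 250 in >99% of seeded realizations (verified over 120
  seeds); a sparser/noisier design leaves the four-ratio product too
  variable to quote at that precision.
- **Sensorgrams** follow the association model exactly, continue the
  dissociation exponentially from the association endpoint with a
  continuous drift term, and add Gaussian RU noise (default 0.5 RU).

## Numerical details and degenerate inputs

- Zero branch lengths, gap-only columns, and single-category gamma are all
  exact special cases, covered by tests.
- Likelihood underflow is handled by per-node log rescaling; posteriors are
  normalized per site after mixing categories.
- E-score foregrounds with empty backgrounds (k-mer in every probe) are
  omitted with a warning; k-mers absent from the library simply have no
  record.
- `least_squares` non-convergence warns and returns the best-found point;
  flat (zero-variance) correlation input and non-decaying dissociation
  signals raise instead of returning nonsense.
- Problem sizes used throughout (60-site/33-taxon reconstructions,
  8,000-probe libraries, 100-replicate fit studies) keep any single check
  within a couple of minutes on one core.

## Known limitations

- Joint (as opposed to marginal) ancestral reconstruction, topology search,
  and branch supports are out of scope; the tree is an input.
- The energy model is strictly additive (no dinucleotide terms) and uses
  uniform positional window weights by default.
- The kinetic model is pure 1:1 Langmuir; mass-transport limitation and
  heterogeneous-surface models are not implemented.
- The E-score truncation convention (top halves, ceil, stable-order ties)
  is one defensible reading of the rank-based scheme; the untruncated
  switch exists because published implementations differ in detail.
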