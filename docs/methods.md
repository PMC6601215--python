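# Methods

This note documents the statistical models and procedures behind `diaq`,
the assumptions they make, the defaults and why they were chosen, and what
the synthetic-data tests do and do not demonstrate about real data.

## The data model

The central object is a precursor × sample intensity matrix
(`QuantMatrix`) with an explicit missing mask. Intensities are MS2-level
areas in arbitrary linear units; a precursor is one peptide sequence at
one charge state; a protein group is kept as the verbatim
semicolon-joined accession string, never re-mapped. Zero intensities are
converted to missing at ingest: under detection-limit semantics a stored
zero carries no quantity information, and keeping it would corrupt CVs,
fold changes and imputation minima. The entry count of a matrix is always
rows × columns — missing entries are entries — which is what makes the
missingness identities below pure arithmetic.

## Dilution benchmarking

CVs are computed per replicate group on raw linear intensities as
SD/mean, using the n−1 sample standard deviation (the convention of
common statistical software; with triplicates the small-sample bias of
the SD estimator pulls the expected CV to ≈0.89σ/μ, which is why a
simulation at a 10% CV target yields empirical medians near 8.5% — both
values sit comfortably inside the acceptance band [0.07, 0.13]).
Precursors observed fewer than twice in a group are excluded rather than
imputed: benchmarking is defined on intensities "as reported". Fold
changes between loads average observed replicates on the linear scale and
then take log2, matching the definition of a fold change of *average*
intensities; the alternative (log before averaging) differs only at
second order for CVs ≤ 20%.

The peptide-mass extrapolation is proportional scaling: with R μg of
peptide recovered from C₀ sorted cells and an injectable fraction v/V
(resuspension volume V, injection volume v), the on-column mass for C
cells is 1000·R·(v/V)·(C/C₀) ng. Defaults R = 3.2 μg, C₀ = 200,000,
v/V = 8/11 ≈ 73%.

## Processing chain

Stage order is fixed: Q-value filter → design-consistency filter →
minimum-peptide filter → imputation → TIC normalization. "Present" in
the consistency filter means a non-missing entry *after* Q-value
filtering, because the Q-value filter runs first. Distinct peptides are
counted by sequence with charge states collapsed — the conservative
reading of "a single peptide". Imputation draws uniformly on
[0.7·m, 0.9·m] of each precursor's observed minimum m; uniform is the
minimal assumption for "random values in the range", and the generator
is seeded so runs are reproducible. TIC normalization computes
factor_s = mean_j(T_j)/T_s from the complete (post-imputation) matrix;
afterwards every column sum equals the pre-normalization grand mean, and
the operation is idempotent. An `observed_only` flag allows normalizing
an unimputed matrix when imputation is undesirable.

The missingness report (entries, missing count and fraction, precursors =
entries/samples, average missing per precursor = missing/precursors) is
computed for the matrix as it enters imputation, i.e. after all three
filters. `missingness_from_counts` exposes the same identities directly
from counts, since they are arithmetic facts about any reported matrix
dimensions.

## Differential analysis

The protein-level test is a deliberately transparent surrogate for
Bayesian peptide-selection models: it keeps their two documented
knobs — an SD factor of 2 and a median intra-protein correlation cutoff
of 0.2 — with fully specified semantics.

1. Charge states of a peptide are collapsed by summing linear
   intensities; analysis proceeds on log2 peptide intensities.
2. Winsorization clips each peptide's values at its own mean ± 2 SD
   across samples (the SD-factor interpretation; an alternative reading
   as a variance prior is not modelled).
3. A peptide is retained when the median of its Pearson correlations with
   the protein's other peptides is ≥ 0.2; if fewer than two survive, the
   two best-correlated peptides are kept, so every protein with ≥2
   peptides remains testable.
4. The contrast is one-vs-rest and donor-paired: within each donor, the
   peptide-level difference is the target cell type minus the unweighted
   mean of the other cell types. Pairing within donor removes the
   protein-specific donor effect exactly, which is what makes five
   unrelated donors sufficient. The protein log2FC is the median of these
   differences over selected peptides and donors; per-donor protein
   values (median over peptides) feed a two-sided one-sample t-test
   against zero, with a seeded sign-flip permutation option for smaller
   designs. BH-FDR is applied per contrast; significance requires
   FDR < 0.01 and |log2FC| > 0.5.

Medians over peptides and donors make the estimate robust to a single
aberrant peptide at the cost of a small efficiency loss; with 5 donors
and CV 10% the median bias of recovered +1 log2 spikes, pooled over 20
simulation seeds, is ≈ −0.02 (TIC normalization transfers a small share
of any asymmetric regulation into all proteins of the affected samples;
this is a property of total-signal normalization itself, visible in the
simulations because their protein abundances are heavy-tailed).

On/off calling uses the pre-imputation mask only: a protein is detected
in a sample when ≥1 of its precursors is observed; a cell type is "on"
when detected in all donors, "off" when detected in none, otherwise
ambiguous; candidates have at least one "on" and one "off" cell type.
Imputed values must never enter this call — imputation at the detection
limit would turn every "off" into a weak quantity.

## Preranked GSEA

The enrichment score is the signed extreme of the weighted
Kolmogorov–Smirnov running sum: hits increment by |r|^p/Σ|r|^p (weight
p = 1, the weighted default), misses decrement by 1/(N−N_hits). A set
covering the whole list has no misses; its ES is defined as 1 via the
hit-only walk. The null permutes gene labels — the only option for
preranked input, since per-sample data are unavailable — with one shared
set of seeded permutations across sets. NES divides ES by the mean |null
ES| of matching sign; the nominal p uses an add-one correction (so
p ≥ 1/(n_perm+1)); the FDR q compares the sign-matched pooled null NES
tail with the observed NES tail, clipped to [0,1]. Sets smaller than 5
genes after intersection with the ranked list are dropped. Two ranking
criteria are provided: log2FC, and log2FC × (−log10 adjusted p); ties
break deterministically by gene symbol. Protein groups with multiple
members are excluded before ranking — only unambiguous single-protein
entries map to gene symbols.

## Concordance

The two differential layers join on gene symbol (a protein group mapping
to several genes is dropped and counted). R² is the squared Pearson
correlation of the two log2FC vectors; it is symmetric under sign flips
by construction, so systematic anti-regulation must be read from the
discordance classification, not from R². Categories use strict
thresholds: "below 0.01" means <, and FDR exactly 0.01 is not
significant. Sign discordance is defined only within the "both" category.
The exported network seed list is the protein-up/mRNA-down subset.

## Synthetic-data generator

The generator emulates, with a single seed determining everything:

* log2 protein baselines ~ N(14, 2) (arbitrary MS2-area units, matching
  the heavy-tailed dynamic range of real proteomes);
* peptides per protein ~ 1 + Poisson(mean−1) (default mean 3), each with
  a log2 ionization-efficiency offset ~ N(0, 1), a hydrophobicity score
  ~ U(0,1), and a 15% chance of a second charge state;
* cell-type effects: a configurable fraction of proteins get ±effect_size
  (default 1.0 log2) in one uniformly chosen cell type; a separate
  fraction is "on/off", i.e. entirely absent (−∞ sentinel) in one cell
  type;
* donor effects ~ N(0, 0.25 log2) per protein × donor, shared across the
  donor's cell types (hence removed by the paired contrast);
* technical noise: additive Gaussian on log2 with
  σ = √ln(1+CV²)/ln 2, the exact log-normal identity for a target
  linear-scale CV (default 0.10, the regime of triplicate injections of
  a few hundred ng);
* detection-limit censoring: linear intensities below the threshold are
  missing; missingness has no missing-at-random component by design —
  the pipeline's imputation-at-the-minimum strategy presumes left
  censoring;
* dilution series: expected intensity scales with load relative to the
  top load, times a retained fraction r = exp(−k·h·(L₀/L − 1)) that
  decays with hydrophobicity h and decreasing load. This law is our
  construction (smooth, no loss at the reference load, faster-than-linear
  drop for hydrophobic peptides); no quantitative form is claimed beyond
  those qualitative properties;
* Q-values for observed entries ~ U(0, 0.01) (all pass) with an optional
  failing fraction ~ U(0.011, 0.2) to exercise the filter;
* the mRNA layer: per gene and cell type, the true protein one-vs-rest
  effect plus N(0, 0.2) noise, with small adjusted p for genes with a
  real effect; a configurable fraction of *differential* genes get a
  sign-flipped mRNA effect in their target cell type. Only genes with a
  real protein effect are eligible for flipping, because a flip of a null
  effect would be invisible to any downstream analysis.

What passing tests show: the pipeline's operations implement their
stated rules exactly (oracle equivalence), the estimators recover known
effects without material bias at the configured noise level, and the
tests' nominal error rates are calibrated. What they do not show:
robustness to interference-driven intensity errors, retention-time drift,
batch effects, missing-at-random dropouts, or library-dependent
identification differences — none of which the generator emulates.

## Numerical and design choices

* All logs are base 2 downstream of the linear intensity scale.
* BH correction via `statsmodels`; t-tests via `scipy.stats`.
* Proteins with zero variance in the contrast give p = 1 (not NaN).
* Degenerate inputs fail loudly: all-missing rows cannot be imputed,
  zero-sum columns cannot be normalized, single-load dilution series and
  empty designs are rejected.
* Simulation sizes in the tests and drivers (150–1,000 proteins, 20
  samples) are chosen so the whole suite runs in well under a minute per
  heavy test while leaving binomial bounds tight enough to detect real
  miscalibration; they are not estimates of real study sizes, where
  matrices are ~20–40× larger but all operations scale linearly or
  n log n.

## Known limitations

* The differential surrogate is not a reimplementation of any published
  Bayesian model; numerical agreement with such tools on real data is
  not claimed.
* TIC normalization assumes globally balanced regulation; strongly
  asymmetric regulation biases fold changes toward zero in the affected
  contrast (quantified above).
* GSEA FDR with few sets (<10) is noisy, as the pooled null is thin;
  nominal p-values are calibrated regardless.
* The on/off caller's default ("all donors" vs "no donor") is strict;
  real analyses may prefer relaxing `on_min_donors` by one to tolerate a
  single failed run.
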