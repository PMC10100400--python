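# Methods

## Scope and data model

`orbimet` analyses OrbiSIMS depth-profile peak lists: per acquisition site,
a single negative-mode spectrum (m/z 75–1125) formed by summing the scans
of a sputter–analyse cycle. Samples are organised as patients ×
histological regions (necrotic, viable, non_cancerous) × sites, and the
scientific questions are (i) which ions discriminate two regions and (ii)
which ions are present at equal abundance across them, and into which
metabolic pathways those ubiquitous ions fall.

## Preprocessing chain

The chain runs in a fixed order, recorded in the matrix's transform log:

1. **Peak selection** — keep peaks with intensity ≥ `threshold_fraction`
   (default 0.001) × base-peak intensity, per spectrum.
2. **Alignment** (`window_ppm`, default 5) — all retained peaks are pooled,
   sorted by m/z and swept once left-to-right; a peak joins the current
   cluster while its ppm distance to the cluster's running
   intensity-weighted centroid is within the window, otherwise it opens a
   new cluster. The sweep is deterministic and O(n log n). Multiple
   within-window peaks from one sample are *summed* (configurable design
   point; maximum would also be defensible). A sample absent from a
   cluster is recorded as missing — explicitly distinct from a measured
   zero, and written as an empty field in every tabular export.
3. **Missingness filter** (`max_missing_fraction`, default 0.20) — features
   missing in strictly more than 20% of samples are dropped.
4. **knn imputation** (`k`, default 5) — a missing cell is replaced by the
   mean of the k nearest samples' observed values for that feature.
   Distance between samples is the root-mean-square difference of
   per-feature standardized values over jointly observed features
   (standardization makes features commensurate; the RMS form keeps
   distances comparable across varying overlap). Ties break by sample
   order; when a feature has fewer than k observing donors, all donors are
   used. Row (sample) neighbours, not feature neighbours: replicate sites
   of the same region are the natural donors.
5. **Background removal** — an optional user-supplied m/z blacklist with a
   ppm tolerance; empty by default since no canonical background list
   exists for tissue work.
6. **TIC normalization** — each sample divided by its total ion count;
   rows sum to 1 afterwards. Idempotent.
7. **Pareto scaling** — per feature, (x − mean)/√sd with the n−1
   denominator; a column of pre-scaling standard deviation s ends with
   variance s. Constant columns are set to zero with a warning rather than
   dropped (feature indices stay aligned with annotation). Re-applying
   Pareto scaling is refused via the transform log, since the composition
   is not idempotent.

Univariate statistics run on the TIC-normalized (not Pareto-scaled)
matrix; the chemometric engine consumes the TIC matrix and applies
centring + Pareto internally so cross-validation can refit the scaling
statistics per fold.

## Chemometrics

**PCA** is the SVD of the column-centred matrix. Q² uses 7-fold
venetian-blind row exclusion: each fold's rows are reconstructed from the
loadings of a model fitted to the remaining rows and Q² = 1 − PRESS/SS.
Row-exclusion reconstruction is mildly optimistic compared with
element-wise schemes; it is used because it is simple, deterministic and
adequate for the qualitative role PCA plays here.

**OPLS-DA** is the orthogonal-signal-correction scheme with one predictive
component: the PLS weight w = Xᵀy/‖Xᵀy‖ is computed from the centred ±1
class dummy; each orthogonal component removes the part of the loading
orthogonal to w (w_o ∝ p − (wᵀp)w) and deflates X; the predictive
component is fitted on the filtered X. One orthogonal component is the
default (selectable 0–3). The predictive scores are orthogonal to every
orthogonal score vector to machine precision by construction.

**Q²** is leave-one-out: each held-out sample is predicted by a model
refit without it, *including* the centring/Pareto statistics, and
Q² = 1 − PRESS/SSY. Leave-one-out is exact for the small per-contrast
sample sizes this design produces (tens of samples); no venetian-blind
approximation is needed.

**VIP** over the single predictive component reduces to √J·|w_j|/‖w‖, so
mean-square VIP is identically 1 and the VIP ≥ 1 threshold selects
features contributing more than the average.

**S-plot** coordinates are cov(t, x_j) and corr(t, x_j) against the
predictive scores, computed on the centred/scaled matrix before orthogonal
deflation (n−1 denominators). Zero-variance features report correlation 0
with a warning.

**Permutation test** — the cross-validated Q² is recomputed under
`n_permutations` (default 999) random relabelings and the add-one
empirical p-value (1 + #{Q²_perm ≥ Q²_obs})/(n_permutations + 1) is
reported. The permutation stream is seeded and reproducible.

**Feature predicates** — discriminative: VIP ≥ 1 and Benjamini–Hochberg
q < 0.05 (the FDR correction applies to the p < 0.05 criterion);
ubiquitous: VIP ≥ 1 and raw p > 0.05. The ubiquitous rule is surprising on
its face (a high-VIP yet non-significant feature); it is implemented as
stated, with `predicate="low_vip"` offering the alternative reading
(VIP < 1 and p > 0.05) without guessing intent. Student's t is
pooled-variance by default (Welch behind a flag); patient is not modelled
as a random effect, a known limitation with N patients contributing n
sites each.

## Mass and annotation conventions

Monoisotopic masses are sums of most-abundant-isotope masses (IUPAC,
hard-coded to 7 decimals). Deprotonation subtracts the proton mass
1.0072765 Da — not a hydrogen atom — because the anion retains its
electron; this convention reproduces measured deprotonated-ion m/z on
Orbitrap instruments to four decimals. Adducts: [M−H]⁻ (−1.007276 Da) and
[M−H₂O−H]⁻ (−19.017841 Da). Annotation reports *all* (compound, adduct)
pairs within the ppm tolerance (default 5), sorted by |ppm error|, because
accurate mass alone cannot arbitrate between isobars (level-3
identification). Pathway mapping converts observed m/z back to neutral
mass via the matched adduct and matches against pathway-member
monoisotopic masses at 2 ppm; coverage is the matched fraction of the
member list. The bundled library holds ~230 metabolite formulae (masses
recomputed from formulae at load) and four pathway tables (tryptophan,
arginine/proline, tyrosine, histidine metabolism).

## Synthetic cohorts

The generator draws library compounds, assigns each one adduct and one
theoretical m/z (mutually separated by ≥ 25 ppm so 5-ppm alignment cannot
merge distinct compounds), and models log-intensity as

    log I = baseline(compound) + patient effect + region effect + noise,

with `noise ~ N(0, σ)`, σ = √log(1 + cv²) from the configured intensity CV
(default 0.4), and a patient random effect (default SD 0.15, exposed
because the within/between-site variance ratio of the emulated design is
not known). Region effects are parameterised in Cohen's-d units of the
total within-group log-SD, so `effect_size` is directly the standardized
group-mean difference the statistics should recover; each spiked compound
receives ±d/2 on the two arms of its contrast, with
`n_discriminative_compounds` spikes per region pair. Observed m/z are
jittered multiplicatively with Gaussian ppm noise (default SD 1 ppm).

Compound baselines are log-uniform over `baseline_range`, default
(1e5, 1e6) counts — one decade. Two considerations fix this default:
spiked ground truth must concern compounds that are detected and
quantifiable at every site (an effect spiked onto a peak at the selection
threshold is censored by the generator's own pipeline, which would make
the emitted truth table wrong); and under Pareto scaling a feature's VIP
scales like corr × √sd, so ground-truth effects on compounds orders of
magnitude below the matrix's intensity scale are unrecoverable by design
of the scaling, not by failure of the model. A wider range is available
for stress-testing via the config field.

Missingness is detection-limited by default: cell-wise censoring
probability follows a logistic weight in the global log-intensity z-score,
rescaled so the marginal rate equals `missing_rate` (default 0.10);
`missing_mechanism="random"` gives completely-at-random censoring for
testing imputation under both regimes. The generator emits each site's
spectrum directly at summed-scan scale (`n_scans` is design metadata);
`sum_scans` is provided and tested as a standalone operation for callers
who hold per-scan peak lists.

What the generator does *not* emulate: sputtering physics, matrix effects,
detector dead-time, isotope envelopes, correlated (co-regulated) compound
intensities, and real SIMS background/contamination peaks. Passing tests
therefore demonstrate that the statistical machinery recovers known
structure under the stated noise model — not that the pipeline is robust
to every artefact of real spectra.

## Problem sizes and numerical choices

The validation suite and the acceptance script use the emulated study
scale: 4 patients × 2 regions × 5 sites (40 samples), 200 compounds with
20 spiked at d = 2, which preprocesses to ~190 features. At this scale the
full leave-one-out OPLS-DA fit takes well under a second; permutation
tests in tests use 19–99 permutations while the pipeline default is 999.
Ties in knn and alignment break deterministically (sample order; sweep
order). Degenerate inputs: empty spectra, zero-total samples, all-missing
columns, single-class labels and out-of-range parameters raise typed
errors naming the offending object; constant features degrade gracefully
(zeroed under scaling, p = 1 under testing, correlation 0 in the S-plot).

Model quality numbers printed by the examples (Q² ≈ 0.84, permutation
p = 0.01 at 99 permutations, 19/20 spiked features at VIP ≥ 1) are
computed live by `examples/01_simulate_and_model.py` and re-derived from
scratch by `scripts/acceptance.py`.
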