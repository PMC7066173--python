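# Methods

This note documents the models and procedures nephrokit implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Mutational-signature refitting

A sample's catalog is a vector of substitution counts over the 96
trinucleotide-context channels (pyrimidine-strand convention, COSMIC
ordering: C>A, C>G, C>T, T>A, T>C, T>G, contexts alphabetical within each
class). Reference signatures are column-stochastic 96-vectors. Exposures
are estimated by non-negative least squares (`scipy.optimize.nnls`), which
is deterministic and exact for this convex problem.

Greedy forward selection encodes the assumption that the clock-like
signatures SBS1 and SBS5 are present in every sample: the forced pair is
refit first and the target check (reconstruction-to-catalog cosine ≥
`cos_target`, default 0.9) is applied after every refit *including* the
forced one — a profile already well explained by the clock signatures gets
no extras. Each round refits every unselected candidate jointly with the
current selection and takes the candidate with the highest cosine; if even
the best gain is below `min_gain` (default 0.01, strict `<`) the candidate
is **not** added and selection stops. Ties (|Δcosine| ≤ 1e−12) resolve to
the earlier column in the reference set, making selection fully
deterministic. SBS40 is excluded from the reference at load time by a
config-level exclusion list (default `["SBS40"]`) because it is too close
to SBS5 to be distinguishable in small cohorts. Exposures are reported on
the mutation-count scale together with normalized fractions.

Degenerate inputs: an all-zero catalog is flagged per sample in cohort
tables (`stop_reason = empty_profile`) and never fitted; an NNLS solution
that is identically zero (catalog orthogonal to all selected signatures)
scores cosine 0 rather than raising.

### Attainability of recovery and the generator's signature shapes

With the 0.9 target checked after the forced refit, recovering a third
signature from a mixture is only possible when its admixture genuinely
drags the two-signature fit below 0.9. That is a geometric constraint: for
near-orthogonal columns the residual L2 fraction of a weight-w admixture is
roughly w·‖c‖/‖catalog‖, so equal-norm signatures can never produce it at
w ≈ 0.15–0.2 (the fit cosine would stay ≥ 0.97). Real references have the
required norm structure — SBS5 is nearly flat (low L2 norm), most other
processes are strongly peaked (high L2 norm) — and `gen_signature_set`
reproduces it: SBS1 moderately peaked (gamma(1) base, 4 channels boosted
4–10×), SBS5 flat (gamma(5)), other signatures sparse with 4 channels
boosted 200–600× carrying most of the mass. The whole set is redrawn until
all pairwise cosines fall below `max_cosine` (default 0.9, the generated-set
contract). Recovery benchmarks draw sets at `max_cosine = 0.5`, the
analogue of a curated reference without near-duplicates — the same reason
the real analysis excludes SBS40. Under those conditions the three-signature
generating set (weights ≥ 0.15, 10,000 mutations noiseless / 3,000 with
Poisson noise) is recovered in 100/100 and ≥ 95/100 seeded runs
respectively.

## Single-cell QC and cycle-gene exclusion

Order of operations: mitochondrial fraction is computed on the full matrix,
mitochondrial genes are then removed, and per-cell transcript totals are
taken on the mito-free matrix. Cells fail on mito fraction strictly above
0.40 ("exceeding") or totals strictly below 1000 ("less than"); both rules
are evaluated independently and reported. "Unique transcripts" is read as
the summed UMI-deduplicated counts per cell — plate-based Sort-seq counts
are UMI-collapsed — not as genes detected. Genes are kept only with ≥ 5
expressing cells and ≥ 2 cells at ≥ 2 transcripts, evaluated after cell
filtering. Normalization is x̂ = ln(1 + 10000·x/total), natural log,
matching the lognormalize semantics of the single-cell ecosystem.

Module scores (S, G2M) are the mean normalized expression of a marker set
minus the mean of control genes sampled per marker from its
average-expression bin: 24 rank-based bins over all genes, 100 controls per
marker drawn without replacement within the bin, seeded. Rank-based binning
keeps bins near-equal-sized regardless of the expression distribution.
Every gene is then Pearson-correlated with both scores (constant genes get
r = 0 and a flag), and the cutoffs are computed exactly as

    s_cut   = max( Med(S_S)   − Med(S_G2M),  Q25(S_S) )
    g2m_cut = max( Med(G2M_G2M) − Med(G2M_S), Q25(G2M_G2M) )

where S_S are the correlations of the known S-phase genes with the S score,
and so on. Quantiles use linear (type-7) interpolation — the default of the
R/numpy ecosystem — and the convention is config-switchable because it
changes the cutoff (the worked example set {0.5, 0.6, 0.7, 0.8} has Q25 =
0.575 under type-7 but 0.55 under type-6). Genes are flagged when a
correlation strictly exceeds its cutoff; known markers are flagged
unconditionally. Variable-gene blacklist profiles: `fig3` removes
mitochondrial pseudogenes, cycle genes and RP-prefixed symbols;
`early_late` additionally removes heat-shock (GO:0006986) and cytosolic
ribosome (GO:0022626) lists — supplied as plain-text files, no ontology
download — chromosome-Y genes, and XIST/TSIX.

Open points resolved here: mito fraction before vs after mito-gene removal
is not derivable from the study's wording (fraction-of-total was chosen,
with downstream totals on the mito-free matrix); correlations are computed
on post-QC cells; "correlated" is taken as Pearson on log-normalized
values, the ecosystem default.

## Marker detection and cell typing

Each cluster is compared against all other cells of the same organoid;
clusters spanning organoids are handled within each organoid separately.
Fold change is computed on de-logged means, (mean(exp(x̂)−1)_in + ε) /
(mean_out + ε) with ε = 1e−9, and a gene is tested only when fold ≥ 1.8 or
≤ 1/1.8 — both directions are kept, with the direction recorded, since both
enriched and depleted markers are reported. P-values are two-sided Wilcoxon
rank-sum: exact enumeration of all rank-subset assignments when both groups
have ≤ 8 cells (mid-ranks, so ties are exact; two-sided p = min(1,
2·min(P(W≤w), P(W≥w)))), otherwise the tie-corrected normal approximation
(`scipy.stats.mannwhitneyu`). Bonferroni uses m = the total number of genes
in the matrix, the denominator the ecosystem's marker functions use; the
number of genes actually passing the fold pre-filter is emitted per
comparison (`n_tested`) so the alternative denominator is auditable. The
all-genes denominator is also what keeps the procedure calibrated: the fold
pre-filter selects noise-extreme genes, so correcting only over tested
genes inflates the null significant fraction well above α.

Cell typing computes Spearman correlations (Pearson on mid-ranks) between
each cell and each reference column over their shared genes (≥ 10
required; rank-robustness matters because the reference may come from a
different platform, e.g. microarray). Each cell takes the argmax label and
each cluster the modal label of its cells; all ties resolve alphabetically.

## Somatic-variant filtering

All rules are evaluated for every record (failures accumulate; nothing
short-circuits), and all threshold comparisons are inclusive (≥) on the
stated values since they are phrased as required quality levels. "Evidence
in the normal" is quantified as ≥ 1 alt-supporting read (configurable) or a
non-reference normal genotype — the strictest reading. Coverage means
tumour depth; an optional normal-depth mirror rule exists but is off by
default. dbSNP membership is consumed as the record's DB flag; no database
is downloaded. The indel-proximity rule fails indels within 100 bp
(|Δpos| ≤ 100, 1-based, same contig) of any control-called variant.
Contig names are normalized (with/without "chr"); anything outside 1–22
fails the autosome rule. Signature-grade filtering applies only to
substitutions with matched normals (others are excluded, not failed
silently) and requires GQ ≥ 10 in the normal and ≥ 99 in the tumour. The
driver report keeps missense, start-loss, stop-gain, in-frame
insertion/deletion and frameshift records — all genes with a matched
normal, a supplied driver-gene list without one.

## Dose-response analysis

Viability is 100 × reading / mean(DMSO readings) per plate. Technical
replicates (default 4) are averaged per concentration before fitting; the
4PL (variable-slope) family is used because IC50s and fitted curves from
6–9-point viability screens are being reproduced and 4PL is the field
standard for them. The fit is bounded least squares on log10 concentration
(top ∈ [50, 150], bottom ∈ [−10, 60], hill ∈ [0.1, 10], log-IC50 within 2
decades of the tested range) from three fixed starts (log-IC50 at the
range's ends and midpoint), keeping the lowest SSE — deterministic without
a seed. IC50 is "reached" iff the fitted curve attains ≤ 50% viability
within the tested range (judged on the curve, not raw minima, since IC50s
derive from curves); otherwise the highest tested concentration is
reported, flagged. The AUC is the mean fitted viability over the tested
log10-concentration range, computed in closed form (the 4PL has an
elementary antiderivative in log space) and normalized by the range width
so plates with different spans are comparable; compounds are ranked
ascending with name tie-breaks. Group comparisons use the equal-variance
two-tailed Student's t-test (Welch available as an option) on per-line IC50
values, each the mean of one experiment's technical quadruplicates.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of their parameters and seed.

* `gen_catalog` draws channel-wise Poisson counts around S·w (or the exact
  real-valued mixture with `noise="none"`) at 3,000 mutations by default —
  the order of magnitude of the noisy benchmark — emulating WGS catalogs of
  a few thousand substitutions.
* `gen_sc_counts` draws negative-binomial counts (fixed dispersion, size 2 —
  realistic overdispersion without extra knobs) with planted structure:
  per-cluster marker blocks (default 3-fold, the marker-detection benchmark
  condition), known S/G2M marker blocks plus extra cycle-responsive blocks
  not on the marker lists (default 8-fold in their own phase, giving
  planted gene–score correlations around 0.55–0.6), half the cells cycling
  by default (organoid cultures proliferate rapidly), ~5% of cells planted
  high-mito (targeting ~60% mito fraction against a 2–15% baseline) and
  ~5% low-depth (300–700 non-mito transcripts against a log-normal baseline
  centred at ~5,000) — margins wide enough that the 0.40/1000 thresholds
  separate the planted sets exactly. Known marker blocks respond
  heterogeneously (per-gene fold log-uniform between fold^0.25 and fold),
  as canonical marker lists do, which keeps the marker-derived cutoffs
  below the full-strength planted cycle genes; cycle-responsive genes also
  respond at sqrt(fold) in the *other* cycling phase, modelling the shared
  proliferation programme — without it S genes anti-correlate with the G2M
  score and the median-difference term inflates the cutoffs. With
  `marker_fold=1` and `cycle_fold=1` the matrix is exchangeable null data
  for calibration. Not emulated: doublets, ambient RNA, batch effects,
  continuous differentiation trajectories — so passing benchmarks show the
  procedures behave as specified on well-separated structure, not that they
  resolve every real-data pathology.
* `gen_variant_table` constructs records that pass every rule, then one
  group per requested rule violating exactly that rule, 10 kb apart so the
  proximity rule fires only where planted. It does not simulate read-level
  evidence or caller artefacts.
* `gen_plate` evaluates known 4PL curves on six half-log concentrations
  (10 nM–3.16 µM) with four technical replicates and multiplicative
  log-normal noise (mean-one; `cv=0` is exactly noise-free), DMSO wells at
  100% and staurosporine wells near 0.5%. Plate-position (edge) effects are
  not modelled. The IC50-recovery benchmark uses a mid-potency compound
  (IC50 300 nM, hill 1.2) at 5% CV; curves with hill ≈ 1 sit near the
  identifiability limit of a 6-point design at that noise level, which is a
  property of the design, not of the fitter.

## Problem sizes and determinism

Default benchmark sizes: 100 seeded mixtures for signature recovery, 50
random catalogs for trace monotonicity, 200 random sets for cutoff
fidelity, 1,500 genes × 360 cells for single-cell benchmarks, 20 seeds for
variant truth recovery, 50 plates for IC50 recovery. These run in well
under a minute each on one CPU while leaving comfortable statistical
margins. Every stochastic step takes an explicit seed; CLI result tables
and manifests contain no timestamps, so identical invocations are
byte-identical. Sub-seeds are derived via `numpy.random.SeedSequence` and
kept below 2³¹.

## Known limitations

Upstream steps are out of scope by design: read mapping, variant calling,
copy-number estimation, methylation processing, PCA/t-SNE/graph clustering
(cluster labels are an *input* here; the upstream tool settings are
recorded in run manifests only). The exact-enumeration Wilcoxon path is
O(C(n₁+n₂, n₁)) and is therefore capped at groups of 8; the asymptotic path
is accurate from roughly there on but is still an approximation for
moderate groups with heavy ties. Dense count matrices are held in memory,
which is appropriate for plate-based (hundreds-of-cells) data but not for
droplet-scale atlases.
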