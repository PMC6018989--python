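# Methods

This note documents the models, estimators and design choices behind
`phenoscreen`, in the order the pipeline runs them, together with the
assumptions under which each is valid and the limits of what the
synthetic-data tests demonstrate.

## Synthetic screen generator

The generator (`phenoscreen.synthetic`) is first-class, tested code: it
defines the study conditions under which every downstream estimator is
validated.

**Age structure.** Cells are assigned relative ages `a ∈ [0, 1]` from
the steady-state exponential-population density `p(a) = 2 ln2 · 2^−a`,
sampled by inverse CDF `a = −log₂(1 − u/2)`. This is the standing
assumption of all snapshot cell-cycle inference in the package; the
generator never produces non-steady-state populations, so the tests say
nothing about robustness to, e.g., populations leaving exponential
phase.

**Single cells.** Length is exponential elongation
`L = L_birth · 2^a` times a lognormal factor with arithmetic CV
`length_cv` (WT default 0.11, an experimentally motivated value);
width is lognormal around `mean_width`. All lognormals are
parameterized by arithmetic mean and CV (not log-scale parameters)
because the screen's literature reports arithmetic CVs. Outline area
and perimeter, volume and surface area follow the spherocylinder model
(cylinder of length `l − w` with hemispherical caps):
`A = w(l−w) + πw²/4`, `P = 2(l−w) + πw`, `V = πw²(l−w)/4 + πw³/6`,
`SA = πw(l−w) + πw²`. The per-age length distribution of real cells is
not observable in a snapshot; exponential elongation is a documented
modelling choice, not a measurement.

**Cell-cycle states.** Nucleoid separation is a hard age threshold
(`nucleoid_count = 2` for `a ≥ t_nuc`; WT default 0.55). The
constriction degree ramps linearly from 0 at `t_const` (default 0.75)
to 1 at division — the ramp's shape is a convenience; downstream only
the binary "degree above 0.15" matters. Division ratios exist only for
constricting cells and are truncated-normal around 0.5 (σ default
0.03). The nucleoid constriction degree ramps from `t_nuc`, which
makes cell and nucleoid constriction positively coupled, as in real
cells. Defaults (`birth_length` 2.0 µm, `mean_width` 0.9 µm,
`width_cv` 0.04, `nucleoid_area_ratio` 0.55) are plausible WT-like
values for a slow-growth condition and are synthetic, not
measurements.

**Growth curves.** OD600 follows `OD(t) = OD₀ · exp(y(t))` with `y`
the modified Gompertz (below); defaults OD₀ = 0.005, saturating OD
0.7, μ = 0.01/min (α_max = 0.6/h, ~70 min doubling), λ = 120 min,
16 h at 5-min sampling, additive Gaussian observation noise (σ
0.002–0.005, plate-reader scale).

**Screens and planted effects.** WT replicates share one baseline
spec; per-strain cell counts are Normal(291, 116) clipped at 50,
mirroring a realistic post-curation screen. Mutant displacement is
specified in *score units* (WT SDs): the WT replicates are generated
first, summarised, and the per-feature SD taken as iqr/1.35; each
offset is then converted to a raw-feature displacement and planted
through a closed-form inverse map onto a generative parameter (e.g.
mean length shifts `birth_length` by `Δ/(2 ln2)` since
`E[2^a] = 2 ln2`; population length CV inverts
`CV_pop² = (1+CV_age²)(1+cv²) − 1` with `CV_age² = 2/(2 ln2)² − 1`).
Only features with such a map can be planted; requesting others is an
error rather than a silent approximation.

The canonical recovery experiment (`planted_archipelago_truth`) uses
24 WT replicates plus three islands of 12 strains, each displaced by
7 WT-SD on a disjoint feature *pair* (`<L>`/`CV_L`, `<W>`/`CV_DR`,
`rel_T_nuc`/`<NA>`). Two displaced features per island are used
because a strain's phenoprint carries ~1 SD of sampling noise in each
of 26 features, so within-island distances are ≈ √52 score units;
single-feature displacements of the same size sit at the edge of that
noise ball, whereas pairs (amplified by the geometrically coupled
features) give islands that any reasonable embedding separates. The
planted effects remain in the "≥ 6 SD" severe-phenotype class.

**Stage-resolved length mixture.** `simulate_length_mixture` builds the
population length distribution as a weighted sum of lognormals at 100
equidistant ages (weights ∝ 2^−a), with the stage-specific CV applied
above age 0.8 (the constricted stage). CVs are computed from exact
mixture moments; tests verify them against independent numerical
integration of the returned densities. Note the "constricted-stage"
distribution mixes ages 0.8–1.0, so its CV slightly exceeds the
per-age CV (0.117 for 0.11) — the small age-spread contribution is
inherent to the construction, and the masking conclusion (population
CV ratio ≪ stage CV ratio) is unaffected.

**Corruption.** `corrupt_cells` perturbs a random subset into four
implausible regimes (width > length, collapsed contours, intensity
outliers, merged cells). This is a stand-in for real segmentation
failure modes and is deliberately strong; the ≤ 10% cross-validated
error demonstrated on it is an operating-point property, not a claim
about any particular real dataset.

## Growth-curve fitting

The Zwietering modified Gompertz is parameterized on the log-relative
scale, `y(t) = ln(OD/OD₀) = A·exp(−exp((μe/A)(λ−t)+1))`, so that μ is
a specific growth rate (per minute; reported as `alpha_max` in 1/h)
comparable across strains. The *residuals*, however, are evaluated on
the OD scale with OD₀ as a fourth fitted parameter: near the baseline,
plate-reader noise is comparable to the signal and log-scale residuals
would let those points dominate (an ~11% upward bias on μ at noise σ
0.005 in simulation; OD-scale residuals bring the median recovery
error to ~1.4%). Optimisation is bounded trust-region least squares
from 5 data-driven starts (amplitude from max y, μ from the steepest
smoothed slope, λ from the tangent intercept); the best RSS wins.
Curves with `max y < 0.05` are declared non-converged rather than
fitted. `od_max` is the mean OD over the final 60 min.

## Contour curation

A linear SVM (`LinearSVC`, inverse-frequency class weights, C chosen
by internal stratified k-fold CV) over the 16 features, each
median/iqr-normalized — robust normalization consistent with the
scoring stage. Missing division ratios are imputed at 0.5 with an
explicit missingness indicator column, so "no visible constriction" is
itself usable evidence. The linear kernel keeps the decision rule
auditable (weights are serialized to JSON). AUROC is computed by the
Mann–Whitney rank statistic with average-rank tie handling. The
published operating point of such classifiers (≈ 10% CV error, AUROC
0.94) is mirrored as a property on synthetic corrupted data, not as a
number to match — the real training images are not reproducible at
desk scale.

## Phenoprints and scores

The 19 morphological features are means and CVs (sample SD, ddof 1) of
per-cell L, W, A, P, V, SA, S/V, Ar = W/L and C = 4πA/P², plus CV_DR.
The 4π circularity convention (circle = 1) is used throughout.
Because cell-pole identity is unknown, division ratios are augmented
with their complements {r, 1−r} before taking the CV — the mean is
then 0.5 by construction and only the spread is informative. Mean
nucleoid area `<NA>` sums nucleoids within each cell and is counted as
the fifth cell-cycle feature (per-cell nucleoid count is redundant
with `rel_T_nuc`).

Plate bias is corrected by forcing each plate's per-feature median to
the parental (WT) median — multiplicatively for strictly positive
features, additively for signed ones (the correction's "set the
median" prescription does not distinguish shift from scale; the
multiplicative choice preserves CVs of positive features). A
Dirichlet-regression correction of imaging-time biases on class
fractions is *not* implemented: its covariates and link are not
recoverable from the available description, and the synthetic
generator images all strains at one time, so the median-recentring
above is the only correction applied.

Scores are `s = 1.35·(F − median_WT)/iqr_WT` per feature, using only
WT replicate rows (≥ 10 required); features with zero WT iqr are
dropped with a warning. Scores are invariant to affine rescaling of
raw features, hence Pearson correlations between score columns equal
those between the underlying corrected features — the basis for
`phenoscreen.supplementary`, which recomputes screen-wide flag counts
and headline correlations from any score table with canonical column
names. `|s| ≥ 3` defines an extreme phenotype; flags are monotone in
the threshold. Strains with < 30 cells are summarised but flagged
`low_n`.

## Snapshot cell-cycle inference

Under steady state, the fraction of cells older than age `a` is
`2^(1−a) − 1`; inverting gives `T = 1 − log₂(1+p)` for the fraction
`p` past an event (two nucleoids; constriction degree > 0.15). Length
rank maps to age via `age(F) = −ln(1−F/2)/ln2` with average-rank
ties. Both the direct fraction route (default) and the 50%-crossing
of the rank-age event curves are implemented; they agree on synthetic
populations and the fraction route is exact under the generator. Only
population-average relative timings are identifiable from snapshots —
no single-cell timing variability, no absolute durations.

Coupling statistics use constricting cells only: `rhoCD` is the
Pearson correlation of cell versus nucleoid constriction degree, and
`CDN_C0` the mean nucleoid constriction degree in the "onset band",
defined operationally as the lowest decile of strictly positive cell
constriction degrees (the decile width is configurable; no external
definition of "onset" exists). Both are NaN-coded below 10
constricting cells.

## Consensus islands

t-SNE (scikit-learn, perplexity 30 by default, capped at (n−1)/3) is
repeated `n_maps` times with per-map seeds `seed + i`; each map is
clustered with DBSCAN. The co-clustering frequency `f_ij` is the
fraction of maps in which strains i, j share a cluster (exact rational
counts / n_maps); islands are the connected components, of size ≥
minPoints, of the graph with edges `f_ij > 0.9`. The ">90% of maps"
rule is formalized as this pairwise graph because no aggregation rule
is otherwise fixed; raising the threshold only ever refines the
partition. Maps are used as-is (no Procrustes alignment) since only
co-membership is aggregated. `tune_dbscan` picks the ε that maximizes
the island count subject to ≥ 90% of WT replicates sharing one island,
ties to the smaller ε. Stability is assessed by disjoint ~2%
holdouts, re-embedding, per-map DBSCAN, and for each reference island
the largest surviving-member fraction landing in one cluster —
a Jaccard-style index averaged per map.

Tests demonstrate recovery of strongly separated planted islands
(ARI ≥ 0.9 over seeds with tuned ε, 20 maps); they do not establish
sensitivity to subtle, overlapping phenotypes, and island counts on
real data depend on the data and on ε.

## Enrichment

Categorical enrichment: two-tailed hypergeometric p-values by the
doubling rule `p = min(1, 2·min(P[X≤k], P[X≥k]))` (the two-tailed
construction is a convention choice; doubling is the conservative
standard), BH adjustment for COG-style independent vocabularies, BY
for GO-style dependent ones. GO terms are taken as a flat gene→term
table; is_a propagation is out of scope.

Spatial (SAFE-style) enrichment: neighborhood radius = the
1-percentile of all pairwise embedding distances; per node and term, a
one-tailed hypergeometric p for the local annotated count given
neighborhood size and global term frequency; BY across all node×term
tests at α 0.05. Attribute-permutation replicates (default 1,000) are
computed alongside and reported as an empirical p and background mean
— the hypergeometric p drives the significance call, the permutations
calibrate it (type-I rate ≤ α under the null in tests). The procedure
is invariant to rigid motions of the embedding.

## Feature network

Belsley's diagnostic: columns scaled to unit norm (no centering), SVD,
condition indices σ_max/σ_i; a feature is implicated when its
variance-decomposition proportion exceeds 0.5 on any index above 30.
Implicated features are excluded before network inference.

Mutual information: both variables rank-transformed and discretized
into `B = ⌈n^(1/3)⌉` equal-frequency bins (deterministic on ties), plug-in
MI plus Miller–Madow correction `(m_x + m_y − m_xy − 1)/(2n)`, clipped
at 0. The estimator depends only on the copula, hence is invariant to
monotone rescaling, and is validated against the Gaussian closed form
`−½ln(1−ρ²)` (within 0.03 nats at n = 10⁵). The estimator choice is a
documented default (the ARACNE literature leaves it open) and is
pluggable via `n_bins`.

ARACNE: for every triangle, edge (i,j) is removed iff
`MI_ij < min(MI_ik, MI_jk)·(1 − tolerance)` strictly — ties keep the
edge (conservative, order-independent); removals are judged against
the original MI matrix, so the operation is idempotent and
order-invariant, and exact on tree-structured models (skeleton F1 ≥
0.9 in tests). Before DPI, edges must clear an MI significance floor
estimated from a row-permutation null at Bonferroni-corrected level
α/n_pairs (200 permutations): bootstrap replicates share the data's
rows, so a chance-level association would otherwise recur across
replicates and acquire spuriously high support. Bootstrap support =
fraction of 200 strain-resampled replicate networks containing the
edge; edges with support > 0.7 are retained, with MI values from the
full data. The network is undirected; no edge orientation is
attempted.

The pipeline's default candidate set is the 10 screened features
`<L>, <W>, <A>, <NA>, α_max, OD_max, rel_T_nuc, rel_T_const, rhoCD,
CDN_C0`; on synthetic screens with planted joint displacements the
dimension features can themselves become collinear and be excluded —
the Belsley screen is doing its job, not failing.

## Correlation intervals, contours, density

Fisher z: `z = atanh(ρ)` is treated as Normal with SE `1/√(n−3)`; the
CI is `tanh(z ± z_crit/√(n−3))`. Degenerate at |ρ| = 1 (interval
collapses, with a warning). Kendall τ has no such transform; a
percentile bootstrap (default 5,000 resamples, seeded) supplies the
CI.

Probability contours: a binned Gaussian KDE on a 128×128 lattice
(histogram + Gaussian filter, per-axis Scott bandwidth `σ·n^(−1/6)`,
lattice padded by 4 bandwidths so kernel mass stays inside); the
contour level for probability p encloses KDE mass p (densities sorted
descending, cumulative mass). Point coverage of the 0.95 contour is
0.95 ± 0.01 on large Gaussian samples — the criterion any bandwidth
selector must meet; the binned estimator was chosen for O(grid) cost
at n = 10⁵. Polygons are extracted with `skimage.measure.find_contours`.

Local density: neighbor counts (self included) within a radius equal
to the 0.03 *percentile* (quantile 0.0003) of the pairwise-distance
distribution, read literally; the percentile and an explicit radius
are both exposed since the convention is ambiguous in parts of the
literature.

## Pipeline and reproducibility

`run_pipeline` executes inputs → growth fits → features → plate
correction → scores → flags → islands → (enrichment) → network,
writing every table plus a manifest with the config hash and seed.
The master seed fans out to stage seeds by SHA-256 of
`"{seed}:{stage}"`, giving stage-level independence with full
reproducibility; reruns are byte-identical. Problem sizes in the test
suite and acceptance script (20 embedding maps, 50-boot networks,
60-strain screens, 3–5 replicate seeds) are chosen so the whole
validation runs in minutes on one CPU while leaving every statistical
conclusion comfortably inside its tolerance; the full-scale defaults
(100 maps, 200 bootstraps, 1,000 permutations) remain the package
defaults.

## Known limitations

- Segmentation itself is out of scope; the cell table is the input
  contract.
- The generator's cell-cycle states are hard age thresholds; real
  populations show graded, noisy transitions, so event curves on real
  data will be smoother than the step-like synthetic ones.
- Imaging-time/OD bias corrections beyond plate-median recentring are
  not modelled.
- The replication of a published screen's deposited score table
  (counts of extreme strains, headline correlations) requires that
  dataset locally; it is not redistributable with the package.
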