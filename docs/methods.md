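# Methods

## Data model

The unit of data is a probes × samples matrix of beta values — per-CpG
methylated fractions in [0, 1] — with per-sample metadata (twin-pair id,
age in years, sex, batch, replicate links) and per-probe annotation
(position, gene, signed TSS offset with negative = upstream, CpG-island
flag). Missing betas are tolerated on input; any probe with a missing value
is excluded before statistics, since every downstream test assumes complete
rows. This is the simplest defensible rule for a platform where missingness
is rare and not informative.

## Preprocessing

Probes are kept when their mean beta lies strictly between 0.05 and 0.95
and their sample variance is positive; the mean rule is attributed first
when reporting removals. Batch adjustment is parametric empirical-Bayes
ComBat (per-probe standardization; per-batch additive and multiplicative
effects shrunk toward pooled normal / inverse-gamma priors with
moments-matched hyperparameters; back-transformation), delegated to
scanpy's implementation and clipped to [0, 1] afterwards so adjusted betas
remain valid fractions. ComBat runs without covariates: age is deliberately
left out of the design, matching how the adjustment is used ahead of an
age-association analysis that must not have age regressed into it. A batch
with a single sample is an error; a single batch is the identity.

The pipeline order is filter → ComBat → outlier removal → replicate
collapse → pair averaging. The order is logged in the run summary. Outliers
are samples whose mean inter-sample Pearson correlation falls below
median − 3·IQR of that statistic; with IQR = 0 (degenerate equal columns)
nothing is flagged. When one co-twin is flagged, the whole pair is removed
so pair averaging never sees a half pair. Pair averaging takes the
arithmetic mean of the two co-twins (who share an age by construction) and
passes controls through untouched.

## Concordance and drift

All pairwise sample correlations are classed as replicate (same
individual), twin (co-twins of one pair) or unrelated (different
individuals from different pairs); replicate self-comparisons and co-twin
comparisons are excluded from "unrelated". Classes are compared with
two-sided Wilcoxon rank-sum tests — exact for small tie-free groups, normal
approximation with tie correction otherwise. "Twin pairs cluster together"
is operationalized as the fraction of pairs that are mutual nearest
neighbours in the 1 − Pearson distance used for the sample dendrogram; a
cophenetic-sibling criterion was considered and rejected as sensitive to
linkage order. Epigenetic drift is tested by correlating intra-pair
distance (1 − r, Euclidean, or Manhattan over shared probes) with pair age;
all-equal distances are reported as not estimable rather than as a number.

## Co-methylation network

The network is built on pair-averaged data, treating each pair as one
independent sample. Signed adjacency a_ij = ((1 + c_ij)/2)^β with β = 12 —
the standard soft-threshold power for signed networks, configurable — maps
anti-correlated probes to adjacency ≈ 0 instead of connecting them. The
topological overlap measure TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)
(ℓ = shared-neighbour connectivity, k = node connectivity) is clustered by
average linkage on 1 − TOM. Modules are branches under a static cut at
`cut_height` × the maximum merge height (default 0.99); clusters below
`min_module_size` (default 30) are relabelled grey. A static cut plus a
minimum size is reproducible and dependency-free; a dynamic hybrid tree cut
would change memberships at the margins but not the module-level
statistics. Modules are named by size rank over a fixed colour list, with
ties broken by the lowest member index so labels do not depend on probe
input order.

Each module is summarised by its eigenlocus: probes are standardized across
samples and the first right-singular vector over samples (unit norm) is
taken, signed so it correlates positively with the module's mean
standardized profile. Note a consequence of this anchor: globally flipping
the betas flips the anchor and therefore the eigenlocus sign. The
eigenlocus–age Pearson correlation is Bonferroni-corrected by the module
count only — the point of the module reduction is that a handful of
comparisons replaces tens of thousands.

Known limitation: with few samples (n ≈ 34) and modest module factors, the
static cut absorbs background probes into the large modules (the planted
partition is recovered exactly only when between-module correlation is
near zero). The detected age-probe module, however, is sharply defined:
probes that share an age slope are mutually correlated and cluster
together, reproducing the "one module carries the age signal" structure at
simulation scale.

## Age association

Per-probe Pearson correlation with age is converted to t = r√(n−2)/√(1−r²)
and a two-sided Student-t p-value on n−2 degrees of freedom; |r| = 1 is
reported as an exact fit with p = 0 rather than dividing by zero. The
association stage runs on pair-averaged twin columns by default (a flag
includes controls/individuals), mirroring a design where each pair is one
biological observation.

Storey q-values: π₀ is estimated from π₀(λ) = #{p > λ}/(m(1−λ)) on the grid
λ = 0.05, 0.10, …, 0.90, smoothed with a cubic polynomial and read off at
the largest λ, clamped to (0, 1]; for m < 100 the tail estimate is unstable
and π₀ = 1 is used (making the q-values exactly Benjamini–Hochberg).
q_(i) = min_{j≥i} π₀·m·p_(j)/j, capped at 1, mapped back to input order.
Selection is strict q < cut (default 0.05) and reports the count, the
minimum |r| among selected probes, and the positive/negative split.

CpG-island enrichment is a two-sided Fisher exact test of the selected
probes against the remaining analysis background (the filtered, annotated
probe set). The TSS summary is the median signed offset with the usual
even-count midpoint convention.

## Predictor

The age model is ordinary least squares of age on marker betas, with an
optional squared term per marker computed on the raw (uncentered) beta —
the squared term is a genuine curvature term, and centering would only
reparametrize the intercept and linear coefficient. Leave-one-out
evaluation refits on n−1 samples per fold and predicts the held-out sample;
accuracy is the mean absolute error in years plus the Pearson correlation
of predicted vs observed age. (For OLS the refits agree with the leverage
identity pred_i = y_i − e_i/(1 − h_ii), which the tests use as an
independent oracle.)

Lasso screening minimizes (1/(2n))·RSS + λΣ|coef| (scikit-learn's
convention) over a decreasing λ path on internally standardized predictors
and a centered response. Candidates are ranked by the λ at which their
coefficient first becomes nonzero — entry order is stable and free of
scaling conventions. The top candidates are then pruned by fitting the
joint OLS model and keeping terms with coefficient p < 0.05, refitting on
the survivors.

## Synthetic data generator

Every probe/sample cell is built on a latent Gaussian scale and pushed
through the logistic function, so betas are bounded in (0, 1) without
truncation artifacts and age slopes are specified in latent units per year:

    x = baseline + slope·age + loading·module_factor + pair_effect
        + individual_effect + batch_shift + batch_scale·noise

Defaults mirror the emulated study design: 34 male MZ twin pairs aged
21–55, 31 male + 29 female controls aged 18–70, 10 replicate arrays, 5,000
probes with five planted modules of 199–842 probes, and 88 age-linear
probes (69 positive : 19 negative) whose latent slopes are calibrated so
the pair-averaged age correlation targets 0.6–0.8 via
slope = (σ_resid/σ_age)·r/√(1−r²). The 5,000-probe default keeps the
network stage comfortably in memory while preserving the multiplicity
regime (88 signals among thousands of nulls); the full 27,578-probe array
size is a config value away. Component scales (latent units): module factor
0.5, pair effect 0.2, individual effect 0.15, noise 0.3, batch shift 0.10
and batch log-scale 0.05 across 4 batches — the study reports no batch
magnitudes, so these are modest-but-removable values, configurable.

Two structural choices matter for interpretation. First, the module factor
is drawn per twin pair (shared by co-twins) and per control, and is then
residualized against the age vector: modules are co-methylation structure,
not age signal, and the projection makes the truth table exact — a probe
labelled non-age-associated has exactly zero in-sample age correlation.
Without it, a factor's chance correlation with age (sd ≈ 1/√33 at 34 pairs)
propagates to hundreds of module probes and the measured "false" discovery
proportion stops being an FDR. Second, the individual effect is shared by
replicate arrays of one person but not by co-twins; it is what separates
the replicate and twin concordance classes, as in real data.

Island flags are Bernoulli(0.73) for background probes (the typical array
probe) and Bernoulli(0.83) for age probes; age-probe TSS offsets centre 238
bp upstream. The validation-cohort generator plants k markers with
independent latent noise so the joint population R² = Σλ/(1+Σλ)
(λ_j = r_j²/(1−r_j²), split equally) hits a target (default 0.73 at n = 66);
ages are truncated-normal mean 38, sd 13 on [18, 70], i.e. a population sd
of ≈ 12.5 years, so the residual sd √(1−R²)·σ_age ≈ 6.5 years puts the
expected LOO MAE near 5 years.

What the generator does **not** emulate: probe cross-hybridization,
SNP-under-probe artifacts, cell-composition mixtures, the bimodal
genome-wide beta distribution, and spatially correlated batch effects.
Passing tests therefore certify the statistical machinery and its operating
regime, not platform-specific artefact handling on real arrays; the
deposited study data (GEO accession GSE28746) can be run through the same
pipeline via the recipe in the README.

## Numerical choices

- Correlations computed by centered dot products; |r| clipped to 1 before
  the t transform; exact fits flagged instead of propagating infinities.
- ComBat output clipped to [0, 1]; adjacency/TOM inputs validated for
  symmetry (atol 1e−10) and range, TOM denominator guarded so isolated
  node pairs yield 0 rather than NaN.
- Linkage ties are broken deterministically (lowest probe index) when
  ranking module sizes; scipy's average linkage is itself deterministic.
- LOO folds use least squares with an explicit rank check per fold; a
  rank-deficient fold is an error naming the fold, not a silent pseudo
  inverse.
- All randomness flows from numpy `default_rng` seeds carried in configs;
  the pipeline fans one global seed out to its stages.

## Problem sizes

The test suite and the acceptance script run the twin study at its default
scale (5,000 probes, 98 primary samples + 10 replicates) and the
validation cohort at n = 66; multi-seed checks use 10–20 seeds. These sizes
were chosen so the whole analysis — including the 5,000-probe TOM and
dendrogram — completes in seconds on one core while keeping every
statistical regime (multiplicity, FDR, LOO) intact.
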