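# Methods

This note documents the models and procedures the package implements, the
choices made where the method left design open, and what the synthetic
validation experiments do and do not establish.

## The analysis in outline

The pipeline asks where and when neural responses to spoken words carry
the same pairwise similarity structure as the internal states of an
automatic speech recognizer (ASR), and whether that shared structure is
better described in terms of articulatory phonetic features than
individual phones.  Its currency is the representational dissimilarity
matrix (RDM): a symmetric condition-by-condition matrix of response
dissimilarities with zero diagonal, here always the correlation distance
1 − Pearson's r, bounded in [0, 2].  Time-indexed sequences of RDMs — one
per sliding-window position — are called dynamic RDMs (dRDMs).

**Model dRDMs.**  The recognizer's acoustic model emits, every 10 ms
frame, a log-likelihood per triphone (a centre phone in left/right
context).  For each phone φ, the triphone columns whose centre is φ are
grouped, and the six frames inside a 60 ms sliding window are
concatenated into one likelihood vector per word.  Correlation distances
between these vectors over word pairs give one model RDM per window
position; sliding the window in 10 ms steps across a 270 ms epoch gives
the phone's model dRDM.  Log-likelihoods enter raw — no exponentiation
or per-triphone normalization — and the concatenation order (frame-major)
is fixed but immaterial, since correlation distance is invariant to a
shared permutation of vector components.

**Data dRDMs.**  Source-space epochs (vertex × 1 ms samples per subject
and condition) are scanned by a spatiotemporal searchlight: a spatial
patch of all in-mask vertices within 20 mm (3D Euclidean distance) of a
centre vertex, crossed with the same 60 ms / 10 ms sliding window.  The
patch × window block is flattened (vertices-major, then time) into one
response vector per condition; per-subject RDMs are computed and averaged
across subjects, yielding one data RDM per (centre vertex, window).  A
fixed 100 ms lag offsets speech input from neural response: the model
window at t is paired with neural data at t + 100 ms, so a 0–270 ms
model epoch reads neural data at 100–370 ms.

**GLM.**  At each vertex and window, all phone model RDMs are fitted
simultaneously to the data RDM by ordinary least squares on
upper-triangle vectors, with an explicit all-ones intercept column:

    D = β₁·1 + Σ_φ β_φ·M_φ + E.

Predictors enter raw (no z-scoring or demeaning): the feature aggregation
downstream sums raw β_φ across phones, and rescaling predictors would
silently reweight features.  Rank-deficient designs (collinear models of
acoustically similar phones) are solved by the minimum-norm solution with
a logged condition-number warning rather than by dropping predictors —
the structural remedy for competitor ambiguity is the feature
aggregation itself.  β values are averaged over the epoch's windows
before feature conversion.

**Feature fits.**  A binary phone × feature matrix χ (shipped as an
editable CSV covering 40 British English phones in six category groups:
broad class, consonant place, consonant manner, vowel frontness,
closeness and roundedness) converts phone coefficients to per-feature
fits: fit_f = Σ_φ χ_f(φ)·β_φ, intercept excluded, no normalization by
phones-per-feature (unequal phone counts are absorbed by the per-feature
null instead).  Phones in the matrix without a fitted model contribute 0
with a log message.

**Permutation statistics.**  Under H0 the condition labels are
exchangeable, so null fits are simulated by randomly permuting the rows
and columns of every data RDM (models untouched), refitting, epoch
averaging, and recomputing fit_f.  Null values are pooled over all
in-mask vertices and iterations into a separate distribution per feature;
the empirical q-quantile (inverted-CDF order statistic, conservative on
pooled samples) gives the threshold θ_f, and a vertex survives when
fit_f > θ_f.  By default one permutation per iteration is shared across
vertices, preserving spatial exchangeability under pooling; independent
per-vertex permutations are available.  The default permutation count is
chosen so that n_perm × vertices ≥ 10,000 samples per feature.  No
multiple-comparison correction is applied beyond the pooled-null
quantile; this is a documented limitation of the procedure.

**Second-order validation.**  Before re-expressing coefficients in
feature terms, the feature set is checked against the second-order
structure of the model space: Spearman rank correlations between the
upper-triangle vectors of every pair of model RDMs at each window.  Two
diagnostics score each binary feature partition: the Davies–Bouldin index
(lower = better separated), computed on models represented as
rank-transformed upper-triangle vectors under Euclidean geometry — a
point space chosen to match the Spearman geometry of the second-order
matrix while giving the index the centroids it needs — and η², the
proportion of pairwise squared dissimilarity variance explained by the
partition, computed directly on the 1 − ρ distances and comparable
against the conventional 0.01 / 0.06 / 0.14 benchmarks.  A non-metric
(stress-minimizing) MDS embedding visualises the arrangement; rank-based
stress matches the Spearman distances, and the Pearson correlation
between embedded distances and input dissimilarities is reported as a
faithfulness measure, never asserted against any external value.
Per-window diagnostics are aggregated as mean ± SD across the epoch.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| patch radius | 20 | mm | searchlight spatial extent |
| window / step | 60 / 10 | ms | sliding temporal window |
| lag | 100 | ms | speech-to-cortex processing delay |
| model epoch | 0–270 | ms | restricted to the shortest stimulus |
| frame step | 10 | ms | likelihood stream resolution |
| windows per epoch | 21 | — | "trimmed" windowing convention (below) |
| n_perm | 100 | — | sized so n_perm × vertices ≥ 10,000 |
| quantiles | 0.95 / 0.99 / 0.999 | — | standard significance levels |

**The 21-vs-22 window question.**  A 60 ms window stepped by 10 ms fits
22 onsets in a 270 ms epoch (0 … 210 ms), but the analysis convention
indexes 21 positions.  The package's default "trimmed" mode drops the final
onset when more than one window fits and the last window would end flush
with the epoch; "formula" mode keeps all fitting onsets.  Both are
available on `SearchlightConfig`; every count-dependent quantity responds
consistently to the choice.

**Patch distance** is 3D Euclidean between vertex coordinates, not
geodesic along the cortical surface — standard for searchlights and all
the synthetic grid geometry requires; geodesic distance would be a
natural extension for folded cortical meshes.

## Synthetic data: what it emulates, what it does not

No public dataset accompanies the analysis, so every input is generated
with known ground truth.

*Likelihood streams*: each condition's phone string is laid out over the
epoch in equal-duration segments; the triphone matching the active
(previous, current, next) context gets a high log-likelihood baseline
(−2), all others a low baseline (−12), plus i.i.d. Gaussian noise
(SD 1).  This reproduces the one property the model RDMs depend on —
conditions sharing a centre phone at a time are more correlated within
that phone's column group — but none of the acoustics of real
recognizers: no coarticulation dynamics, no graded likelihoods among
confusable phones, no duration variation.

*Source epochs*: a regular 3D grid stands in for the cortical mesh;
background activity is i.i.d. Gaussian noise.  Representational geometry
is implanted by drawing, for each window, a patch × window response block
whose expected condition-pair correlation structure matches the chosen
model RDM frame (similarity S = 1 − RDM is projected to the nearest PSD
matrix by eigenvalue clipping, factored, and multiplied into a Gaussian
matrix), scaled by an effect amplitude (default 1, against noise SD 1)
and added at the lagged window position.  Structure is shared across
subjects; noise is independent per subject.  Because adjacent windows
overlap in time, their injected blocks sum, so the realised geometry at
any window is a mixture dominated by that window's target — adjacent
model frames are themselves similar, and recovery experiments confirm
the intended phone dominates the fit.  Not emulated: source-leakage
correlations between vertices, 1/f noise spectra, evoked transients, or
inter-subject anatomical variability.  Passing validation therefore
shows the estimator and its null are correct under exchangeable noise
with planted effects, not that real EMEG data meet those assumptions.

*Scales*: generator defaults mirror the full study (400 conditions, 16
subjects, 21 windows, 100 ms lag).  Validation experiments construct
reduced-scale specs explicitly — 24 conditions, 2 subjects, a 7×7×7 grid
(343 vertices), 100 permutations — so a complete pass runs on one CPU in
minutes.  At validation scale the grid spacing is set equal to the patch
radius (20 mm), so neighbouring searchlight patches overlap only weakly
and the H0 survival fraction is estimated from quasi-independent cells;
the calibration experiment additionally pools three independent
replicates (>21,000 cells) to stabilise the estimate.  Survival-rate
summaries count only features with at least one fitted phone model:
features with none have fit ≡ 0 and a degenerate all-zero null, and can
never survive a strict threshold.

## Numerical choices

- Correlation distances are clipped to [0, 2] against floating-point
  overshoot; RDMs are stored exactly symmetrised with an exactly zero
  diagonal.
- Zero-variance response vectors raise a `DegenerateInputError` naming
  the offending condition rather than propagating NaN, which would
  corrupt downstream GLM fits invisibly.
- The upper-triangle traversal is row-major over the strict upper
  triangle, fixed globally; only cross-module consistency matters.
- Least squares uses SVD-based solvers (`lstsq` / pseudo-inverse); the
  batch engine used for permutations is verified in tests to agree with
  the per-RDM path to ~1e−9.
- Null quantiles use the inverted-CDF order statistic (`numpy`
  `method="inverted_cdf"`), conservative on pooled empirical samples.
- η² is clipped to [0, 1]; the all-points-coincident 0/0 case is defined
  as 0 with a warning.  Davies–Bouldin requires ≥2 points per class and
  returns 0 when both clusters collapse onto their centroids.
- MDS runs 8 restarts from a fixed seed; non-convergence surfaces
  through the reported stress and correlation.
- All generators are pure functions of (spec, seed) via
  `numpy.random.default_rng` seed sequences; pipeline reruns with an
  identical config are byte-identical.

## Known limitations

- The shipped feature matrix is a standard British English articulatory
  assignment, editable as configuration; users with a different phone set
  or feature theory should supply their own CSV.
- Euclidean (not geodesic) patch distance; no correction for multiple
  comparisons across vertices beyond the pooled null; per-window
  statistical maps are computed only on request (epoch-averaged summaries
  are the default output).
- The permutation-sharing convention across vertices (one permutation per
  iteration) is a modelling choice; the alternative (independent
  per-vertex permutations) is implemented and switchable, and the two
  pool to the same marginal null.
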