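# Methods

This note documents the models and procedures `semrsa` implements, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## The semantic model

Verb selectional preferences are modelled distributionally.  Each verb is
treated as a *document* containing the direct-object (DO) nouns it
co-occurs with, each noun repeated N times where N is the (rounded)
association weight from a verb–noun co-occurrence table.  Weights are
arbitrary nonnegative reals (raw counts, or LMI-style association
scores); they are rounded half-up to integers, and verbs whose document
rounds to empty are dropped with a warning.

Latent Dirichlet allocation with K topics is fitted to these documents
with batch variational EM (scikit-learn's implementation), symmetric
Dirichlet priors α = 1/K (document–topic) and η = 0.01 (topic–word), both
configurable.  Variational EM is prone to local optima in which one
well-separated topic is split across two fitted components; `n_init = 3`
random restarts are run (child seeds of the user seed) and the fit with
the best evidence lower bound is kept.  The fit is deterministic given
the seed.

From the fitted model:

* **verb topic vector** — P(topic | verb), the verb document's fitted
  topic mixture (normalized);
* **noun topic vector** — P(topic | noun) ∝ P(noun | topic) · P(topic).
  P(topic) is not identified by the model itself; it is computed as the
  token-count-weighted mean of the per-document topic mixtures (the
  standard empirical topic marginal);
* **verb-weighted noun vector** — the element-wise product of the two.
  It is *not* renormalized: all downstream comparisons are cosine
  distances, which are scale-invariant, and leaving the raw product makes
  an identically-zero product (disjoint topic supports) detectable rather
  than silently masked;
* **topic entropy** H(v) = −Σ p log p in nats (natural log throughout);
  H ∈ [0, ln K];
* **verb constraint error** — cosine distance between the verb and noun
  topic vectors.

**Topic informativeness.**  Topics differ in semantic dispersion, which
biases entropy comparisons.  Each topic receives a weight equal to the
normalized entropy deficit of its word distribution,
w_k = (ln V − H(topic k)) / ln V ∈ [0, 1]; a topic uniform over the
vocabulary weighs 0, a one-word topic weighs 1.  When weighting is
enabled (default) it is applied to both verb and noun topic vectors
before *any* downstream quantity (entropy, product, distances) is
computed; a config switch disables it, making the choice auditable.

## Model RDMs

The stimulus design is 60 sets × (3 verbs × 2 DO nouns) = 360 sentences;
sentence order is the canonical RDM row order.  Five model RDMs are
built: cosine-distance RDMs over verb, noun, and verb-weighted noun
vectors, and absolute-difference RDMs over verb topic entropy and verb
constraint error.  Sentence pairs sharing a verb get exact zeros in the
verb-based RDMs (identical vectors are detected bytewise, avoiding
1e-16 jitter).  The verb–noun *interaction* is not a separate matrix: it
is the verb-weighted noun RDM fitted with the verb topic and noun topic
RDMs partialled out at correlation time, which keeps model RDMs pure.

RDMs are compared through row-major upper-triangle condensed vectors.
`partial_spearman` rank-transforms every vector (average ranks for
ties), residualizes target and reference against an intercept plus the
ranked controls, and returns the Pearson correlation of the residuals;
with no controls this is ordinary Spearman.  If a residual is
numerically zero (the vector is fully explained by the controls) the
partial correlation is defined as 0.

Epoch lengths follow the word-duration arithmetic: mean + 1 SD of the
spoken word duration, rounded half-up to 10 ms — 487 + 116 → 600 ms for
the verb epoch, 523 + 114 → 640 ms for the noun epoch, at a 2 ms
sampling step (500 Hz).

## Searchlight RSA

The searchlight is spatiotemporal: all vertices within a 10 mm radius of
a centre vertex (the centre always included), crossed with a ±30 ms
window (60 ms total).  Per searchlight, each trial's vertices × samples
patch is flattened and the data RDM is the pairwise Pearson correlation
distance (1 − r).  Model fit is the (partial) Spearman correlation of
condensed data and model RDMs.  Centres whose full window exceeds the
epoch are NaN rather than truncated, keeping window size constant across
the map.  A `center_step` parameter strides the centre-time grid; the
study-scale recovery analyses in this repository use a 10 ms stride
(step 5 at 2 ms sampling), which is the problem size the acceptance run
uses.  A `method` switch selects rank-based (default) or linear
(Pearson) partialling; see "Additivity" below.

**Multivariate noise normalization.**  Spatial whitening by Σ^(−1/2),
where Σ is estimated from trial-demeaned data pooled over all samples
(single-presentation designs have no condition replicates, so the
trial-mean residual is the least-assumptive noise estimate), shrunk
toward its diagonal with a Ledoit–Wolf-style coefficient ("auto") or a
fixed λ ∈ [0, 1].  λ = 1 reduces to per-vertex scaling by noise SD.

**Group inference.**  Per grid point, a one-tailed one-sample t test
across subjects (the direction is fixed: mean model fit > 0).  Points
above the t quantile of the point-wise α (default 0.01, df = n−1) form
clusters by joint spatiotemporal adjacency — spatial edges are vertex
pairs within the searchlight radius, temporal edges connect consecutive
centre times.  The cluster statistic is *mass* (summed t; more sensitive
to strong compact effects than extent).  The null distribution is the
maximum cluster mass under random per-subject sign flips (default 5,000
permutations, seeded); cluster p uses the add-one estimator
(1 + #null ≥ mass) / (1 + n_perm), so p is never 0 and the attainable
minimum is 1/(1 + n_perm).  Note the sign-flip null is discrete: with n
subjects, one-sided p cannot fall below ~1/2^n, so α = 0.01 requires
n ≥ 8.

## Directed connectivity

Granger-style dependence on representational geometry: the connectivity
A→B at epoch time t and lag dt is the partial correlation between
condensed D(A, t − dt) and D(B, t), partialling out D(B, t − dt).  Data
RDMs here are *instantaneous* (single-sample ROI patterns) to avoid
leakage from neighbouring samples.  The lag grid is every sampling step
from 2 to 120 ms.  The correlation flavour is rank-based by default
(consistent with the RSA model-fit statistic), with a Pearson option;
with a single control the implementation uses the closed-form
first-order partial correlation on standardized (ranked) condensed RDMs,
verified against the general residual-regression path.

ROIs are either vertex lists or selected from a group result: each
vertex scored by the sum of its t values over significant time points,
top 100 within an anatomical label mask, ties broken by ascending vertex
id.  Group inference on (t, dt) maps mirrors the RSA machinery with
4-neighbourhood lattice adjacency and point/cluster α of 0.001/0.01;
pcc values are Fisher z-transformed first (variance stabilization —
unspecified in the source analysis, chosen here as the standard
treatment of correlations).  Points with t − dt before epoch start are
NaN and excluded from clustering.

## Synthetic data

The generators replace a training corpus and source-localized
recordings.

* **Topics/corpus** — planted topic-word rows ~ Dirichlet(concentration)
  over V nouns; per-verb topic mixtures ~ Dirichlet(verb concentration);
  documents sampled topic-then-word.  Defaults for recovery analyses:
  K = 5, V = 100, concentration 0.05 (well-separated topics), 200 verbs
  × 5,000 tokens.
* **Mesh** — an abstract quasi-uniform 3-D point cloud (Halton sequence,
  seed-independent so planted locations are stable across seeds); the
  searchlight needs only coordinates and distances, not a cortical
  surface.  Default 500 vertices in a 60 mm cube, giving ~8-vertex
  searchlight neighbourhoods at 10 mm radius.
* **Epochs** — unit-variance Gaussian noise smoothed along time (Gaussian
  kernel, σ = 4 ms) and across the mesh (Gaussian kernel, σ = 5 mm,
  truncated at 2σ).  Default 300 samples at 2 ms, 12 subjects, 120
  stimulus items for the study-scale recovery analyses (the full 360-item
  design is exercised in the structural checks).
* **Planted geometry** — per-item patterns realizing a target RDM inside
  a region × window, scaled so the planted feature RMS is `snr` × noise
  SD.  The similarity matrix G = 1 − D is factorized
  (eigendecomposition); when G is not PSD its diagonal is shifted
  (G + αI), which rescales all pairwise correlations by 1/(1+α) — the
  realized correlation distances are an exact strictly monotone
  transform of D, so rank-based fits see the planted geometry exactly.
  Item coordinates are mapped through a random orthonormal basis of
  patch space orthogonal to the constant vector (feature-mean-zero
  patterns make Pearson correlation equal cosine similarity).  The
  geometry (RDM, region, window) is shared across subjects; the basis is
  redrawn per subject.  Sharing the voxel-level basis would make
  searchlight *sub-patch* distortion identical across subjects and
  produce spurious group-level fits for secondary models; sharing only
  the geometry matches what RSA assumes subjects have in common.
* **Planted coupling** — B's pattern at t receives gain × M × A's pattern
  at t − delay, with M a fixed per-subject random linear map scaled to
  preserve variance; ROIs must be disjoint and the delay a multiple of
  the sampling step.

What the generator does **not** emulate: forward-model leakage between
regions, 1/f and oscillatory spectra, evoked transients, inter-subject
anatomical variability, or any acoustic/lexical properties of the
stimuli.  Passing recovery tests therefore shows the *estimators* are
correct and well-calibrated under their assumptions, not that real EMEG
effects of a given size would be detected.

## Interactions between model RDMs (what nulls are attainable)

Model RDMs built from one stimulus design are rank-coupled: same-verb
sentence pairs sit at the bottom of both the verb-topic and entropy
RDMs, and the verb-weighted noun RDM shares noun-derived structure with
the noun-topic RDM.  Planting any verb-topic-like geometry therefore
induces a genuine, smaller secondary fit for the coupled models; the
pipeline tests assert dominance of the planted model (cluster-mass
margins) rather than literal emptiness of the secondary map.

**Additivity.**  Data whose distance structure is exactly additive in
the verb and noun RDMs carries no interaction — but only under *linear*
partialling: the rank transform does not preserve linear combinations
(rank(0.5a + 0.5b) is not in the span of rank(a) and rank(b)), and the
leftover rank-nonlinearity term can reach |ρ| ≈ 0.1–0.2 with either
sign.  The additive-null test and the corresponding acceptance identity
therefore use the Pearson variant, under which the null is exact; the
default interaction analysis remains rank-based.  Exactness also
requires partialling out the *same* fitted RDMs the additive structure
was built from — estimation error in the controls leaks through.

## Numerical choices

* Distance matrices are symmetrized and clipped at 0; identical input
  vectors give exact zeros.
* The searchlight loop computes, per centre time, batched per-vertex
  window Gram matrices, aggregates them over neighbourhoods with a
  sparse indicator matrix, converts to condensed correlation distances,
  and ranks row-wise with a vectorized average-rank routine (equivalent
  to `scipy.stats.rankdata`, verified exactly, including ties).  The
  fast path is verified against the naive per-searchlight computation to
  1e-10.
* t statistics guard zero variance (all-zero maps give t = 0; noise-free
  planted maps give arbitrarily large finite t).
* Degenerate inputs raise typed errors naming the offending trial,
  sentence, or token; they are never silently skipped.

## Problem sizes used by the acceptance run

Topic recovery: 200 documents × 5,000 tokens, K = V/20 = 5.  Searchlight
recovery: 500 vertices, 300 samples, 12 subjects, 120 items, SNR 4,
1,000 permutations, 10 ms centre stride.  Error-rate calibration: 200
null group analyses at 500 permutations on reduced grids (40 vertices ×
20 times; 30 × 20 lattice).  Delay recovery: 100 vertices, two 15-vertex
ROIs, 20 ms delay, gain 1.5, 12 subjects.  These sizes are the package's
standard desk-scale study conditions; all are configurable.
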