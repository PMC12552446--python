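# Methods

This note documents the models, defaults and design choices behind
`camannotate`, and what the synthetic-data tests do and do not establish
about real study data.

## Annotation model and intensity rules

A raw annotation string is `prefix;…;prefix;CODE description`, split on
`";"`. Compendium codes are nominally 5-digit, but 4-digit forms occur in
real exports, so a leading 4- or 5-digit integer on the terminal segment is
accepted as a code and its width recorded; 6+ digit numbers are treated as
text. Parsing is total: malformed strings yield no code and the raw
terminal segment as description.

Labels matching a configurable *unknown vocabulary* (defaults:
`uncodeable`, `undefined`, `image dark/blurred/obscured`; matched
case-insensitively after whitespace normalisation, at whole-string or
segment level) are uncodeable and always map to intensity `unknown`.

Intensity assignment is a total function of (MET, posture, waking):
non-waking → sleep; MET ≤ 1.5 with sitting/lying/reclining posture → SB;
otherwise MET < 3 → LIPA; MET ≥ 3 → MVPA. Boundary conventions: 1.5 MET
sitting is SB; 3.0 MET is MVPA. A MET ≤ 1.5 observation with *unknown*
posture is classified LIPA with a warning: the sedentary definition is
posture-conditional, so SB requires positive posture evidence. MET and
posture come from a lookup table (code or description → MET/posture)
supplied as configuration rather than an embedded Compendium (licensing
and versioning); posture falls back to description tokens
(sitting/seated → sitting, walking/running/cycling → moving, …).

## Capture statistics, coverage and epochs

Inter-image intervals δt are successive timestamp differences within a
participant's stream; gaps above a 4 h threshold are treated as stream
breaks (camera off) and excluded. All quantiles in the package use linear
interpolation between order statistics. Labelled-time coverage is
`n_labelled × median δt / 3600` hours, reported after half-up rounding to
integer hours with the exact value retained. This deliberately credits one
full capture interval per labelled image and is therefore an optimistic
estimate for sparse time-lapse data.

Epoch aggregation treats each maximal run of consecutive same-label images
as an interval from its first to last image timestamp (annotation extent
is image-based; single-image runs have zero extent). The epoch grid is
anchored at the participant's first image, half-open `[start, start+L)`;
each epoch takes the intensity with the greatest covered duration, ties
breaking to the higher-intensity class (deterministic, and biased against
the majority class SB); uncovered epochs are `unknown`. Epoch length is a
parameter (default 60 s in the pipeline) — nothing in the processing fixes
a canonical value.

## Label cleanup

Unique raw labels are embedded, clustered agglomeratively with **average
linkage on cosine distance** (standard for sentence-embedding
deduplication and invariant to vector scaling), and groups proposed by
cutting the dendrogram at a height threshold. The reproducible artifact is
the *reviewed merge map* file, not the clustering: `propose_merges` only
assists review. Applying a map never changes row counts; unmapped codeable
labels are reported (or raise in strict mode) rather than passing through.

## Embedding contract and the reference embedder

All retrieval logic is written against a minimal contract: deterministic
`embed(text) → fixed-length vector`. Real sentence-embedding backends plug
in directly. The bundled reference embedder is a hashed character trigram
frequency vector (dimension 256, CRC32 hashing with a fixed salt,
L2-normalised, lowercase/whitespace/punctuation-normalised input). It is
deterministic across platforms and order-insensitive, which is what the
correctness tests need; it measures surface string similarity, not
semantics, so measured agreement values under it say nothing about the
semantic quality of any real embedding model — only about the correctness
of the mapping, tie-breaking and evaluation machinery around it.

## Zero-shot mapping

`retrieve_nearest` is an argmax of cosine similarity over the target set;
ties break to the lowest target index (target files are ordered). Query
scale never matters. Description normalisation before embedding:
lowercase, strip punctuation, collapse whitespace. Empty descriptions
yield `unknown` with absent similarity rather than an error. Because
nearest-neighbour mapping never checks that an intensity is *implied* by a
description, low best-vs-runner-up margins can be exported for human audit
(`low_margin_report`) instead of attempting entailment checking. Token
limits, prompt choice and class-phrase wording are configuration
(`PromptBank`); describer backends are adapters behind
`run_backend(manifest, backend, prompt)`.

## Evaluation

Metrics are computed per participant on image-level intensities (the
classifiers under evaluation see single images). Cohen's κ uses
p_o = trace/n and p_e = Σ row·col / n²; κ is undefined when p_e = 1 (both
sides constant on one class) and such participants are excluded from κ
summaries with exclusion counts reported — zero-filling was rejected
because participants with few LIPA/MVPA instances would bias medians.
Per-class F1 is the harmonic mean of precision and recall with 0/0
undefined under the same policy. Five-number summaries use
linear-interpolation quartiles. Stratified evaluation (e.g. darkest-5%
images by cohort-level brightness percentile) flags strata below a
10-image support floor. The implementation is self-contained NumPy; the
test suite cross-checks it against scikit-learn on random inputs, keeping
implementation and oracle distinct.

## Image quality

Brightness is the mean grey intensity (luma weights 0.299/0.587/0.114) and
variation the population standard deviation of grey pixels — simple,
deterministic statistics chosen as the package's definition of "darkness".
Darkness flags are cohort-level percentile cuts (per-participant cutting
is available as a switch). Capture-rate clustering is descriptive 1-D
k-means over per-participant median δt, default k = 4.

## Synthetic studies

The generator's defaults are the study conditions all tests run under:

| parameter | default | rationale |
|---|---|---|
| capture-rate centres | 24 s, 84 s | the two studies' device medians |
| rate jitter | 2 s s.d. | keeps per-participant medians clustered |
| day window | 8 h | one waking day of wear |
| bout durations | log-normal, median 10 min, σ = 0.75 | bouts long enough to make runs/epochs non-trivial, short enough for ~40 bouts/day |
| class prevalence | 0.62 / 0.31 / 0.07 | SB-dominant, echoing per-participant median instance ratios ≈ 884 : 441.5 : 81 |
| unknown rate | 0.10 | between the two studies' unlabelled extremes |
| dark mixture | 8% at N(30, 12), else N(140, 30) | a dark tail plus bright bulk on the 0–255 scale |
| dark→unknown odds | ×4 | qualitative mirror of dark images being harder to annotate; directional only |

Bouts are a semi-Markov chain: class drawn from the prevalence simplex,
activity uniform within class, duration log-normal independent of class —
so image-level class shares match the prevalence in expectation, but the
*realised* marginal of any one study fluctuates at the bout (not image)
scale. Analytic comparisons therefore condition on the realised activity
marginal where bout clustering matters. The catalogue (8 activities with
codes, METs, postures and description templates) is validated at
construction: each activity's declared intensity must equal what the
MET/posture rules derive, welding generator and rules together. Template 0
of each activity echoes its clean label, so a noise-free describer is an
exact retrieval fixed point (κ = 1 everywhere).

Simulated classifier output draws each image's prediction independently
from the confusion row of its true class, optionally degraded on dark
images by multiplying off-diagonal mass before renormalising. This gives
closed-form expected joints (`prevalence row-wise × confusion`) whose κ
the evaluation stack must recover — the repository's primary end-to-end
check.

What passing these tests does **not** show: anything about real-image
difficulty, real embedding semantics, annotator behaviour, device clock
drift, or the true bout structure of free-living behaviour (unpublished;
all generator parameters are declared fiction).

## Numerical and scale choices

Problem sizes were chosen so the whole suite runs in seconds on one CPU:
confusion-matrix recovery uses 100 000 iid images (κ and recalls recovered
to ±0.01); end-to-end runs use 12 participants × 4 h at 24 s (~7 000
images, kernel-κ agreement to ±0.03); independence checks use 10 000
images. Cosine similarities are clamped to [−1, 1] against rounding;
cosine distances clipped at 0 before linkage. Reported percentages follow
the conventional display: integer per cent for labelled fractions, one
decimal for unknown fractions, half-up integer hours for coverage.
Splitting is by participant (floor sizes, remainder to the training
split), never by image, and pipeline evaluation is restricted to the
held-out split by construction.

## Known limitations

* The reference embedder is lexical; semantic near-duplicates with
  disjoint character n-grams will not cluster or retrieve correctly —
  use a sentence-embedding backend for real label sets.
* Epoch aggregation ignores unlabelled gaps inside runs (extent is first
  to last image of the run).
* The darkness statistic is mean grey only; blur/obstruction detection is
  out of scope.
* No significance testing or bootstrap intervals — spreads are reported
  as quartiles only.
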