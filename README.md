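# camannotate

Tools for turning wearable-camera activity annotations and free-text model
descriptions into physical-activity **intensity classes** — sedentary
behaviour (SB), light intensity physical activity (LIPA) and
moderate-to-vigorous physical activity (MVPA) — with per-participant
agreement evaluation and data-quality diagnostics.

## Who this is for

Free-living validation studies of wearable activity measurement often use
chest-worn time-lapse cameras as the ground-truth source: trained
annotators label each captured image with a Compendium-of-Physical-
Activities style string (e.g. `occupation;interruption;13030 eating
sitting`), whose MET value and posture determine the intensity class.
Researchers who want to (a) process such annotation exports, (b) evaluate
automated describers/classifiers against them, or (c) prototype that
pipeline without access to restricted study images, can use this package.
The sensitive first-person images themselves never need to be present: a
synthetic study generator emulates their statistical structure.

## The model in brief

**Intensity rules.** With MET the metabolic equivalent of task (resting
rate convention 3.5 ml O₂·kg⁻¹·min⁻¹):

* SB — waking, MET ≤ 1.5, in a sitting/lying/reclining posture
* LIPA — waking, MET < 3, not meeting the SB definition
* MVPA — waking, MET ≥ 3
* sleep — non-waking

**Zero-shot mapping.** Classification is text retrieval: a query embedding
(an image embedding from a dual-encoder backend, or the embedding of a
generated description) is matched to the most cosine-similar target.
Targets are either the three intensity phrases ("sedentary behavior",
"light physical activity", "moderate-to-vigorous physical activity") or a
set of *clean labels* — semantically deduplicated colloquial activity
labels with known intensity mappings, produced by embedding raw labels,
agglomerative clustering, and a human-reviewed merge map.

**Evaluation.** Agreement is computed *per participant*: a 3×3 confusion
matrix (rows truth, columns prediction, fixed order SB/LIPA/MVPA), Cohen's
κ = (p_o − p_e)/(1 − p_e), per-class precision/recall/F1, accuracy; the
spread across participants is reported as five-number summaries
(min, Q1, median, Q3, max), optionally stratified by image darkness.

**Coverage.** Labelled time for a sparse time-lapse study is estimated as
`hours = n_labelled_images × median δt / 3600` where δt is the inter-image
capture interval.

## Worked example

```python
from camannotate import (StudyConfig, generate_study, generate_descriptions,
                         ZeroShotIntensityClassifier, per_participant_metrics,
                         summarize_metric, estimate_time_covered)

cfg = StudyConfig(n_participants=12, day_length_s=4 * 3600,
                  capture_rate_centres=(24.0,), seed=31)
annotations, truth = generate_study(cfg)

# a mock describer with 20% template-substitution noise stands in for a
# generative vision-language backend
desc = generate_descriptions(truth, cfg.catalogue, noise_rate=0.2, seed=1)

clf = ZeroShotIntensityClassifier(mode="clean_label").fit(
    [a.label for a in cfg.catalogue], [a.intensity for a in cfg.catalogue])
joined = truth.assign(truth=truth["intensity"],
                      pred=clf.predict(desc["description"]))
print(summarize_metric(per_participant_metrics(joined), "kappa"))
print(estimate_time_covered(231_837, 24))
```

prints

```
FiveNumberSummary(min=0.4944..., q1=0.6215..., median=0.6932...,
                  q3=0.7306..., max=0.7613..., n=12, n_excluded=0)
CoverageEstimate(n_labelled_images=231837, median_delta_t=24.0,
                 hours_exact=1545.58, hours=1546)
```

i.e. with a describer that substitutes a wrong activity template for 20%
of images, per-participant chance-corrected agreement sits around κ ≈ 0.69
(dropping the noise to 0 gives κ = 1 for every participant — the retrieval
fixed point), and 231 837 labelled images at a 24 s median capture interval
correspond to 1546 h of labelled time.

A command-line interface mirrors the library
(`camannotate simulate|ingest|summarize|epochs|labels|classify|quality|evaluate|run`).

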