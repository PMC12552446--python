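"""Synthetic wearable-camera studies with known ground truth.

The images and labels of real chest-camera validation studies are
restricted (sensitive first-person footage), so every pipeline stage here
is exercised on generated studies whose structure mirrors the published
summaries of such data-sets:

* participants capture time-lapse images at device-specific intervals
  clustered around study-specific centres (defaults 24 s and 84 s, the two
  study medians);
* activities arrive as a semi-Markov bout process over a small
  Compendium-style catalogue, with log-normal bout durations and a heavily
  SB-dominant stationary class distribution (default 0.62/0.31/0.07,
  echoing per-participant median instance counts of roughly 884/441.5/81);
* a fraction of images carry uncodeable labels ("uncodeable",
  "image dark/blurred/obscured"), enriched among dark images;
* image darkness follows a two-component mixture (a dark tail plus a
  bright bulk);
* simulated classifier output is drawn from a known 3x3 row-stochastic
  confusion matrix, which makes analytic kappa recovery checks possible.

All randomness flows through one seeded ``numpy.random.Generator``; a fixed
seed reproduces a study byte-for-byte.  Every parameter here is declared
fiction fit for testing — real bout and transition statistics of the
underlying studies are unpublished.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import (INTENSITY_CLASSES, DEFAULT_UNKNOWN_VOCABULARY,
                          assign_intensity)

_CLASS_INDEX = {c: i for i, c in enumerate(INTENSITY_CLASSES)}


@dataclass(frozen=True)
class Activity:
    """One catalogue entry: Compendium-style code, clean label, MET,
    posture, intensity and template descriptions (template 0 echoes the
    clean label so a noise-free describer is a retrieval fixed point)."""
    code: int
    label: str
    met: float
    posture: str
    intensity: str
    templates: tuple


DEFAULT_CATALOGUE = (
    Activity(13030, "eating sitting", 1.5, "sitting", "SB",
             ("eating sitting", "a person eating a meal at a table",
              "plates and food on a table in front of the person")),
    Activity(11580, "office work general", 1.3, "sitting", "SB",
             ("office work general", "a computer screen and keyboard on a desk",
              "sitting at a desk working on a computer")),
    Activity(7020, "watching television lying", 1.0, "lying", "SB",
             ("watching television lying", "a television screen seen from a sofa",
              "lying on a couch watching tv")),
    Activity(5060, "shopping miscellaneous", 2.3, "standing", "LIPA",
             ("shopping miscellaneous", "shelves of groceries in a shop",
              "standing in a supermarket aisle")),
    Activity(5040, "washing dishes standing", 1.8, "standing", "LIPA",
             ("washing dishes standing", "a kitchen sink full of dishes",
              "standing at the sink washing up")),
    Activity(17151, "walking slowly indoors", 2.0, "moving", "LIPA",
             ("walking slowly indoors", "a corridor seen while strolling",
              "walking slowly through a room")),
    Activity(17170, "walking briskly outdoors", 3.5, "moving", "MVPA",
             ("walking briskly outdoors", "a pavement moving past quickly",
              "walking fast along a street")),
    Activity(12020, "jogging general", 7.0, "moving", "MVPA",
             ("jogging general", "a park path seen while running",
              "running outdoors in sports clothes")),
)

_PREFIX_POOL = ("", "occupation", "leisure", "home activity")


@dataclass
class StudyConfig:
    """Generator parameters for one synthetic study.

    Defaults are the study conditions the rest of the package is tested
    under; see the methods note for the rationale behind each value.
    """
    n_participants: int = 20
    capture_rate_centres: tuple = (24.0, 84.0)   # seconds, device clusters
    rate_jitter: float = 2.0                     # s.d. of participant offsets
    day_length_s: float = 8 * 3600.0             # waking-day capture window
    bout_median_s: float = 600.0                 # log-normal median duration
    bout_sigma: float = 0.75                     # log-normal shape
    class_prevalence: tuple = (0.62, 0.31, 0.07)  # SB, LIPA, MVPA
    unknown_rate: float = 0.10                   # marginal uncodeable rate
    dark_rate: float = 0.08                      # dark-mixture weight
    dark_brightness: tuple = (30.0, 12.0)        # mean, s.d. of dark component
    bright_brightness: tuple = (140.0, 30.0)     # mean, s.d. of bright bulk
    dark_unknown_odds: float = 4.0               # uncodeable odds multiplier when dark
    catalogue: tuple = DEFAULT_CATALOGUE
    unknown_vocabulary: tuple = DEFAULT_UNKNOWN_VOCABULARY
    prefix_rate: float = 0.5                     # chance of a context prefix
    start_time: str = "2024-01-01T08:00:00+00:00"
    seed: int = 0

    def validate(self) -> None:
        prev = np.asarray(self.class_prevalence, dtype=float)
        if prev.shape != (3,) or np.any(prev < 0) or not math.isclose(
                prev.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("class_prevalence must be a 3-simplex")
        for rate in (self.unknown_rate, self.dark_rate, self.prefix_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_participants < 1 or self.day_length_s <= 0:
            raise ValueError("need >= 1 participant and a positive day length")
        for a in self.catalogue:
            derived = assign_intensity(a.met, a.posture)
            if derived != a.intensity:
                raise ValueError(
                    f"catalogue activity {a.label!r} declares {a.intensity} "
                    f"but MET/posture imply {derived}")


def _validate_confusion(confusion) -> np.ndarray:
    M = np.asarray(confusion, dtype=float)
    if M.shape != (3, 3) or np.any(M < 0) or not np.allclose(M.sum(axis=1), 1.0):
        raise ValueError("confusion matrix must be 3x3 row-stochastic")
    return M


def activity_distribution(catalogue, class_prevalence) -> np.ndarray:
    """Bout-level activity probabilities: class from the prevalence simplex,
    then uniform over that class's catalogue entries."""
    prev = np.asarray(class_prevalence, dtype=float)
    by_class = {c: [i for i, a in enumerate(catalogue) if a.intensity == c]
                for c in INTENSITY_CLASSES}
    for c, idxs in by_class.items():
        if not idxs:
            raise ValueError(f"catalogue has no activity of class {c}")
    pi = np.zeros(len(catalogue))
    for ci, c in enumerate(INTENSITY_CLASSES):
        for i in by_class[c]:
            pi[i] = prev[ci] / len(by_class[c])
    return pi


def generate_study(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (annotation table, truth table) for one synthetic study.

    The annotation table has the external dialect (participant_id,
    timestamp, raw_label); the truth table joins 1:1 on
    participant_id+timestamp and carries the generating clean label,
    intensity, bout id, darkness and brightness.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    catalogue = config.catalogue
    pi = activity_distribution(catalogue, config.class_prevalence)
    mu = math.log(config.bout_median_s)
    t_start = pd.Timestamp(config.start_time)
    # odds-based uncodeable probabilities; dark images are enriched
    u = config.unknown_rate
    if 0 < u < 1:
        odds = u / (1 - u)
        p_unknown_dark = odds * config.dark_unknown_odds / (
            1 + odds * config.dark_unknown_odds)
    else:
        p_unknown_dark = u
    annot_rows, truth_rows = [], []
    for p in range(config.n_participants):
        pid = f"P{p + 1:03d}"
        centre = config.capture_rate_centres[p % len(config.capture_rate_centres)]
        rate = max(1.0, centre + rng.normal(0.0, config.rate_jitter))
        # semi-Markov bout sequence covering the capture window
        bout_starts, bout_acts = [], []
        t = 0.0
        while t < config.day_length_s:
            bout_starts.append(t)
            bout_acts.append(int(rng.choice(len(catalogue), p=pi)))
            t += rng.lognormal(mu, config.bout_sigma)
        bout_starts = np.asarray(bout_starts)
        img_times = np.arange(0.0, config.day_length_s, rate)
        bout_of = np.searchsorted(bout_starts, img_times, side="right") - 1
        for i, (ti, bi) in enumerate(zip(img_times, bout_of)):
            act = catalogue[bout_acts[bi]]
            dark = bool(rng.random() < config.dark_rate)
            mean, sd = (config.dark_brightness if dark
                        else config.bright_brightness)
            brightness = float(np.clip(rng.normal(mean, sd), 0.0, 255.0))
            p_unk = p_unknown_dark if dark else u
            unknown = bool(rng.random() < p_unk)
            if unknown:
                raw = str(rng.choice(config.unknown_vocabulary))
            else:
                prefix = ""
                if rng.random() < config.prefix_rate:
                    prefix = str(rng.choice(_PREFIX_POOL[1:]))
                body = f"{act.code} {act.label}"
                raw = f"{prefix};{body}" if prefix else body
            ts = (t_start + pd.to_timedelta(ti, unit="s")).isoformat()
            annot_rows.append({"participant_id": pid, "timestamp": ts,
                               "raw_label": raw})
            truth_rows.append({"participant_id": pid, "timestamp": ts,
                               "clean_label": act.label,
                               "intensity": act.intensity,
                               "met": act.met, "posture": act.posture,
                               "bout_id": int(bi), "dark": dark,
                               "brightness": brightness,
                               "codeable": not unknown})
    return pd.DataFrame(annot_rows), pd.DataFrame(truth_rows)


def simulate_classifier(truth: pd.DataFrame, confusion, seed: int,
                        dark_col: str | None = None,
                        dark_offdiag_factor: float = 1.0) -> pd.DataFrame:
    """Draw per-image predictions from a known confusion structure.

    Each image's predicted intensity is drawn independently from the
    confusion row of its true intensity.  With ``dark_col`` set, rows
    flagged dark use a degraded matrix whose off-diagonal mass is
    multiplied by ``dark_offdiag_factor`` before row renormalisation.
    """
    M = _validate_confusion(confusion)
    rng = np.random.default_rng(seed)
    M_dark = M
    if dark_offdiag_factor != 1.0:
        M_dark = M.copy()
        off = ~np.eye(3, dtype=bool)
        M_dark[off] *= dark_offdiag_factor
        M_dark /= M_dark.sum(axis=1, keepdims=True)
    truth_idx = truth["intensity"].map(_CLASS_INDEX).to_numpy()
    if np.any(pd.isna(truth_idx)):
        raise ValueError("truth table contains non-SB/LIPA/MVPA intensities")
    dark = (truth[dark_col].to_numpy(dtype=bool) if dark_col is not None
            else np.zeros(len(truth), dtype=bool))
    pred_idx = np.empty(len(truth), dtype=int)
    classes = np.arange(3)
    # fixed iteration order (class x darkness) keeps draws deterministic
    for ci in range(3):
        for is_dark, mat in ((False, M), (True, M_dark)):
            mask = (truth_idx == ci) & (dark == is_dark)
            n = int(mask.sum())
            if n:
                pred_idx[mask] = rng.choice(classes, size=n, p=mat[ci])
    out = truth[["participant_id", "timestamp"]].copy()
    out["pred"] = [INTENSITY_CLASSES[i] for i in pred_idx]
    return out


def generate_descriptions(truth: pd.DataFrame, catalogue=DEFAULT_CATALOGUE,
                          noise_rate: float = 0.0, seed: int = 0,
                          template_index: int = 0) -> pd.DataFrame:
    """Mock describer output: each image gets a template of its true
    activity; with probability ``noise_rate`` the template of a different
    (uniformly chosen) activity is substituted.  The substitute's label is
    recorded as ``generating_label`` so downstream agreement can be checked
    against the substitution kernel analytically."""
    if not 0 <= noise_rate <= 1:
        raise ValueError("noise_rate must lie in [0, 1]")
    by_label = {a.label: i for i, a in enumerate(catalogue)}
    for a in catalogue:
        if len(a.templates) <= template_index:
            raise ValueError(f"activity {a.label!r} lacks template "
                             f"{template_index}")
    rng = np.random.default_rng(seed)
    n_act = len(catalogue)
    true_idx = truth["clean_label"].map(by_label).to_numpy()
    if np.any(pd.isna(true_idx)):
        raise ValueError("truth table contains labels outside the catalogue")
    substitute = rng.random(len(truth)) < noise_rate
    r = rng.integers(0, n_act - 1, size=len(truth))
    gen_idx = np.where(substitute, r + (r >= true_idx), true_idx).astype(int)
    out = truth[["participant_id", "timestamp"]].copy()
    out["description"] = [catalogue[i].templates[template_index]
                          for i in gen_idx]
    out["generating_label"] = [catalogue[i].label for i in gen_idx]
    out["generating_intensity"] = [catalogue[i].intensity for i in gen_idx]
    return out


def generate_toy_images(truth: pd.DataFrame, out_dir, size: int = 32,
                        noise_amplitude: float = 5.0, seed: int = 0) -> list:
    """Write flat-grey PNGs at each image's drawn brightness plus uniform
    pixel noise.  The noise amplitude is clipped to the distance from the
    intensity bounds so the measured mean brightness stays unbiased (an
    all-black request measures exactly 0); returns file paths in row order."""
    from pathlib import Path

    from PIL import Image

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, row in truth.reset_index(drop=True).iterrows():
        base = float(row["brightness"])
        amp = min(noise_amplitude, base, 255.0 - base)
        amp = max(amp, 0.0)
        noise = rng.uniform(-amp, amp, (size, size))
        arr = np.clip(base + noise, 0, 255).astype(np.uint8)
        path = out_dir / f"{row['participant_id']}_{i:06d}.png"
        Image.fromarray(arr, mode="L").save(path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# analytic agreement values for parameter-recovery checks
# ---------------------------------------------------------------------------

def kappa_from_joint(joint) -> float:
    """Cohen's kappa of a joint truth/prediction distribution."""
    J = np.asarray(joint, dtype=float)
    p_o = float(np.trace(J))
    p_e = float(J.sum(axis=1) @ J.sum(axis=0))
    return (p_o - p_e) / (1.0 - p_e)


def analytic_kappa(class_prevalence, confusion) -> float:
    """Kappa induced by truth ~ prevalence and predictions drawn from the
    confusion rows: joint = diag(prevalence) @ confusion."""
    prev = np.asarray(class_prevalence, dtype=float)
    M = _validate_confusion(confusion)
    return kappa_from_joint(prev[:, None] * M)


def substitution_intensity_joint(catalogue, class_prevalence,
                                 noise_rate: float,
                                 activity_probs=None) -> np.ndarray:
    """Intensity-level joint distribution induced by the description
    substitution kernel of :func:`generate_descriptions` (true activity
    kept w.p. 1-noise, else uniform over the other activities).

    By default the bout-level activity distribution implied by the class
    prevalence is used; pass ``activity_probs`` (catalogue-ordered) to
    condition on a realised activity marginal instead — e.g. the empirical
    label frequencies of a generated study, which fluctuate around the
    prevalence because activities arrive in bouts.
    """
    if activity_probs is not None:
        pi = np.asarray(activity_probs, dtype=float)
        if pi.shape != (len(catalogue),) or not math.isclose(
                pi.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("activity_probs must be a catalogue-ordered simplex")
    else:
        pi = activity_distribution(catalogue, class_prevalence)
    n = len(catalogue)
    J = np.zeros((3, 3))
    for a, act in enumerate(catalogue):
        ia = _CLASS_INDEX[act.intensity]
        for b, sub in enumerate(catalogue):
            ib = _CLASS_INDEX[sub.intensity]
            k = (1.0 - noise_rate) if a == b else noise_rate / (n - 1)
            J[ia, ib] += pi[a] * k
    return J
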