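"""Parsing and intensity rules for wearable-camera activity annotations.

Free-living validation studies annotate each wearable-camera image with a
Compendium-of-Physical-Activities style string such as
``"occupation;interruption;13030 eating sitting"``: semicolon-separated
context prefixes followed by a terminal segment that usually starts with a
4- or 5-digit Compendium code.  The Compendium entry carries an estimated
MET value (metabolic equivalent of task; 1 MET is the resting rate
convention of 3.5 ml O2 per kg body weight per minute) and, together with
the annotated posture, determines the activity intensity class:

* **SB**   — waking behaviour at <= 1.5 METs in a sitting, lying or
  reclining posture;
* **LIPA** — waking behaviour at < 3 METs not meeting the SB definition;
* **MVPA** — waking behaviour at >= 3 METs;
* **sleep** — non-waking behaviour.

This module also provides the capture-stream statistics used for data
quality assessment (inter-image interval ``delta t`` medians and quartiles,
labelled-hours coverage estimates) and the aggregation of image-timestamp
annotations onto a fixed epoch grid.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SB = "SB"
LIPA = "LIPA"
MVPA = "MVPA"
SLEEP = "sleep"
UNKNOWN = "unknown"

#: Fixed class order used everywhere (confusion matrices, tie-breaking).
INTENSITY_CLASSES = (SB, LIPA, MVPA)
_INTENSITY_INDEX = {c: i for i, c in enumerate(INTENSITY_CLASSES)}

SEDENTARY_POSTURES = frozenset({"sitting", "lying", "reclining"})
POSTURES = ("sitting", "lying", "reclining", "standing", "moving", "unknown")

#: Labels that mark an image as uncodeable; configurable per study.
DEFAULT_UNKNOWN_VOCABULARY = (
    "uncodeable",
    "undefined",
    "image dark/blurred/obscured",
)

# Compendium codes are nominally 5 digits but 4-digit forms (e.g. "5060")
# occur in real annotation exports; both are accepted and the width recorded.
_CODE_RE = re.compile(r"^(\d{4,5})(?:\s+(.*))?$")
_WS_RE = re.compile(r"\s+")

_POSTURE_TOKENS = {
    "sitting": "sitting", "seated": "sitting", "sit": "sitting",
    "lying": "lying", "reclining": "reclining",
    "standing": "standing", "stand": "standing",
    "walking": "moving", "running": "moving", "jogging": "moving",
    "cycling": "moving", "moving": "moving",
}


class InvalidMETError(ValueError):
    """Raised when an intensity is requested for a missing or non-positive MET."""


@dataclass(frozen=True)
class ParsedLabel:
    """Decomposition of one raw annotation string."""
    prefixes: tuple[str, ...]
    compendium_code: int | None
    code_width: int | None
    description: str


def parse_raw_label(raw: str) -> ParsedLabel:
    """Split a raw Compendium-style label into prefixes, code and description.

    The string is split on ``";"``; all but the terminal segment become
    prefixes.  The terminal segment is scanned for a leading 4- or 5-digit
    Compendium code; if none is found the code is absent and the whole
    segment is the description.  Parsing is total: malformed input never
    raises, it simply yields no code.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("raw label must be non-empty text")
    segments = [s.strip() for s in raw.split(";")]
    terminal = segments[-1]
    m = _CODE_RE.match(terminal)
    if m:
        code_str = m.group(1)
        description = (m.group(2) or "").strip()
        return ParsedLabel(tuple(segments[:-1]), int(code_str),
                           len(code_str), description)
    return ParsedLabel(tuple(segments[:-1]), None, None, terminal)


def is_codeable(raw: str,
                unknown_vocabulary: Iterable[str] = DEFAULT_UNKNOWN_VOCABULARY,
                ) -> bool:
    """True unless the label matches the uncodeable vocabulary.

    Matching is case-insensitive after whitespace normalisation and applies
    to the whole string as well as to each semicolon segment, so
    ``"leisure;uncodeable"`` is also flagged.
    """
    patterns = {_WS_RE.sub(" ", p.strip().lower()) for p in unknown_vocabulary}
    norm = _WS_RE.sub(" ", raw.strip().lower())
    if norm in patterns:
        return False
    return not any(seg.strip() in patterns for seg in norm.split(";"))


def assign_intensity(met: float | None, posture: str = "unknown",
                     waking: bool = True) -> str:
    """Map (MET, posture, waking) to an intensity class.

    Total over valid inputs: non-waking behaviour is ``sleep``; otherwise
    exactly one of SB/LIPA/MVPA is returned.  SB requires positive posture
    evidence — at <= 1.5 METs with an *unknown* posture the conservative
    call is LIPA, with a warning, because the sedentary definition is
    posture-conditional.
    """
    if not waking:
        return SLEEP
    if met is None or not math.isfinite(met) or met <= 0:
        raise InvalidMETError(f"MET must be positive and finite, got {met!r}")
    if met <= 1.5:
        if posture in SEDENTARY_POSTURES:
            return SB
        if posture not in ("standing", "moving"):
            warnings.warn(
                f"MET {met} <= 1.5 with posture {posture!r}: classifying as "
                "LIPA because SB requires a sitting/lying/reclining posture",
                stacklevel=2)
        return LIPA
    return LIPA if met < 3 else MVPA


def posture_from_description(description: str) -> str:
    """Heuristic posture from description tokens; 'unknown' when no token matches."""
    for token in _WS_RE.sub(" ", description.lower()).split(" "):
        if token in _POSTURE_TOKENS:
            return _POSTURE_TOKENS[token]
    return "unknown"


# ---------------------------------------------------------------------------
# capture streams and coverage
# ---------------------------------------------------------------------------

@dataclass
class CaptureStats:
    """Inter-image interval statistics for one participant's capture stream."""
    participant_id: object
    delta_t_values: np.ndarray
    delta_t_median: float | None
    delta_t_q1: float | None
    delta_t_q3: float | None
    n_images: int
    n_labelled: int


def _to_seconds(timestamps) -> np.ndarray:
    """Coerce timestamps (numeric seconds, datetimes or ISO strings) to float seconds."""
    arr = np.asarray(timestamps)
    if arr.dtype.kind in "mM" or arr.dtype == object or arr.dtype.kind == "U":
        ts = pd.to_datetime(pd.Series(arr.ravel()), utc=True, format="ISO8601")
        return (ts.astype("int64") / 1e9).to_numpy()
    return arr.astype(float)


def capture_stats(timestamps, labelled_flags=None, participant_id=None,
                  split_gap_s: float = 4 * 3600.0) -> CaptureStats:
    """Successive-difference statistics of one capture stream.

    Timestamps must be strictly increasing.  Gaps longer than
    ``split_gap_s`` (default 4 h) are treated as stream breaks — e.g. the
    camera taken off overnight — and excluded from the interval sample, so
    ``delta_t_values`` has length n-1 per contiguous stream.  Quantiles use
    linear interpolation between order statistics.  Fewer than two
    timestamps yield an empty sample and absent quantiles.
    """
    ts = _to_seconds(timestamps)
    if ts.size > 1 and not np.all(np.diff(ts) > 0):
        raise ValueError("timestamps must be strictly increasing")
    diffs = np.diff(ts)
    dts = diffs[diffs <= split_gap_s]
    if labelled_flags is None:
        n_labelled = ts.size
    else:
        n_labelled = int(np.asarray(labelled_flags, dtype=bool).sum())
    if dts.size == 0:
        return CaptureStats(participant_id, dts, None, None, None,
                            int(ts.size), n_labelled)
    q1, med, q3 = np.percentile(dts, [25, 50, 75])
    return CaptureStats(participant_id, dts, float(med), float(q1), float(q3),
                        int(ts.size), n_labelled)


@dataclass(frozen=True)
class CoverageEstimate:
    """Labelled-time coverage: n_labelled x median delta-t, reported in hours."""
    n_labelled_images: int
    median_delta_t: float
    hours_exact: float
    hours: int  # rounded half-up for reporting


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_time_covered(n_labelled: int, median_delta_t: float) -> CoverageEstimate:
    """Hours of labelled time: ``n_labelled * median_delta_t / 3600``.

    This is the optimistic coverage estimate used to compare sparse
    time-lapse studies with video studies: each labelled image is credited
    with one median capture interval.
    """
    if median_delta_t is None or median_delta_t <= 0:
        raise ValueError("median_delta_t must be positive")
    if n_labelled < 0:
        raise ValueError("n_labelled must be >= 0")
    hours = n_labelled * median_delta_t / 3600.0
    return CoverageEstimate(int(n_labelled), float(median_delta_t),
                            hours, _round_half_up(hours))


# ---------------------------------------------------------------------------
# epoch aggregation
# ---------------------------------------------------------------------------

@dataclass
class EpochLabel:
    participant_id: object
    epoch_start: object
    epoch_length: float
    intensity: str
    support_fraction: float


def aggregate_to_epochs(df: pd.DataFrame, epoch_length: float,
                        time_col: str = "timestamp",
                        label_col: str = "raw_label",
                        intensity_col: str = "intensity",
                        participant_col: str = "participant_id",
                        ) -> pd.DataFrame:
    """Aggregate image-timestamp annotations onto a fixed epoch grid.

    Each maximal run of consecutive images with the same label is treated as
    an activity interval extending from its first to its last image
    timestamp (annotation extent is image-based, not true-boundary based).
    The epoch grid is anchored at the participant's first image with
    half-open epochs ``[start, start + L)``.  Each epoch is assigned the
    intensity with the greatest covered duration inside it; ties break
    towards the higher-intensity class, and epochs with no labelled cover
    get intensity ``unknown``.  ``support_fraction`` is covered-and-labelled
    time divided by the epoch length.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    out: list[EpochLabel] = []
    L = float(epoch_length)
    for pid, grp in df.groupby(participant_col, sort=True):
        grp = grp.sort_values(time_col)
        ts = _to_seconds(grp[time_col].to_numpy())
        if ts.size == 0:
            continue
        labels = grp[label_col].to_numpy()
        intens = grp[intensity_col].to_numpy()
        # run boundaries: label change
        change = np.ones(ts.size, dtype=bool)
        change[1:] = labels[1:] != labels[:-1]
        starts = np.flatnonzero(change)
        ends = np.r_[starts[1:] - 1, ts.size - 1]
        t0 = ts[0]
        n_ep = int((ts[-1] - t0) // L) + 1
        acc = np.zeros((n_ep, len(INTENSITY_CLASSES)))
        for s, e in zip(starts, ends):
            cls = intens[s]
            if cls not in _INTENSITY_INDEX:
                continue
            a, b = ts[s], ts[e]
            if b <= a:
                continue  # single-image runs have zero extent
            ci = _INTENSITY_INDEX[cls]
            i0 = int((a - t0) // L)
            i1 = min(int((b - t0) // L), n_ep - 1)
            for ei in range(i0, i1 + 1):
                es = t0 + ei * L
                ov = min(b, es + L) - max(a, es)
                if ov > 0:
                    acc[ei, ci] += ov
        first = grp[time_col].iloc[0]
        is_datetime = not isinstance(first, (int, float, np.integer, np.floating))
        for ei in range(n_ep):
            covered = acc[ei].sum()
            if covered <= 0:
                cls = UNKNOWN
            else:
                # argmax with ties to the higher class index
                cls = INTENSITY_CLASSES[
                    len(INTENSITY_CLASSES) - 1 - int(np.argmax(acc[ei][::-1]))]
            if is_datetime:
                start = pd.to_datetime(first, utc=True) + pd.to_timedelta(ei * L, unit="s")
            else:
                start = t0 + ei * L
            out.append(EpochLabel(pid, start, L, cls, min(covered / L, 1.0)))
    return pd.DataFrame([vars(e) for e in out],
                        columns=["participant_id", "epoch_start",
                                 "epoch_length", "intensity",
                                 "support_fraction"])


# ---------------------------------------------------------------------------
# ingest and study summaries
# ---------------------------------------------------------------------------

def _lookup_met_posture(parsed: ParsedLabel, met_table: Mapping | None):
    if met_table is None:
        return None, None
    for key in (parsed.compendium_code, parsed.description):
        if key is not None and key in met_table:
            entry = met_table[key]
            return entry.get("met"), entry.get("posture")
    return None, None


def annotate_table(df: pd.DataFrame, met_table: Mapping | None = None,
                   unknown_vocabulary=DEFAULT_UNKNOWN_VOCABULARY,
                   label_col: str = "raw_label") -> pd.DataFrame:
    """Parse every raw label and derive MET, posture and intensity columns.

    ``met_table`` maps Compendium codes (int) and/or descriptions (str) to
    ``{"met": float, "posture": str}``.  Explicit ``met``/``posture``
    columns in the input take precedence over the table; posture falls back
    to description tokens.  Uncodeable rows get intensity ``unknown``.
    """
    df = df.copy()
    prefixes, codes, widths, descs = [], [], [], []
    mets, postures, codeables, intensities = [], [], [], []
    has_met = "met" in df.columns
    has_posture = "posture" in df.columns
    for _, row in df.iterrows():
        raw = row[label_col]
        parsed = parse_raw_label(raw)
        codeable = is_codeable(raw, unknown_vocabulary)
        t_met, t_posture = _lookup_met_posture(parsed, met_table)
        met = row["met"] if has_met and pd.notna(row.get("met")) else t_met
        posture = (row["posture"] if has_posture and pd.notna(row.get("posture"))
                   else t_posture)
        if posture is None:
            posture = posture_from_description(parsed.description)
        if codeable and met is not None and met > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                intensity = assign_intensity(float(met), posture)
        else:
            intensity = UNKNOWN
        prefixes.append(";".join(parsed.prefixes))
        codes.append(parsed.compendium_code)
        widths.append(parsed.code_width)
        descs.append(parsed.description)
        mets.append(met)
        postures.append(posture)
        codeables.append(codeable)
        intensities.append(intensity)
    df["prefixes"] = prefixes
    df["compendium_code"] = pd.array(codes, dtype="Int64")
    df["code_width"] = pd.array(widths, dtype="Int64")
    df["description"] = descs
    df["met"] = mets
    df["posture"] = postures
    df["codeable"] = codeables
    df["intensity"] = intensities
    return df


def summarize_study(df: pd.DataFrame,
                    unknown_vocabulary=DEFAULT_UNKNOWN_VOCABULARY,
                    label_col: str = "raw_label",
                    participant_col: str = "participant_id",
                    intensity_col: str | None = "intensity") -> dict:
    """Study-level summary: labelled counts and fractions, unique labels,
    per-participant class-count medians.

    ``pct_labelled`` is rounded to the nearest integer per cent and
    ``pct_unknown`` to one decimal, matching the usual reporting style.
    """
    n_images = len(df)
    if n_images == 0:
        return {"n_images": 0, "n_labelled": 0, "pct_labelled": None,
                "pct_unknown": None, "n_unique_labels": 0,
                "n_participants": 0, "median_instances_per_participant": {}}
    if "codeable" in df.columns:
        codeable = df["codeable"].astype(bool)
    else:
        codeable = df[label_col].map(
            lambda r: is_codeable(r, unknown_vocabulary))
    n_labelled = int(codeable.sum())
    medians = {}
    if intensity_col is not None and intensity_col in df.columns:
        sub = df[df[intensity_col].isin(INTENSITY_CLASSES)]
        if len(sub):
            counts = (sub.groupby([participant_col, intensity_col])
                      .size().unstack(fill_value=0)
                      .reindex(columns=INTENSITY_CLASSES, fill_value=0))
            medians = {c: float(counts[c].median()) for c in INTENSITY_CLASSES}
    return {
        "n_images": n_images,
        "n_labelled": n_labelled,
        "pct_labelled": round(100.0 * n_labelled / n_images),
        "pct_unknown": round(100.0 * (n_images - n_labelled) / n_images, 1),
        "n_unique_labels": int(df.loc[codeable, label_col].nunique()),
        "n_participants": int(df[participant_col].nunique()),
        "median_instances_per_participant": medians,
    }


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_annotations(path) -> pd.DataFrame:
    """Read a comma-delimited annotation table (participant_id, timestamp,
    raw_label[, met, posture])."""
    df = pd.read_csv(path)
    required = {"participant_id", "timestamp", "raw_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_met_table(path) -> dict:
    """Load a MET/posture lookup table from YAML or CSV.

    YAML: a mapping of code-or-description to ``{met: ..., posture: ...}``.
    CSV: columns ``key, met, posture`` (keys that look like integers are
    treated as Compendium codes).
    """
    import yaml

    path = str(path)
    if path.endswith((".yml", ".yaml")):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        table = {}
        for key, entry in raw.items():
            try:
                key = int(key)
            except (TypeError, ValueError):
                pass
            table[key] = {"met": float(entry["met"]),
                          "posture": entry.get("posture", "unknown")}
        return table
    df = pd.read_csv(path)
    table = {}
    for _, row in df.iterrows():
        key = row["key"]
        try:
            key = int(key)
        except (TypeError, ValueError):
            pass
        table[key] = {"met": float(row["met"]),
                      "posture": row.get("posture", "unknown")}
    return table
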