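"""Zero-shot intensity classification by embedding-space retrieval.

Classification is framed as text retrieval: a query vector — either an
image embedding from a dual-encoder backend, or the embedding of a
generated free-text description — is matched to the most cosine-similar
member of a *target set*.  Targets are either the three intensity phrases
directly ("sedentary behavior", "light physical activity",
"moderate-to-vigorous physical activity") or the more colloquial clean
labels, each of which has a known mapping to an intensity class.

Because nearest-neighbour mapping never checks that an intensity class is
actually implied by a description, predictions whose best-vs-runner-up
similarity margin is small can be exported for human audit
(:func:`low_margin_report`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .annotations import INTENSITY_CLASSES, UNKNOWN
from .embedding import HashedNgramEmbedder, normalize_text

#: Natural-language representations of the intensity classes used as
#: retrieval targets in intensity-direct mode.
DEFAULT_INTENSITY_PHRASES = {
    "SB": "sedentary behavior",
    "LIPA": "light physical activity",
    "MVPA": "moderate-to-vigorous physical activity",
}

DEFAULT_PROMPT = ("Walking, Running, Sitting, Standing, Other. Based on the "
                  "objects in the image, what is the person likely doing?")

#: Seed prompt bank for generative describer backends; prompts are opaque
#: pass-through strings, extend freely via PromptBank.from_file.
DEFAULT_PROMPTS = (
    DEFAULT_PROMPT,
    "Question: What is the intensity of the physical activity in the image? "
    "Options: Sedentary, Light, Moderate-Vigorous. Short answer:",
    "a photo of",
)


class UndefinedSimilarityError(ValueError):
    """Cosine similarity requested for a zero vector."""


class BackendError(RuntimeError):
    """An external describer/encoder backend failed; carries row context."""


@dataclass
class PromptBank:
    prompts: list

    def __post_init__(self):
        if not self.prompts:
            raise ValueError("prompt bank must be non-empty")

    @classmethod
    def default(cls) -> "PromptBank":
        return cls(list(DEFAULT_PROMPTS))

    @classmethod
    def from_file(cls, path) -> "PromptBank":
        with open(path) as fh:
            prompts = [line.rstrip("\n") for line in fh if line.strip()]
        return cls(prompts)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.prompts) + "\n")


def cosine_similarity(u, v) -> float:
    """u.v / (|u||v|), clamped to [-1, 1] against rounding."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedSimilarityError("cosine similarity undefined for zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


class TargetSet:
    """Ordered retrieval targets with their embeddings.

    Parameters
    ----------
    targets : sequence of (target_text, intensity)
        Order matters: ties in retrieval break towards the lowest index.
    embedder : object with ``embed(text)``, optional
    mode : {'intensity_direct', 'clean_label'}
    """

    def __init__(self, targets, embedder=None, mode: str = "clean_label"):
        targets = [(str(t), str(i)) for t, i in targets]
        if not targets:
            raise ValueError("target set must be non-empty")
        texts = [t for t, _ in targets]
        if len(set(texts)) != len(texts):
            raise ValueError("duplicate target texts")
        for _, intensity in targets:
            if intensity not in INTENSITY_CLASSES:
                raise ValueError(f"invalid target intensity {intensity!r}")
        self.mode = mode
        self.targets = targets
        self.embedder = embedder or HashedNgramEmbedder()
        self.embeddings = np.vstack(
            [self.embedder.embed(t) for t in texts])
        norms = np.linalg.norm(self.embeddings, axis=1)
        if np.any(norms == 0):
            raise ValueError("degenerate (zero-vector) target embedding")
        self._unit = self.embeddings / norms[:, None]

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def texts(self):
        return [t for t, _ in self.targets]

    @property
    def intensities(self):
        return [i for _, i in self.targets]

    @classmethod
    def intensity_direct(cls, embedder=None, phrases=None) -> "TargetSet":
        phrases = phrases or DEFAULT_INTENSITY_PHRASES
        targets = [(phrases[c], c) for c in INTENSITY_CLASSES]
        return cls(targets, embedder, mode="intensity_direct")

    @classmethod
    def from_clean_labels(cls, clean_to_intensity: dict,
                          embedder=None) -> "TargetSet":
        return cls(list(clean_to_intensity.items()), embedder,
                   mode="clean_label")

    @classmethod
    def from_csv(cls, path, embedder=None, mode="clean_label") -> "TargetSet":
        df = pd.read_csv(path)
        return cls(list(zip(df["target_text"], df["intensity"])), embedder,
                   mode=mode)


def retrieve_nearest(query, target_set: TargetSet) -> tuple[int, float, float]:
    """Argmax of cosine similarity over the target set.

    Returns (index, similarity, runner-up margin).  Ties break towards the
    lowest target index; a single-target set has margin 0.
    """
    q = np.asarray(query, dtype=float)
    if q.shape != (target_set.embeddings.shape[1],):
        raise ValueError(
            f"query dimension {q.shape} does not match targets "
            f"{target_set.embeddings.shape[1]}")
    nq = np.linalg.norm(q)
    if nq == 0:
        raise UndefinedSimilarityError("zero query vector")
    sims = np.clip(target_set._unit @ (q / nq), -1.0, 1.0)
    idx = int(np.argmax(sims))  # first maximum = lowest index on ties
    best = float(sims[idx])
    if sims.size > 1:
        margin = best - float(np.partition(sims, -2)[-2])
    else:
        margin = 0.0
    return idx, best, max(margin, 0.0)


@dataclass
class PredictionRecord:
    """One image's resolved prediction."""
    description: str | None
    matched_target: str | None
    similarity: float | None
    predicted_intensity: str
    runner_up_margin: float | None
    participant_id: object = None
    timestamp: object = None


def classify_description(description: str, target_set: TargetSet,
                         embedder=None, participant_id=None,
                         timestamp=None) -> PredictionRecord:
    """Embed a free-text description and map it to the nearest target.

    Empty or whitespace-only descriptions yield an 'unknown' prediction
    with absent similarity instead of raising.
    """
    embedder = embedder or target_set.embedder
    norm = normalize_text(description or "")
    if not norm:
        return PredictionRecord(description, None, None, UNKNOWN, None,
                                participant_id, timestamp)
    q = embedder.embed(description)
    if np.linalg.norm(q) == 0:
        return PredictionRecord(description, None, None, UNKNOWN, None,
                                participant_id, timestamp)
    idx, sim, margin = retrieve_nearest(q, target_set)
    text, intensity = target_set.targets[idx]
    return PredictionRecord(description, text, sim, intensity, margin,
                            participant_id, timestamp)


def classify_image_embedding(image_vector, target_set: TargetSet,
                             participant_id=None,
                             timestamp=None) -> PredictionRecord:
    """Retrieval contract of :func:`classify_description` minus the
    text-embedding step (dual-encoder mode: the image vector must share the
    target embedding space)."""
    idx, sim, margin = retrieve_nearest(image_vector, target_set)
    text, intensity = target_set.targets[idx]
    return PredictionRecord(None, text, sim, intensity, margin,
                            participant_id, timestamp)


class ZeroShotIntensityClassifier(ClassifierMixin, BaseEstimator):
    """Zero-shot text-retrieval classifier with the estimator interface.

    ``fit(X, y)`` takes target texts and their intensity classes and embeds
    them (no iterative training happens — "fitting" builds the retrieval
    index); ``predict(X)`` maps free-text descriptions to the intensity of
    their nearest target.  With ``X=None`` at fit time the three default
    intensity phrases are used.

    Parameters
    ----------
    embedder : object with ``embed(text)``, optional
        Deterministic text embedder; defaults to the reference hashed
        n-gram embedder.  Real sentence-embedding backends are drop-in.
    mode : {'intensity_direct', 'clean_label'}
        Recorded on the target set; 'intensity_direct' with default
        targets guarantees predictions in {SB, LIPA, MVPA}.
    """

    def __init__(self, embedder=None, mode: str = "intensity_direct"):
        self.embedder = embedder
        self.mode = mode

    def fit(self, X=None, y=None):
        if X is None:
            self.target_set_ = TargetSet.intensity_direct(self.embedder)
        else:
            X = list(X)
            if y is None or len(X) != len(list(y)):
                raise ValueError("target texts X require aligned intensities y")
            self.target_set_ = TargetSet(list(zip(X, y)), self.embedder,
                                         mode=self.mode)
        self.classes_ = np.unique(self.target_set_.intensities)
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return np.array([classify_description(d, self.target_set_).
                         predicted_intensity for d in X], dtype=object)

    def predict_records(self, X, participant_ids=None,
                        timestamps=None) -> pd.DataFrame:
        """Full prediction table: matched target, similarity, margin."""
        self._check_fitted()
        n = len(X)
        pids = participant_ids if participant_ids is not None else [None] * n
        tss = timestamps if timestamps is not None else [None] * n
        records = [classify_description(d, self.target_set_,
                                        participant_id=p, timestamp=t)
                   for d, p, t in zip(X, pids, tss)]
        return pd.DataFrame([vars(r) for r in records])

    def score(self, X, y):
        """Mean accuracy against true intensity labels."""
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))

    def _check_fitted(self):
        if not hasattr(self, "target_set_"):
            raise RuntimeError("classifier is not fitted")


def run_backend(manifest: pd.DataFrame, backend, prompt: str = DEFAULT_PROMPT,
                ) -> pd.DataFrame:
    """Run a describer backend over a manifest, one output row per input.

    ``backend`` implements ``describe(row, prompt) -> str`` (generative
    mode).  Backend exceptions are re-raised as :class:`BackendError` with
    the offending row's context.  The returned table carries the backend
    identity and prompt in ``DataFrame.attrs``.
    """
    descriptions = []
    for i, row in manifest.iterrows():
        try:
            descriptions.append(backend.describe(row, prompt))
        except Exception as exc:  # surface with row context
            raise BackendError(f"backend failed on row {i} "
                               f"({row.to_dict()!r}): {exc}") from exc
    out = manifest.copy()
    out["description"] = descriptions
    out.attrs["backend"] = repr(backend)
    out.attrs["prompt"] = prompt
    return out


class EchoBackend:
    """Trivial backend echoing a manifest column; used in tests and as the
    reference implementation of the describe contract."""

    def __init__(self, column: str = "description"):
        self.column = column

    def describe(self, row, prompt: str) -> str:
        return row[self.column]

    def __repr__(self) -> str:
        return f"EchoBackend(column={self.column!r})"


def low_margin_report(predictions: pd.DataFrame,
                      threshold: float = 0.05) -> pd.DataFrame:
    """Predictions whose best-vs-runner-up margin falls below ``threshold``
    — candidates for semantic-mismatch audit by a human."""
    mask = predictions["runner_up_margin"].notna() & (
        predictions["runner_up_margin"] < threshold)
    return predictions.loc[mask].copy()
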