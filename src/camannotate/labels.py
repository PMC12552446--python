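"""Semantic deduplication of raw annotation labels ("clean labels").

Raw annotation exports contain near-duplicate labels — misspellings
("office wok/computer work general") and the same activity under different
context prefixes ("walking;5060 shopping miscellaneous" vs "5060 shopping
miscellaneous").  The cleanup workflow embeds the unique labels, builds an
agglomerative-clustering dendrogram (average linkage on cosine distance)
and proposes merge groups at a height threshold.  The durable,
reproducible artifact is the *reviewed merge map* (raw label -> clean
label) together with a clean-label -> intensity table; the clustering only
assists the human review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .annotations import INTENSITY_CLASSES, UNKNOWN
from .embedding import HashedNgramEmbedder, normalize_text


class DegenerateTreeError(ValueError):
    """Raised when clustering is requested for fewer than two labels."""


@dataclass
class LabelEmbedding:
    label: str
    vector: np.ndarray

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vector))


def embed_labels(labels, embedder=None, strip_code_prefixes: bool = False,
                 ) -> list[LabelEmbedding]:
    """Embed the unique labels, preserving first-appearance order.

    Labels are normalised (lowercase, collapsed whitespace) before
    embedding; with ``strip_code_prefixes`` the semicolon prefixes and
    leading Compendium code are removed first, so duplicates that differ
    only by prefixes collapse.
    """
    embedder = embedder or HashedNgramEmbedder()
    unique = list(dict.fromkeys(labels))
    out = []
    for label in unique:
        text = label
        if strip_code_prefixes:
            from .annotations import parse_raw_label
            text = parse_raw_label(label).description or label
        out.append(LabelEmbedding(label, embedder.embed(text)))
    return out


def build_dendrogram(embeddings: list[LabelEmbedding]) -> np.ndarray:
    """Average-linkage agglomerative clustering on cosine distance.

    Returns the scipy linkage matrix (full merge tree with heights).
    Average linkage is reducible, so merge heights are non-decreasing.
    """
    if len(embeddings) < 2:
        raise DegenerateTreeError("need at least 2 labels to cluster")
    X = np.vstack([e.vector for e in embeddings])
    d = np.clip(pdist(X, metric="cosine"), 0.0, None)
    return linkage(d, method="average")


def propose_merges(tree: np.ndarray, labels, height_threshold: float,
                   ) -> list[list[str]]:
    """Cut the dendrogram at a height; returns disjoint label groups
    (ordered by first label appearance) covering every label."""
    if height_threshold < 0:
        raise ValueError("height_threshold must be >= 0")
    labels = list(labels)
    assignments = fcluster(tree, t=height_threshold, criterion="distance")
    groups: dict[int, list[str]] = {}
    for label, cid in zip(labels, assignments):
        groups.setdefault(cid, []).append(label)
    return sorted(groups.values(), key=lambda g: labels.index(g[0]))


@dataclass
class MergeMap:
    """Reviewed raw-label -> clean-label map plus clean-label intensities."""
    entries: dict
    clean_to_intensity: dict = field(default_factory=dict)

    def validate(self) -> None:
        for raw, clean in self.entries.items():
            if not isinstance(clean, str) or not clean:
                raise ValueError(f"raw label {raw!r} maps to invalid clean label")
        for clean, intensity in self.clean_to_intensity.items():
            if intensity not in INTENSITY_CLASSES + (UNKNOWN,):
                raise ValueError(
                    f"clean label {clean!r} has invalid intensity {intensity!r}")

    @classmethod
    def identity(cls, labels) -> "MergeMap":
        return cls({l: l for l in labels})

    @classmethod
    def from_csv(cls, entries_path, intensity_path=None) -> "MergeMap":
        """Load from two-column ``raw_label,clean_label`` (and optionally
        ``clean_label,intensity``) delimited files."""
        df = pd.read_csv(entries_path)
        entries = dict(zip(df["raw_label"], df["clean_label"]))
        intensities = {}
        if intensity_path is not None:
            idf = pd.read_csv(intensity_path)
            intensities = dict(zip(idf["clean_label"], idf["intensity"]))
        mm = cls(entries, intensities)
        mm.validate()
        return mm

    def to_csv(self, entries_path, intensity_path=None) -> None:
        pd.DataFrame(sorted(self.entries.items()),
                     columns=["raw_label", "clean_label"]
                     ).to_csv(entries_path, index=False)
        if intensity_path is not None:
            pd.DataFrame(sorted(self.clean_to_intensity.items()),
                         columns=["clean_label", "intensity"]
                         ).to_csv(intensity_path, index=False)


def apply_merge_map(df: pd.DataFrame, merge_map: MergeMap,
                    label_col: str = "raw_label",
                    codeable_col: str = "codeable",
                    strict: bool = False) -> tuple[pd.DataFrame, list[str]]:
    """Attach a ``clean_label`` column; returns (table, rejects).

    Every codeable annotation must be covered by the map; unmapped codeable
    labels are reported in the rejects list (and raise in strict mode)
    rather than passed through silently.  Row count is never changed.
    """
    merge_map.validate()
    df = df.copy()
    df["clean_label"] = df[label_col].map(merge_map.entries)
    if codeable_col in df.columns:
        unmapped_mask = df["clean_label"].isna() & df[codeable_col].astype(bool)
    else:
        unmapped_mask = df["clean_label"].isna()
    rejects = sorted(df.loc[unmapped_mask, label_col].unique())
    if strict and rejects:
        raise KeyError(f"unmapped codeable labels: {rejects}")
    return df, rejects


class LabelDeduplicator(BaseEstimator):
    """Agglomerative label-deduplication assistant (estimator interface).

    ``fit`` embeds the unique labels and builds the linkage tree;
    ``fit_predict`` / ``predict`` return cluster ids at
    ``distance_threshold``; :meth:`propose` returns the merge groups and
    :meth:`to_merge_map` a draft map (first group member as clean label)
    intended for human review.

    Parameters
    ----------
    embedder : object with ``embed(text)``, optional
        Defaults to the reference hashed n-gram embedder.
    distance_threshold : float
        Cosine-distance cut height for proposing merge groups.
    strip_code_prefixes : bool
        Remove semicolon prefixes and Compendium codes before embedding.
    """

    def __init__(self, embedder=None, distance_threshold: float = 0.3,
                 strip_code_prefixes: bool = False):
        self.embedder = embedder
        self.distance_threshold = distance_threshold
        self.strip_code_prefixes = strip_code_prefixes

    def fit(self, X, y=None):
        embedder = self.embedder or HashedNgramEmbedder()
        self.embeddings_ = embed_labels(X, embedder,
                                        self.strip_code_prefixes)
        self.labels_in_ = [e.label for e in self.embeddings_]
        self.linkage_ = build_dendrogram(self.embeddings_)
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        return fcluster(self.linkage_, t=self.distance_threshold,
                        criterion="distance")

    def propose(self, height_threshold: float | None = None) -> list[list[str]]:
        if not hasattr(self, "linkage_"):
            raise RuntimeError("fit the deduplicator first")
        t = (self.distance_threshold if height_threshold is None
             else height_threshold)
        return propose_merges(self.linkage_, self.labels_in_, t)

    def to_merge_map(self, height_threshold: float | None = None) -> MergeMap:
        groups = self.propose(height_threshold)
        entries = {}
        for group in groups:
            clean = normalize_text(group[0])
            for raw in group:
                entries[raw] = clean
        return MergeMap(entries)
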