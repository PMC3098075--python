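"""Similarity between symptom names through their prescribed remedies.

Three metrics over remedy bags (multisets of remedy occurrences):

* set-based Jaccard on remedy supports;
* TF-IDF weighted cosine, where a remedy's weight for a symptom is its
  occurrence frequency times log(N / df), df being the number of symptom
  bags containing the remedy;
* truncated bipartite SimRank over the symptom-remedy graph: two symptoms
  are similar if their remedies are similar, and two remedies are similar
  if they treat similar symptoms.  Scores propagate through a decay factor
  C and the recursion is cut off after a fixed number of iterations
  (default 4).

Symptom keys are opaque and hashable; the pipeline uses (name, role) pairs
so that identical spellings on the standard and clinical sides stay
distinct nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import RemedyBag

__all__ = [
    "jaccard_similarity",
    "TfidfModel",
    "fit_tfidf",
    "cosine_similarity",
    "BipartiteGraph",
    "SimRankState",
    "simrank",
    "RemedyContext",
    "remedy_similarity",
    "REMEDY_METHODS",
]

Key = Hashable


def jaccard_similarity(remedies: Iterable[str], remedies2: Iterable[str]) -> float:
    """|R ∩ R'| / |R ∪ R'|; two empty sets score 0 by convention."""
    a, b = set(remedies), set(remedies2)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


@dataclass
class TfidfModel:
    """TF-IDF weighted remedy vectors for a collection of symptom bags.

    ``idf_base`` selects the numerator N of the idf term log(N / df_j):
    ``symptom_count`` (the number of symptom bags, standard document-count
    semantics, the default) or ``remedy_count`` (the size of the remedy
    vocabulary).
    """

    doc_index: dict[Key, int]
    remedy_index: dict[str, int]
    matrix: np.ndarray  # docs x remedies, dense weights
    df: dict[str, int]
    idf_base: str = "symptom_count"
    _norms: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._norms = np.linalg.norm(self.matrix, axis=1)

    @property
    def n_docs(self) -> int:
        return len(self.doc_index)

    @property
    def n_remedies(self) -> int:
        return len(self.remedy_index)

    def vector(self, key: Key) -> np.ndarray:
        return self.matrix[self.doc_index[key]]

    def cosine(self, key: Key, key2: Key) -> float:
        """Cosine between two fitted documents; 0 if either norm is 0."""
        i, j = self.doc_index[key], self.doc_index[key2]
        denom = self._norms[i] * self._norms[j]
        if denom == 0.0:
            return 0.0
        # rounding can push a self-cosine a ulp past 1
        return float(min(np.dot(self.matrix[i], self.matrix[j]) / denom, 1.0))


def fit_tfidf(bags: Mapping[Key, RemedyBag], idf_base: str = "symptom_count") -> TfidfModel:
    """Fit TF-IDF weights w = f * log(N / df) over a bag collection."""
    if not bags:
        raise ValueError("fit_tfidf requires at least one remedy bag")
    if idf_base not in ("symptom_count", "remedy_count"):
        raise ValueError(f"unknown idf_base {idf_base!r}")
    doc_index = {key: i for i, key in enumerate(bags)}
    remedies = sorted({r for bag in bags.values() for r in bag.counts})
    remedy_index = {r: j for j, r in enumerate(remedies)}
    df = {r: 0 for r in remedies}
    for bag in bags.values():
        for r in bag.counts:
            df[r] += 1
    n = len(bags) if idf_base == "symptom_count" else len(remedies)
    idf = np.array([math.log(n / df[r]) if df[r] > 0 else 0.0 for r in remedies])
    # log(N/df) can go negative when df exceeds the remedy-count numerator;
    # negative weights would break the [0,1] cosine contract, so floor at 0.
    idf = np.maximum(idf, 0.0)
    matrix = np.zeros((len(bags), len(remedies)))
    for key, bag in bags.items():
        i = doc_index[key]
        for r, f in bag.counts.items():
            matrix[i, remedy_index[r]] = f * idf[remedy_index[r]]
    return TfidfModel(doc_index=doc_index, remedy_index=remedy_index, matrix=matrix,
                      df=df, idf_base=idf_base)


def cosine_similarity(v: np.ndarray, v2: np.ndarray) -> float:
    """Cosine of two non-negative weight vectors; 0 if either norm is 0."""
    v = np.asarray(v, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    denom = np.linalg.norm(v) * np.linalg.norm(v2)
    if denom == 0.0:
        return 0.0
    return float(min(np.dot(v, v2) / denom, 1.0))


@dataclass
class BipartiteGraph:
    """Symptom-remedy incidence graph built from remedy-bag supports."""

    symptoms: list[Key]
    remedies: list[str]
    adjacency: np.ndarray  # bool, len(symptoms) x len(remedies)

    @classmethod
    def from_bags(cls, bags: Mapping[Key, RemedyBag]) -> "BipartiteGraph":
        symptoms = list(bags)
        remedies = sorted({r for bag in bags.values() for r in bag.counts})
        remedy_index = {r: j for j, r in enumerate(remedies)}
        adjacency = np.zeros((len(symptoms), len(remedies)), dtype=bool)
        for i, key in enumerate(symptoms):
            for r in bags[key].counts:
                adjacency[i, remedy_index[r]] = True
        return cls(symptoms=symptoms, remedies=remedies, adjacency=adjacency)


@dataclass
class SimRankState:
    """Paired similarity tables after k truncated SimRank iterations."""

    symptoms: list[Key]
    remedies: list[str]
    sim_s: np.ndarray  # symptom x symptom
    sim_r: np.ndarray  # remedy x remedy
    k: int
    C: float
    _s_index: dict[Key, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._s_index = {key: i for i, key in enumerate(self.symptoms)}

    def symptom_similarity(self, key: Key, key2: Key) -> float:
        return float(self.sim_s[self._s_index[key], self._s_index[key2]])


def simrank(graph: BipartiteGraph, C: float = 0.8, k_max: int = 4) -> SimRankState:
    """Truncated bipartite SimRank from the identity initialization.

    Each iteration updates, for s != s',

        SimS_k(s,s') = C/(|R||R'|) * sum_{i,j} SimR_{k-1}(r_i, r'_j)

    over the remedy neighborhoods of s and s', and symmetrically for
    remedy pairs over their symptom neighborhoods; both updates read the
    previous iteration's tables.  Diagonals stay pinned at 1; a pair with
    an empty neighborhood on either side scores 0.
    """
    if not 0.0 < C < 1.0:
        raise ValueError("decay factor C must be in (0, 1)")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    adj = graph.adjacency.astype(float)
    n_s, n_r = adj.shape
    deg_s = adj.sum(axis=1)
    deg_r = adj.sum(axis=0)
    # Row-normalized incidence: P[s, r] = 1/|R(s)| for r in R(s).
    with np.errstate(divide="ignore", invalid="ignore"):
        p_s = np.where(deg_s[:, None] > 0, adj / np.maximum(deg_s[:, None], 1), 0.0)
        p_r = np.where(deg_r[None, :] > 0, adj / np.maximum(deg_r[None, :], 1), 0.0)
    sim_s = np.eye(n_s)
    sim_r = np.eye(n_r)
    for _ in range(k_max):
        new_s = C * (p_s @ sim_r @ p_s.T)
        new_r = C * (p_r.T @ sim_s @ p_r)
        np.fill_diagonal(new_s, 1.0)
        np.fill_diagonal(new_r, 1.0)
        sim_s, sim_r = new_s, new_r
    return SimRankState(symptoms=graph.symptoms, remedies=graph.remedies,
                        sim_s=sim_s, sim_r=sim_r, k=k_max, C=C)


REMEDY_METHODS = ("set", "vsm_tfidf", "simrank")


@dataclass
class RemedyContext:
    """Fitted models shared by the remedy-based metrics.

    Only the models needed by the requested methods have to be fitted;
    a symptom key absent from ``bags`` is treated as having an empty bag
    and scores 0 against everything.
    """

    bags: Mapping[Key, RemedyBag]
    tfidf: TfidfModel | None = None
    simrank: SimRankState | None = None

    @classmethod
    def fit(
        cls,
        bags: Mapping[Key, RemedyBag],
        methods: Sequence[str] = REMEDY_METHODS,
        idf_base: str = "symptom_count",
        C: float = 0.8,
        k_max: int = 4,
    ) -> "RemedyContext":
        tfidf = fit_tfidf(bags, idf_base=idf_base) if "vsm_tfidf" in methods else None
        state = simrank(BipartiteGraph.from_bags(bags), C=C, k_max=k_max) \
            if "simrank" in methods else None
        return cls(bags=bags, tfidf=tfidf, simrank=state)


def remedy_similarity(key: Key, key2: Key, method: str, context: RemedyContext) -> float:
    """Uniform facade over the three remedy-based metrics."""
    if method not in REMEDY_METHODS:
        raise ValueError(f"unknown remedy method {method!r}; expected one of {REMEDY_METHODS}")
    bag = context.bags.get(key)
    bag2 = context.bags.get(key2)
    if bag is None or bag2 is None or not bag.counts or not bag2.counts:
        return 0.0
    if method == "set":
        return jaccard_similarity(bag.support, bag2.support)
    if method == "vsm_tfidf":
        if context.tfidf is None:
            raise RuntimeError("TF-IDF model not fitted; build the context with 'vsm_tfidf'")
        return context.tfidf.cosine(key, key2)
    if context.simrank is None:
        raise RuntimeError("SimRank state not fitted; build the context with 'simrank'")
    return context.simrank.symptom_similarity(key, key2)
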