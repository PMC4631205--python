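"""Presence/absence comparison of a model ensemble.

Tissue- or condition-specific GEMs derived from a common generic network
differ in which reactions, metabolites and genes they retain. This module
quantifies that divergence per element class:

* pairwise Hamming distances (size of the symmetric difference between two
  models' element sets) with their directed decomposition |A\\B| and |B\\A| —
  the number of element changes required to transform one model into the
  other, in each direction;
* per-model average distance to all other ensemble members;
* a heterogeneity degree = mean / max pairwise distance, a dimensionless
  [0, 1] summary of ensemble divergence (0 when all models coincide);
* core/unique statistics: how many elements are shared by every model,
  and how many are private to a single one.

Distances are raw counts, never normalized by union size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .model_core import ElementSets

__all__ = [
    "PresenceMatrix",
    "DistanceReport",
    "HeterogeneityReport",
    "CoreStats",
    "presence_matrix",
    "pairwise_distances",
    "heterogeneity",
    "core_statistics",
]

ELEMENT_CLASSES = ("reaction", "metabolite", "gene")

_CLASS_ATTR = {
    "reaction": "reaction_ids",
    "metabolite": "metabolite_ids",
    "gene": "gene_ids",
}


@dataclass
class PresenceMatrix:
    """Binary model x element matrix for one element class."""

    data: pd.DataFrame           # index: model ids, columns: element ids
    element_class: str

    @property
    def model_ids(self) -> list[str]:
        return list(self.data.index)

    def row_set(self, model_id: str) -> frozenset[str]:
        row = self.data.loc[model_id]
        return frozenset(row.index[row == 1])


def presence_matrix(models_or_sets, element_class: str,
                    model_ids: list[str] | None = None) -> PresenceMatrix:
    """Build the binary matrix over the union of the ensemble's elements.

    Accepts :class:`ElementSets` records or plain sets of element ids.
    """
    if element_class not in ELEMENT_CLASSES:
        raise ValueError(f"element_class must be one of {ELEMENT_CLASSES}")
    sets = []
    for item in models_or_sets:
        if isinstance(item, ElementSets):
            sets.append(frozenset(getattr(item, _CLASS_ATTR[element_class])))
        else:
            sets.append(frozenset(item))
    if len(sets) < 2:
        raise ValueError("need at least two element-set records")
    if model_ids is None:
        model_ids = [f"model_{i}" for i in range(len(sets))]
    if len(model_ids) != len(set(model_ids)):
        raise ValueError(f"duplicate model ids: {model_ids}")
    union = sorted(set().union(*sets))
    data = pd.DataFrame(
        [[1 if el in s else 0 for el in union] for s in sets],
        index=model_ids, columns=union, dtype=int)
    return PresenceMatrix(data=data, element_class=element_class)


@dataclass
class PairDistance:
    total: int        # Hamming distance = |A \ B| + |B \ A|
    a_minus_b: int    # elements to drop going A -> B
    b_minus_a: int    # elements to gain going A -> B


@dataclass
class DistanceReport:
    element_class: str
    pairs: dict[tuple[str, str], PairDistance] = field(default_factory=dict)
    average: dict[str, float] = field(default_factory=dict)

    def distance(self, a: str, b: str) -> int:
        if (a, b) in self.pairs:
            return self.pairs[(a, b)].total
        return self.pairs[(b, a)].total

    def to_frame(self) -> pd.DataFrame:
        rows = [{"model_a": a, "model_b": b, "total": d.total,
                 "a_minus_b": d.a_minus_b, "b_minus_a": d.b_minus_a}
                for (a, b), d in self.pairs.items()]
        return pd.DataFrame(rows)


def pairwise_distances(matrix: PresenceMatrix) -> DistanceReport:
    """Hamming distances over all unordered model pairs, decomposed by
    direction, plus each model's average distance to the rest."""
    report = DistanceReport(element_class=matrix.element_class)
    ids = matrix.model_ids
    sets = {m: matrix.row_set(m) for m in ids}
    totals = {m: 0 for m in ids}
    for a, b in combinations(ids, 2):
        ab = len(sets[a] - sets[b])
        ba = len(sets[b] - sets[a])
        report.pairs[(a, b)] = PairDistance(total=ab + ba, a_minus_b=ab,
                                            b_minus_a=ba)
        totals[a] += ab + ba
        totals[b] += ab + ba
    for m in ids:
        report.average[m] = totals[m] / (len(ids) - 1)
    return report


@dataclass
class HeterogeneityReport:
    element_class: str
    mean_distance: float
    max_distance: int
    heterogeneity_degree: float   # mean / max, 0 when max == 0


def heterogeneity(matrix: PresenceMatrix) -> HeterogeneityReport:
    report = pairwise_distances(matrix)
    totals = [d.total for d in report.pairs.values()]
    mx = max(totals)
    mean = sum(totals) / len(totals)
    return HeterogeneityReport(
        element_class=matrix.element_class,
        mean_distance=mean,
        max_distance=mx,
        heterogeneity_degree=(mean / mx) if mx > 0 else 0.0,
    )


@dataclass
class CoreStats:
    element_class: str
    union_count: int
    core_count: int      # present in every model
    unique_count: int    # present in exactly one model
    core_percentage: float

    def __post_init__(self):
        assert self.core_count <= self.union_count
        assert self.unique_count <= self.union_count


def core_statistics(matrix: PresenceMatrix) -> CoreStats:
    """Union / core / unique counts; core percentage to one decimal."""
    col_sums = matrix.data.sum(axis=0)
    n_models = len(matrix.model_ids)
    union = int((col_sums > 0).sum())
    core = int((col_sums == n_models).sum())
    unique = int((col_sums == 1).sum())
    pct = round(100.0 * core / union, 1) if union else 0.0
    return CoreStats(element_class=matrix.element_class, union_count=union,
                     core_count=core, unique_count=unique,
                     core_percentage=pct)
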