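"""External clustering accuracy against ground-truth labels.

The Rand index between two partitions X and Y of the same object set is

    R = (a + b) / C(N, 2),

with a the number of object pairs co-clustered in both partitions and b the
number separated in both. R is 1 iff the partitions are identical up to label
renaming. When only part of a dataset carries ground-truth labels, the index
is computed on the labelled subset alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.metrics import adjusted_rand_score

from .clustering import Clustering

__all__ = ["LabeledPartition", "rand_index", "evaluate_on_subset",
           "adjusted_rand"]


@dataclass
class LabeledPartition:
    ids: list[str]
    labels: list  # subset names or cluster indices

    def validate(self) -> None:
        if len(self.ids) != len(self.labels):
            raise ValueError("ids and labels differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in partition")

    @classmethod
    def from_clustering(cls, clustering: Clustering) -> "LabeledPartition":
        return cls(ids=list(clustering.ids), labels=list(clustering.labels))

    @classmethod
    def from_tsv(cls, path) -> "LabeledPartition":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["model_id", "label"], dtype=str)
        p = cls(ids=df["model_id"].tolist(), labels=df["label"].tolist())
        p.validate()
        return p

    def restricted_to(self, ids) -> "LabeledPartition":
        wanted = set(ids)
        pairs = [(i, l) for i, l in zip(self.ids, self.labels) if i in wanted]
        return LabeledPartition(ids=[p[0] for p in pairs],
                                labels=[p[1] for p in pairs])


def _aligned_labels(x: LabeledPartition, y: LabeledPartition):
    x.validate()
    y.validate()
    if set(x.ids) != set(y.ids):
        raise ValueError("partitions cover different id sets")
    pos = {i: t for t, i in enumerate(x.ids)}
    lx = np.asarray(x.labels, dtype=object)
    ly = np.empty(len(x.ids), dtype=object)
    for i, l in zip(y.ids, y.labels):
        ly[pos[i]] = l
    return lx, ly


def rand_index(x: LabeledPartition, y: LabeledPartition) -> float:
    """Fraction of object pairs on which the two partitions agree."""
    lx, ly = _aligned_labels(x, y)
    n = len(lx)
    if n < 2:
        raise ValueError("Rand index needs at least 2 objects")
    ct = pd.crosstab(pd.Series(lx), pd.Series(ly)).to_numpy()
    a = comb(ct, 2).sum()  # co-clustered in both
    same_x = comb(ct.sum(axis=1), 2).sum()
    same_y = comb(ct.sum(axis=0), 2).sum()
    total = comb(n, 2)
    b = total - same_x - same_y + a  # separated in both
    return float((a + b) / total)


def adjusted_rand(x: LabeledPartition, y: LabeledPartition) -> float:
    """Chance-corrected Rand index (reported alongside, clearly non-plain)."""
    lx, ly = _aligned_labels(x, y)
    codes_x = pd.factorize(lx)[0]
    codes_y = pd.factorize(ly)[0]
    return float(adjusted_rand_score(codes_x, codes_y))


def evaluate_on_subset(clustering: Clustering, truth: LabeledPartition) -> float:
    """Rand index restricted to the ids carrying ground-truth labels."""
    truth.validate()
    cluster_part = LabeledPartition.from_clustering(clustering)
    common = [i for i in truth.ids if i in set(cluster_part.ids)]
    if not common:
        raise ValueError("no overlap between clustering ids and truth ids")
    return rand_index(cluster_part.restricted_to(common),
                      truth.restricted_to(common))
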