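"""MIML-kNN baseline: neighbor/citer voting over Hausdorff bag distances.

For a query bag X, the *references* are its ``n_neighbors`` nearest
training bags; the *citers* are the training bags that would count X among
their own ``n_citers`` nearest when X joins the training pool. Label l is
scored as the fraction of bags in references ∪ citers that carry l, with a
positive call at score ≥ 0.5. Distance ties break toward the lower training
index. The original method's second-stage linear transform of neighbor
label counts is deliberately simplified to direct voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bagdist import pairwise_bag_distances
from .datamodel import LabelMatrix


@dataclass
class MIMLkNN:
    n_neighbors: int = 10
    n_citers: int = 20
    distance: str = "avg"
    _train_bags: list = field(default_factory=list, repr=False)
    _train_labels: np.ndarray | None = field(default=None, repr=False)
    _D_train: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.n_citers < 0:
            raise ValueError("n_citers must be >= 0")
        if self.distance not in ("avg", "max"):
            raise ValueError(f"unknown distance {self.distance!r}")

    def fit(self, bags, Y: LabelMatrix, D: np.ndarray | None = None):
        if len(bags) == 0:
            raise ValueError("empty training set")
        if self.n_neighbors > len(bags):
            raise ValueError(
                f"n_neighbors={self.n_neighbors} exceeds training size {len(bags)}"
            )
        self._train_bags = list(bags)
        self._train_labels = Y.values.astype(np.int8)
        self._D_train = (
            D if D is not None else pairwise_bag_distances(bags, metric=self.distance)
        )
        return self

    def predict(self, bags=None, D_to_train: np.ndarray | None = None):
        """Score query bags; returns (score matrix, binary matrix).

        ``D_to_train`` (n_query × m_train) may carry precomputed distances.
        """
        if self._train_labels is None:
            raise ValueError("model is not fitted")
        if D_to_train is None:
            D_to_train = pairwise_bag_distances(
                bags, self._train_bags, metric=self.distance
            )
        m = len(self._train_bags)
        n = D_to_train.shape[0]
        L = self._train_labels.shape[1]
        scores = np.zeros((n, L))
        for q in range(n):
            d_q = D_to_train[q]
            # references: n_neighbors nearest training bags (stable => low index wins ties)
            refs = np.argsort(d_q, kind="stable")[: self.n_neighbors]
            voters = set(int(i) for i in refs)
            if self.n_citers > 0:
                # citers: training bags having the query among their n_citers
                # nearest within training ∪ {query}
                for i in range(m):
                    # distances from training bag i to the other training
                    # bags plus the query; the query sits in the final slot,
                    # so a tying training bag (earlier position) outranks it
                    row = np.append(self._train_D_row_without_self(i), d_q[i])
                    order = np.argsort(row, kind="stable")
                    pos_of_query = int(np.flatnonzero(order == len(row) - 1)[0])
                    if pos_of_query < self.n_citers:
                        voters.add(i)
            voters = sorted(voters)
            scores[q] = self._train_labels[voters].mean(axis=0)
        return scores, (scores >= 0.5).astype(np.int8)

    def _train_D_row_without_self(self, i: int) -> np.ndarray:
        row = self._D_train[i].copy()
        return np.delete(row, i)
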