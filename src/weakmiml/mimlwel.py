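"""The MIMLwel learner: weak-label MIML with coupled linear predictors.

Pipeline: each bag X is mapped to a fixed-length vector Φ^C(X) of RBF
responses to K medoid bags (average-Hausdorff k-medoids over the training
bags, K = round(α·m)) plus a bias coordinate, with kernel width μ·δ where δ
is the mean nearest-medoid distance. Per-label linear predictors
f_l(X) = w_l^T Φ^C(X) are trained on ±1-coded targets with squared loss.

Labels judged related (cosine similarity of observed columns ≥ τ) share a
group-sparsity penalty: for each related pair the stacked predictor pair
[w_l w_l~] is penalized by its squared (2,1)-norm, pushing entire embedding
coordinates to be jointly (un)used — the formalization of "highly relevant
labels usually share common instances".

Because observed zeros are unknowns, the learner also completes the label
matrix: alternating with the predictor fit, a corrected matrix Ȳ ≥ Ŷ flips
at most ⌊ε·‖Ŷ_l‖₁⌋ unobserved entries per label to positive, choosing the
highest-scoring candidates and only where the score is positive. Both steps
decrease the joint objective, so the recorded trace is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .bagdist import avg_hausdorff, k_medoids, pairwise_bag_distances
from .datamodel import LabelMatrix
from .weak_label import MaskingConfig  # noqa: F401  (re-export convenience)

SMOOTHING = 1e-8  # ς in the smoothed row norm sqrt(. + ς²)


@dataclass
class BagEmbeddingModel:
    """Hausdorff k-medoids RBF bag embedding Φ^C with width scale μ."""

    medoids: list  # the K medoid bags
    medoid_indices: list  # their indices in the training set
    delta: float  # base kernel width δ
    mu: float
    alpha: float

    @property
    def K(self) -> int:
        return len(self.medoids)

    @property
    def dim(self) -> int:
        return self.K + 1  # bias


@dataclass
class RelationMatrix:
    """Symmetric binary label-relation matrix with zero diagonal."""

    values: np.ndarray
    threshold: float

    def __post_init__(self):
        R = np.asarray(self.values)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("relation matrix must be square")
        if not np.array_equal(R, R.T):
            raise ValueError("relation matrix must be symmetric")
        if np.any(np.diag(R) != 0):
            raise ValueError("relation matrix must have zero diagonal")
        self.values = R.astype(np.int8)

    def pairs(self):
        """Related (l, l~) pairs with l < l~."""
        iu = np.triu_indices_from(self.values, k=1)
        mask = self.values[iu] == 1
        return list(zip(iu[0][mask], iu[1][mask]))


@dataclass
class MIMLwelModel:
    W: np.ndarray  # d × L
    Y_bar: LabelMatrix  # corrected training labels
    eta: float
    epsilon: float
    embedding: BagEmbeddingModel
    relations: RelationMatrix
    trace: list = field(default_factory=list)


def fit_bag_embedding(
    bags, alpha: float, mu: float, seed: int = 0, D: np.ndarray | None = None
) -> BagEmbeddingModel:
    """Cluster the training bags and fix the RBF width.

    K = max(1, round(α·m)); δ is the mean distance of a training bag to its
    nearest medoid (with fallbacks for the degenerate all-coincident case).
    ``D`` may carry precomputed pairwise average-Hausdorff distances.
    """
    m = len(bags)
    if m == 0:
        raise ValueError("empty bag list")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if D is None:
        D = pairwise_bag_distances(bags)
    K = max(1, int(np.round(alpha * m)))
    medoid_idx = k_medoids(K=K, seed=seed, D=D)
    delta = float(D[:, medoid_idx].min(axis=1).mean())
    if delta == 0.0:
        med_D = D[np.ix_(medoid_idx, medoid_idx)]
        positive = med_D[med_D > 0]
        delta = float(positive.min()) if positive.size else 1.0
    return BagEmbeddingModel(
        medoids=[bags[i] for i in medoid_idx],
        medoid_indices=list(medoid_idx),
        delta=delta,
        mu=mu,
        alpha=alpha,
    )


def embed(model: BagEmbeddingModel, bag) -> np.ndarray:
    """Φ^C(X): RBF responses to each medoid plus a trailing bias 1."""
    d = np.array([avg_hausdorff(bag, med) for med in model.medoids])
    return np.append(np.exp(-(d**2) / (2.0 * (model.mu * model.delta) ** 2)), 1.0)


def embed_many(
    model: BagEmbeddingModel, bags=None, D_to_train: np.ndarray | None = None
) -> np.ndarray:
    """Embed a collection of bags; rows are Φ^C vectors.

    ``D_to_train`` (n_bags × m_train average-Hausdorff distances) lets
    cross-validation reuse one precomputed matrix instead of re-measuring.
    """
    if D_to_train is not None:
        d = D_to_train[:, model.medoid_indices]
    else:
        d = pairwise_bag_distances(bags, model.medoids)
    phi = np.exp(-(d**2) / (2.0 * (model.mu * model.delta) ** 2))
    return np.hstack([phi, np.ones((phi.shape[0], 1))])


def build_relation_matrix(Y_hat: LabelMatrix, tau: float = 0.5) -> RelationMatrix:
    """Relate label pairs whose observed columns have cosine similarity ≥ τ."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    Y = Y_hat.values.astype(float)
    norms = np.linalg.norm(Y, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    cos = (Y.T @ Y) / np.outer(safe, safe)
    # zero-norm columns are unrelated to everything, even at tau = 0
    cos[norms == 0, :] = -1.0
    cos[:, norms == 0] = -1.0
    R = (cos >= tau).astype(np.int8)
    np.fill_diagonal(R, 0)
    return RelationMatrix(R, tau)


def group_penalty(W: np.ndarray, pairs, smoothing: float = SMOOTHING) -> float:
    """Σ over related pairs of the squared (smoothed) (2,1)-norm of [w_l w_l~]."""
    total = 0.0
    for l, lt in pairs:
        rows = np.sqrt(W[:, l] ** 2 + W[:, lt] ** 2 + smoothing**2)
        total += rows.sum() ** 2
    return float(total)


def _objective_and_grad(W, Phi, T, eta, pairs, smoothing):
    resid = Phi @ W - T
    loss = eta * float((resid**2).sum())
    grad = 2.0 * eta * (Phi.T @ resid)
    pen = 0.0
    for l, lt in pairs:
        rows = np.sqrt(W[:, l] ** 2 + W[:, lt] ** 2 + smoothing**2)
        s = rows.sum()
        pen += s**2
        grad[:, l] += 2.0 * s * W[:, l] / rows
        grad[:, lt] += 2.0 * s * W[:, lt] / rows
    return loss + pen, grad


def _w_step(Phi, T, eta, pairs, W0, max_inner=500, tol=1e-10):
    shape = W0.shape

    def fun(w_flat):
        f, g = _objective_and_grad(
            w_flat.reshape(shape), Phi, T, eta, pairs, SMOOTHING
        )
        return f, g.ravel()

    res = minimize(
        fun,
        W0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_inner, "ftol": tol, "gtol": 1e-12},
    )
    return res.x.reshape(shape)


def _y_step(F, Y_hat, epsilon):
    """Exact minimizer of the loss over feasible corrections given scores F.

    Per label, flip to 1 the top-⌊ε·‖Ŷ_l‖₁⌋ unobserved entries by score,
    only where the score is strictly positive; observed positives persist.
    """
    Y_bar = Y_hat.copy()
    for l in range(Y_hat.shape[1]):
        budget = int(np.floor(epsilon * Y_hat[:, l].sum()))
        if budget == 0:
            continue
        candidates = np.flatnonzero((Y_hat[:, l] == 0) & (F[:, l] > 0))
        if candidates.size == 0:
            continue
        order = candidates[np.argsort(-F[candidates, l], kind="stable")]
        Y_bar[order[:budget], l] = 1
    return Y_bar


def fit_mimlwel(
    embeddings: np.ndarray,
    Y_hat: LabelMatrix,
    R: RelationMatrix,
    eta: float = 1.0,
    epsilon: float = 0.2,
    max_outer: int = 20,
    tol: float = 1e-10,
    embedding_model: BagEmbeddingModel | None = None,
) -> MIMLwelModel:
    """Alternating optimization of predictors W and corrected labels Ȳ.

    W-step: minimize η·Σ_l Σ_i (w_l^T φ_i − (2ȳ_{i,l}−1))² plus the group
    penalty over related pairs (smoothed, quasi-Newton descent to relative
    objective change below tolerance or 500 inner iterations). Ȳ-step: the
    budgeted positive-score completion. Stops when Ȳ is unchanged or after
    ``max_outer`` rounds; the objective trace is non-increasing.
    """
    Phi = np.asarray(embeddings, dtype=float)
    if not np.isfinite(Phi).all():
        raise ValueError("non-finite embeddings")
    if eta <= 0:
        raise ValueError(f"eta must be positive, got {eta}")
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    Yh = Y_hat.values.astype(np.int8)
    m, L = Yh.shape
    if Phi.shape[0] != m or R.values.shape != (L, L):
        raise ValueError("inconsistent shapes between embeddings, labels, relations")

    pairs = R.pairs()
    W = np.zeros((Phi.shape[1], L))
    Y_bar = Yh.copy()
    trace = []
    for _ in range(max_outer):
        T = 2.0 * Y_bar - 1.0
        W = _w_step(Phi, T, eta, pairs, W, tol=tol)
        F = Phi @ W
        Y_new = _y_step(F, Yh, epsilon)
        T_new = 2.0 * Y_new - 1.0
        obj = eta * float(((Phi @ W - T_new) ** 2).sum()) + group_penalty(W, pairs)
        trace.append(obj)
        if np.array_equal(Y_new, Y_bar):
            Y_bar = Y_new
            break
        Y_bar = Y_new
    return MIMLwelModel(
        W=W,
        Y_bar=LabelMatrix(Y_bar, "corrected"),
        eta=eta,
        epsilon=epsilon,
        embedding=embedding_model,
        relations=R,
        trace=trace,
    )


def predict(model: MIMLwelModel, bags=None, embeddings: np.ndarray | None = None):
    """Score unseen bags: f_l(X) = w_l^T Φ^C(X); positive call iff score > 0."""
    if model.W is None:
        raise ValueError("model is not fitted")
    if embeddings is None:
        if model.embedding is None:
            raise ValueError("model carries no embedding; pass embeddings explicitly")
        embeddings = embed_many(model.embedding, bags)
    scores = embeddings @ model.W
    return scores, (scores > 0).astype(np.int8)


def save_model(model: MIMLwelModel, path, label_space=None) -> None:
    """Serialize a fitted model (predictors, embedding, relations) as JSON."""
    import json

    doc = {
        "schema_version": 1,
        "W": model.W.tolist(),
        "Y_bar": model.Y_bar.values.tolist(),
        "eta": model.eta,
        "epsilon": model.epsilon,
        "trace": list(model.trace),
        "relations": {
            "values": model.relations.values.tolist(),
            "threshold": model.relations.threshold,
        },
        "embedding": {
            "medoids": [
                {"bag_id": b.bag_id, "instances": b.instances.tolist()}
                for b in model.embedding.medoids
            ],
            "medoid_indices": list(model.embedding.medoid_indices),
            "delta": model.embedding.delta,
            "mu": model.embedding.mu,
            "alpha": model.embedding.alpha,
        },
        "label_space": list(label_space.terms) if label_space is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path):
    """Load a model saved by :func:`save_model`; returns (model, label_space)."""
    import json

    from .datamodel import Bag, LabelSpace

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != 1:
        raise ValueError(f"{path}: unsupported model schema version")
    emb_doc = doc["embedding"]
    emb = BagEmbeddingModel(
        medoids=[
            Bag(b["bag_id"], np.asarray(b["instances"], float))
            for b in emb_doc["medoids"]
        ],
        medoid_indices=list(emb_doc["medoid_indices"]),
        delta=emb_doc["delta"],
        mu=emb_doc["mu"],
        alpha=emb_doc["alpha"],
    )
    model = MIMLwelModel(
        W=np.asarray(doc["W"], float),
        Y_bar=LabelMatrix(np.asarray(doc["Y_bar"]), "corrected"),
        eta=doc["eta"],
        epsilon=doc["epsilon"],
        embedding=emb,
        relations=RelationMatrix(
            np.asarray(doc["relations"]["values"]), doc["relations"]["threshold"]
        ),
        trace=list(doc["trace"]),
    )
    space = (
        LabelSpace(doc["label_space"]) if doc.get("label_space") is not None else None
    )
    return model, space


class MIMLwel:
    """Convenience estimator wrapping embedding, relations and the fit.

    Parameters mirror the pipeline defaults: cluster fraction ``alpha``,
    width scale ``mu``, empirical-risk weight ``eta``, correction budget
    ``epsilon`` (fraction of observed positives per label), relation
    threshold ``tau``.
    """

    def __init__(
        self,
        mu: float = 1.0,
        alpha: float = 0.1,
        eta: float = 1.0,
        epsilon: float = 0.2,
        tau: float = 0.5,
        max_outer: int = 20,
        seed: int = 0,
    ):
        self.mu = mu
        self.alpha = alpha
        self.eta = eta
        self.epsilon = epsilon
        self.tau = tau
        self.max_outer = max_outer
        self.seed = seed
        self.model_: MIMLwelModel | None = None
        self._train_bags = None

    def fit(self, bags, Y_hat: LabelMatrix, D: np.ndarray | None = None):
        emb = fit_bag_embedding(bags, self.alpha, self.mu, seed=self.seed, D=D)
        Phi = embed_many(emb, bags, D_to_train=D)
        R = build_relation_matrix(Y_hat, self.tau)
        self.model_ = fit_mimlwel(
            Phi,
            Y_hat,
            R,
            eta=self.eta,
            epsilon=self.epsilon,
            max_outer=self.max_outer,
            embedding_model=emb,
        )
        self._train_bags = list(bags)
        return self

    def predict(self, bags, D_to_train: np.ndarray | None = None):
        if self.model_ is None:
            raise ValueError("estimator is not fitted")
        Phi = embed_many(self.model_.embedding, bags, D_to_train=D_to_train)
        return predict(self.model_, embeddings=Phi)
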