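"""Mixed-membership factorization of property assignments (collapsed-Gibbs LDA).

Subjects play the role of documents and their active hidden properties the
role of tokens (each active property is one token of count 1).  A k-factor
latent Dirichlet allocation then expresses every subject as a point theta on
the k-simplex (mixed membership over neurobiological factors) and every
factor as a distribution phi over properties.  theta and phi are posterior
means over post-burn-in Gibbs sweeps, which stabilizes the factor maps
relative to a single sample.

Factor identity is arbitrary (label switching); recovery comparisons align
factors by maximum-correlation bipartite matching before scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ibp import PropertyAssignments

__all__ = [
    "LDAConfig",
    "FactorModel",
    "FactorEdgeWeights",
    "fit_lda",
    "infer_theta_new",
    "factor_edge_weights",
    "assign_biological_label",
    "heldout_per_token_loglik",
]


@dataclass(frozen=True)
class LDAConfig:
    """k factors with symmetric Dirichlet concentrations.

    The documents here are *short*: a subject typically carries only a
    handful of active properties, so the classic text-corpus default
    ``alpha_lda = 50/k`` would swamp the data (theta posterior means are
    ``(n_df + alpha)/(n_d + k alpha)``; with n_d ~ 5 tokens a large alpha
    pins every subject near the uniform point regardless of the data).  The
    default ``alpha_lda = 0.5`` is weakly informative at these document
    lengths; ``beta_lda = 0.1`` follows standard collapsed-Gibbs practice.
    """

    k: int = 3
    alpha_lda: float = 0.5
    beta_lda: float = 0.1
    n_sweeps: int = 400
    burn_in: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha_lda <= 0:
            raise ValueError("alpha_lda must be positive")
        if self.beta_lda <= 0:
            raise ValueError("beta_lda must be positive")
        if not 0 <= self.burn_in < self.n_sweeps:
            raise ValueError("need 0 <= burn_in < n_sweeps")


@dataclass
class FactorModel:
    phi: np.ndarray                 # k x n_properties, rows on the simplex
    theta: np.ndarray               # n_subjects x k, rows on the simplex
    config: LDAConfig
    property_ids: tuple[str, ...]
    empty_subjects: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def k(self) -> int:
        return self.phi.shape[0]


@dataclass
class FactorEdgeWeights:
    W: np.ndarray                   # k x n_edges
    edge_names: tuple[str, ...] | None = None


def _docs_from_assignments(assignments: PropertyAssignments) -> list[np.ndarray]:
    return [np.flatnonzero(row) for row in assignments.Z]


def _gibbs_lda(docs, V, k, alpha, beta, n_sweeps, burn_in, rng,
               phi_fixed=None, theta_only=False):
    """Shared collapsed-Gibbs core; with ``phi_fixed`` it is fold-in inference."""
    n_docs = len(docs)
    doc_of, word_of = [], []
    for d, words in enumerate(docs):
        doc_of.extend([d] * len(words))
        word_of.extend(words)
    doc_of = np.asarray(doc_of, dtype=int)
    word_of = np.asarray(word_of, dtype=int)
    n_tokens = doc_of.size

    n_dk = np.zeros((n_docs, k))
    n_kv = np.zeros((k, V))
    n_k = np.zeros(k)
    z = rng.integers(0, k, size=n_tokens)
    for t in range(n_tokens):
        n_dk[doc_of[t], z[t]] += 1
        n_kv[z[t], word_of[t]] += 1
        n_k[z[t]] += 1

    theta_acc = np.zeros((n_docs, k))
    phi_acc = np.zeros((k, V))
    n_acc = 0
    for sweep in range(n_sweeps):
        for t in range(n_tokens):
            d, v, old = doc_of[t], word_of[t], z[t]
            n_dk[d, old] -= 1
            if phi_fixed is None:
                n_kv[old, v] -= 1
                n_k[old] -= 1
                p = (n_dk[d] + alpha) * (n_kv[:, v] + beta) / (n_k + V * beta)
            else:
                p = (n_dk[d] + alpha) * phi_fixed[:, v]
            total = p.sum()
            if total <= 0:
                p = np.full(k, 1.0 / k)
                total = 1.0
            if k > 1:
                new = int(np.searchsorted(np.cumsum(p), rng.random() * total))
                new = min(new, k - 1)
            else:
                new = 0
            z[t] = new
            n_dk[d, new] += 1
            if phi_fixed is None:
                n_kv[new, v] += 1
                n_k[new] += 1
        if sweep >= burn_in:
            theta_acc += (n_dk + alpha) / (n_dk.sum(axis=1, keepdims=True) + k * alpha)
            if not theta_only:
                phi_acc += (n_kv + beta) / (n_kv.sum(axis=1, keepdims=True) + V * beta)
            n_acc += 1
    theta = theta_acc / max(n_acc, 1)
    phi = phi_acc / max(n_acc, 1) if not theta_only else phi_fixed
    return theta, phi


def fit_lda(assignments: PropertyAssignments, config: LDAConfig) -> FactorModel:
    """Collapsed Gibbs over token-factor indicators; posterior-mean theta, phi.

    Each active property of a subject is one token of count 1.  Subjects with
    zero active properties receive uniform theta and are flagged in
    ``empty_subjects``.
    """
    docs = _docs_from_assignments(assignments)
    V = assignments.n_properties
    if sum(len(d) for d in docs) == 0:
        raise ValueError("empty corpus: no subject has an active property")
    if config.k > V:
        warnings.warn(f"k={config.k} exceeds the number of properties ({V})",
                      UserWarning, stacklevel=2)
    rng = np.random.default_rng(config.seed)
    theta, phi = _gibbs_lda(docs, V, config.k, config.alpha_lda,
                            config.beta_lda, config.n_sweeps, config.burn_in, rng)
    empty = np.array([d for d, words in enumerate(docs) if words.size == 0], dtype=int)
    theta[empty] = 1.0 / config.k
    return FactorModel(phi=phi, theta=theta, config=config,
                       property_ids=tuple(assignments.property_ids),
                       empty_subjects=empty)


def infer_theta_new(assignments_new: PropertyAssignments, model: FactorModel,
                    seed: int = 0, n_sweeps: int = 200) -> np.ndarray:
    """Fold-in: infer theta for new subjects with phi frozen.

    Runs ``n_sweeps`` Gibbs sweeps over the new subjects' tokens, averaging
    theta over the last half.  Subjects with zero active properties receive
    the uniform (1/k, ..., 1/k) point.  Deterministic given ``seed``.
    """
    if tuple(assignments_new.property_ids) != tuple(model.property_ids):
        raise ValueError("property_ids do not align with the trained model")
    docs = _docs_from_assignments(assignments_new)
    rng = np.random.default_rng(seed)
    theta, _ = _gibbs_lda(docs, len(model.property_ids), model.k,
                          model.config.alpha_lda, model.config.beta_lda,
                          n_sweeps, n_sweeps // 2, rng,
                          phi_fixed=model.phi, theta_only=True)
    for d, words in enumerate(docs):
        if words.size == 0:
            theta[d] = 1.0 / model.k
    return theta


def factor_edge_weights(model: FactorModel, A_mean: np.ndarray,
                        edge_names=None) -> FactorEdgeWeights:
    """Project factors into edge space: ``W = phi @ A_mean``.

    Row f is the phi-weighted convex combination of the property loading
    rows — the per-factor edge-coupling weight map.
    """
    A_mean = np.asarray(A_mean, dtype=float)
    if model.phi.shape[1] != A_mean.shape[0]:
        raise ValueError(
            f"phi has {model.phi.shape[1]} properties but A_mean has "
            f"{A_mean.shape[0]} rows")
    return FactorEdgeWeights(model.phi @ A_mean,
                             tuple(edge_names) if edge_names is not None else None)


def assign_biological_label(theta_row: np.ndarray) -> int:
    """Dominant factor of one subject: argmax theta, ties to the lowest index."""
    theta_row = np.asarray(theta_row, dtype=float).ravel()
    if theta_row.size == 0 or (theta_row < 0).any() or not np.isclose(
            theta_row.sum(), 1.0, atol=1e-6):
        raise ValueError("theta row must be non-negative and sum to 1")
    return int(np.argmax(theta_row))


def heldout_per_token_loglik(phi: np.ndarray, theta: np.ndarray,
                             assignments: PropertyAssignments) -> float:
    """Mean log p(token) under mixture weights theta and topics phi."""
    docs = _docs_from_assignments(assignments)
    total, count = 0.0, 0
    for d, words in enumerate(docs):
        for v in words:
            total += np.log(float(theta[d] @ phi[:, v]) + 1e-300)
            count += 1
    if count == 0:
        raise ValueError("no tokens in held-out assignments")
    return total / count
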