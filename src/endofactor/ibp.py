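"""Indian Buffet Process linear-Gaussian latent-feature model, collapsed Gibbs.

The continuous fingerprints X (subjects x edges) are modeled as
``X = Z A + E`` with a binary feature-assignment matrix Z under an IBP
prior (concentration alpha), Gaussian loadings ``A ~ N(0, sigma_a^2)`` and
noise ``E ~ N(0, sigma_x^2)``.  The loadings are integrated out analytically
(collapsed likelihood), so the sampler walks over binary matrices with a
data-adapted number of columns: the model infers *how many* hidden
properties the cohort carries as well as which subjects express each one.
The selected binary matrix is the "discrete, positive-valued" representation
handed to the mixed-membership stage.

Posterior sampling follows the standard collapsed scheme: each existing
entry z_ik is resampled from its collapsed conditional (prior odds
``m_-ik : N - m_-ik``); per subject, the number of singleton features is
born/killed through a Metropolis-Hastings step with truncated-Poisson
(alpha/N) proposals; alpha is resampled from its conjugate Gamma
conditional; and the two model scales are resampled over fixed log-spaced
grids by conditional posterior weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import gamma as gamma_dist

from ._utils import left_order

_log = logging.getLogger("endofactor.ibp")

__all__ = [
    "IBPConfig",
    "IBPPosterior",
    "PropertyAssignments",
    "collapsed_loglik",
    "gibbs_conditional_prob",
    "ibp_log_pmf",
    "harmonic_number",
    "sample_alpha",
    "sample_ibp_prior",
    "fit_ibp",
    "posterior_mean_loadings",
    "select_assignment",
    "assign_heldout",
]


@dataclass(frozen=True)
class IBPConfig:
    """Sampler configuration.

    ``sigma_x`` / ``sigma_a`` may be fixed positive scalars; ``None`` (the
    default) resamples them over log-spaced grids scaled to the data's
    standard deviation.  ``alpha_prior`` is the (shape, rate) of the Gamma
    hyperprior on the IBP concentration.
    """

    alpha_prior: tuple[float, float] = (1.0, 1.0)
    sigma_x: float | None = None
    sigma_a: float | None = None
    n_sweeps: int = 1000
    burn_in: int = 500
    max_new_features_per_step: int = 4
    anneal_start: float = 0.2
    burnin_schedule: str = "anneal"
    n_restarts: int = 1
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        a, b = self.alpha_prior
        if a <= 0 or b <= 0:
            raise ValueError("alpha_prior shape and rate must be positive")
        if not 0 <= self.burn_in < self.n_sweeps:
            raise ValueError("need 0 <= burn_in < n_sweeps")
        for name in ("sigma_x", "sigma_a"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive (or None for a grid)")
        if self.max_new_features_per_step < 1:
            raise ValueError("max_new_features_per_step must be >= 1")
        if not 0 < self.anneal_start <= 1:
            raise ValueError("anneal_start must lie in (0, 1]")
        if self.burnin_schedule not in ("anneal", "continuation"):
            raise ValueError("burnin_schedule must be 'anneal' or 'continuation'")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class IBPPosterior:
    z_samples: list[np.ndarray]
    sample_logpost: np.ndarray
    alpha_trace: np.ndarray
    joint_logpost_trace: np.ndarray
    K_trace: np.ndarray
    selected_Z: np.ndarray
    A_mean: np.ndarray
    sigma_x: float
    sigma_a: float
    sigma_x_trace: np.ndarray = field(default=None)  # type: ignore[assignment]
    sigma_a_trace: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class PropertyAssignments:
    """Binary subjects x properties matrix (left-ordered, no empty columns)."""

    Z: np.ndarray
    property_ids: tuple[str, ...]

    def __post_init__(self):
        self.Z = np.asarray(self.Z)
        if not np.isin(self.Z, (0, 1)).all():
            raise ValueError("assignments must be binary")
        if len(self.property_ids) != self.Z.shape[1]:
            raise ValueError("property_ids must match Z columns")

    @property
    def n_properties(self) -> int:
        return self.Z.shape[1]


def harmonic_number(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n + 1)))


# ---------------------------------------------------------------------------
# collapsed marginal likelihood
# ---------------------------------------------------------------------------

def _loglik_from_stats(ZtZ, ZtX, trXX, N, D, sigma_x, sigma_a):
    """log p(X|Z) from sufficient statistics; K = 0 handled in closed form."""
    K = ZtZ.shape[0]
    base = -0.5 * N * D * np.log(2 * np.pi)
    if K == 0:
        return base - N * D * np.log(sigma_x) - trXX / (2 * sigma_x**2)
    lam = (sigma_x / sigma_a) ** 2
    G = ZtZ + lam * np.eye(K)
    L = cholesky(G, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    W = solve_triangular(L, ZtX, lower=True)
    quad = trXX - float(np.einsum("ij,ij->", W, W))
    return (base
            - (N - K) * D * np.log(sigma_x)
            - K * D * np.log(sigma_a)
            - 0.5 * D * logdet
            - quad / (2 * sigma_x**2))


def collapsed_loglik(Z: np.ndarray, X: np.ndarray, sigma_x: float,
                     sigma_a: float) -> float:
    """log p(X | Z, sigma_x, sigma_a) with the loadings integrated out.

    Closed form of the linear-Gaussian marginal,

    ``-ND/2 log 2pi - (N-K)D log sx - KD log sa - D/2 log|Z'Z + (sx/sa)^2 I|
    - tr(X'(I - Z M Z')X) / (2 sx^2)``  with  ``M = (Z'Z + (sx/sa)^2 I)^-1``.
    """
    X = np.asarray(getattr(X, "X", X), dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != X.shape[0]:
        raise ValueError("Z rows must match X rows")
    N, D = X.shape
    return _loglik_from_stats(Z.T @ Z, Z.T @ X, float(np.einsum("ij,ij->", X, X)),
                              N, D, sigma_x, sigma_a)


def gibbs_conditional_prob(Z: np.ndarray, X: np.ndarray, i: int, k: int,
                           sigma_x: float, sigma_a: float) -> float:
    """P(z_ik = 1 | Z_-ik, X) for an existing (non-singleton) feature.

    Prior odds are ``m_-ik : N - m_-ik`` (the IBP predictive for a feature
    held by ``m_-ik`` other subjects), combined with the collapsed
    likelihood ratio.  Exposed so small instances can be checked against
    exhaustive enumeration of the prior pmf times the likelihood.
    """
    Z = np.asarray(Z, dtype=float).copy()
    N = Z.shape[0]
    m = Z[:, k].sum() - Z[i, k]
    if m <= 0 or m >= N:
        raise ValueError("conditional defined for non-singleton, non-full columns")
    Z[i, k] = 1.0
    ll1 = collapsed_loglik(Z, X, sigma_x, sigma_a)
    Z[i, k] = 0.0
    ll0 = collapsed_loglik(Z, X, sigma_x, sigma_a)
    logit = np.log(m) - np.log(N - m) + ll1 - ll0
    return float(1.0 / (1.0 + np.exp(-logit)))


def ibp_log_pmf(Z: np.ndarray, alpha: float) -> float:
    """log P([Z] | alpha) of the left-ordered equivalence class of Z."""
    Z = np.asarray(Z)
    N, K = Z.shape
    if K == 0:
        return -alpha * harmonic_number(N)
    m = Z.sum(axis=0)
    if (m == 0).any():
        raise ValueError("Z must have no all-zero columns")
    # multiplicities of identical columns (the K_h! correction)
    _, counts = np.unique(Z.T, axis=0, return_counts=True)
    log_kh = float(gammaln(counts + 1.0).sum())
    return (K * np.log(alpha)
            - alpha * harmonic_number(N)
            - log_kh
            + float(np.sum(gammaln(N - m + 1) + gammaln(m) - gammaln(N + 1))))


def sample_alpha(K_plus: int, n_subjects: int, prior: tuple[float, float],
                 seed) -> float:
    """Conjugate update: alpha | K+ ~ Gamma(a + K+, b + H_n)."""
    a, b = prior
    if a <= 0 or b <= 0:
        raise ValueError("prior shape and rate must be positive")
    if K_plus < 0:
        raise ValueError("K_plus must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = b + harmonic_number(n_subjects)
    return float(rng.gamma(a + K_plus, 1.0 / rate))


def sample_ibp_prior(alpha: float, n_subjects: int, seed) -> np.ndarray:
    """Simulate the buffet process: one prior draw of Z (no data)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts: list[int] = []
    rows: list[np.ndarray] = []
    for i in range(1, n_subjects + 1):
        K = len(counts)
        row = np.zeros(K, dtype=np.int8)
        for k in range(K):
            if rng.random() < counts[k] / i:
                row[k] = 1
                counts[k] += 1
        k_new = rng.poisson(alpha / i)
        if k_new:
            counts.extend([1] * k_new)
            row = np.concatenate([row, np.ones(k_new, dtype=np.int8)])
        rows.append(row)
    K = len(counts)
    Z = np.zeros((n_subjects, K), dtype=np.int8)
    for i, row in enumerate(rows):
        Z[i, :row.size] = row
    return Z


def posterior_mean_loadings(Z: np.ndarray, X: np.ndarray, sigma_x: float,
                            sigma_a: float) -> np.ndarray:
    """Posterior mean of the loadings: ``(Z'Z + (sx/sa)^2 I)^-1 Z'X``."""
    X = np.asarray(getattr(X, "X", X), dtype=float)
    Z = np.asarray(Z, dtype=float)
    K = Z.shape[1]
    if K == 0:
        return np.zeros((0, X.shape[1]))
    if (Z.sum(axis=0) == 0).any():
        raise ValueError("Z has an all-zero column; prune before estimating loadings")
    G = Z.T @ Z + (sigma_x / sigma_a) ** 2 * np.eye(K)
    return cho_solve(cho_factor(G), Z.T @ X)


def select_assignment(posterior: IBPPosterior) -> PropertyAssignments:
    """The stored post-burn-in sample with maximal joint log posterior.

    All-zero columns are removed and columns are put in left-ordered
    canonical form (binary-number reading, ties by first active row).
    """
    if not posterior.z_samples:
        raise ValueError("posterior holds no post-burn-in samples")
    best = int(np.argmax(posterior.sample_logpost))
    Z = np.asarray(posterior.z_samples[best])
    Z = Z[:, Z.sum(axis=0) > 0]
    Z = left_order(Z)
    ids = tuple(f"p{k:03d}" for k in range(Z.shape[1]))
    return PropertyAssignments(Z.astype(np.int8), ids)


# ---------------------------------------------------------------------------
# the collapsed Gibbs sampler
# ---------------------------------------------------------------------------

def _truncated_poisson(rng, lam: float, cap: int) -> int:
    ks = np.arange(cap + 1)
    logp = ks * np.log(lam + 1e-300) - lam - gammaln(ks + 1.0)
    p = np.exp(logp - logsumexp(logp))
    return int(rng.choice(cap + 1, p=p))


def _loglik_fast(ZtZ, BBt, trXX, N, D, sigma_x, sigma_a):
    """log p(X|Z) from (Z'Z, (Z'X)(Z'X)', tr X'X); avoids any O(KD) work."""
    K = ZtZ.shape[0]
    base = -0.5 * N * D * np.log(2 * np.pi)
    if K == 0:
        return base - N * D * np.log(sigma_x) - trXX / (2 * sigma_x**2)
    G = ZtZ + (sigma_x / sigma_a) ** 2 * np.eye(K)
    L = np.linalg.cholesky(G)
    logdet = 2.0 * np.log(np.einsum("kk->k", L)).sum()
    quad = trXX - float(np.einsum("ij,ij->", np.linalg.inv(G), BBt))
    return (base
            - (N - K) * D * np.log(sigma_x)
            - K * D * np.log(sigma_a)
            - 0.5 * D * logdet
            - quad / (2 * sigma_x**2))


class _GibbsState:
    """Binary matrix plus incrementally-maintained sufficient statistics.

    Caches Z'Z and B B' with B = Z'X, so one likelihood evaluation costs
    O(K^3) regardless of the number of edges.  Incremental updates are
    refreshed from scratch periodically to wash out floating-point drift.
    """

    def __init__(self, Z: np.ndarray, X: np.ndarray):
        self.X = X
        self.xx = np.einsum("ij,ij->i", X, X)       # per-subject ||x_i||^2
        self.trXX = float(self.xx.sum())
        self.Z = np.asarray(Z, dtype=float)
        self.refresh()

    def refresh(self):
        self.ZtZ = self.Z.T @ self.Z
        self.B = self.Z.T @ self.X
        self.BBt = self.B @ self.B.T

    @property
    def K(self) -> int:
        return self.Z.shape[1]

    def loglik(self, sigma_x: float, sigma_a: float) -> float:
        N, D = self.X.shape
        return _loglik_fast(self.ZtZ, self.BBt, self.trXX, N, D,
                            sigma_x, sigma_a)

    def toggle(self, i: int, k: int):
        v = self.Z[i, k]
        d = 1.0 - 2.0 * v
        row = self.Z[i].copy()
        self.ZtZ[k, :] += d * row
        self.ZtZ[:, k] += d * row
        self.ZtZ[k, k] += d * d
        x = self.X[i]
        w = self.B @ x                               # B_l . x_i (old B)
        self.BBt[k, :] += d * w
        self.BBt[:, k] += d * w
        self.BBt[k, k] += d * d * self.xx[i]
        self.B[k, :] += d * x
        self.Z[i, k] = 1.0 - v

    def snapshot(self):
        return (self.Z.copy(), self.ZtZ.copy(), self.B.copy(), self.BBt.copy())

    def restore(self, snap):
        self.Z, self.ZtZ, self.B, self.BBt = (a.copy() for a in snap)

    def replace_singletons(self, i: int, drop: np.ndarray, n_new: int):
        """Remove subject i's singleton columns ``drop`` and append ``n_new``
        fresh columns active only for subject i (stats updated incrementally)."""
        if drop.size:
            self.Z = np.delete(self.Z, drop, axis=1)
            self.ZtZ = np.delete(np.delete(self.ZtZ, drop, axis=0), drop, axis=1)
            self.B = np.delete(self.B, drop, axis=0)
            self.BBt = np.delete(np.delete(self.BBt, drop, axis=0), drop, axis=1)
        if n_new:
            K = self.K
            x = self.X[i]
            cols = np.zeros((self.Z.shape[0], n_new))
            cols[i, :] = 1.0
            zi = self.Z[i]
            w = self.B @ x
            self.Z = np.hstack([self.Z, cols])
            new_ZtZ = np.empty((K + n_new, K + n_new))
            new_ZtZ[:K, :K] = self.ZtZ
            new_ZtZ[:K, K:] = zi[:, None]
            new_ZtZ[K:, :K] = zi[None, :]
            new_ZtZ[K:, K:] = 1.0   # all new columns share only row i
            self.ZtZ = new_ZtZ
            new_BBt = np.empty((K + n_new, K + n_new))
            new_BBt[:K, :K] = self.BBt
            new_BBt[:K, K:] = w[:, None]
            new_BBt[K:, :K] = w[None, :]
            new_BBt[K:, K:] = self.xx[i]
            self.BBt = new_BBt
            self.B = np.vstack([self.B, np.tile(x, (n_new, 1))])

    def prune_empty(self):
        m = np.einsum("kk->k", self.ZtZ)
        if (m == 0).any():
            keep = np.flatnonzero(m > 0)
            self.Z = self.Z[:, keep]
            self.ZtZ = self.ZtZ[np.ix_(keep, keep)]
            self.B = self.B[keep]
            self.BBt = self.BBt[np.ix_(keep, keep)]


def _prior_terms(m: np.ndarray, N: int, alpha: float) -> float:
    """IBP pmf log-terms that depend on column counts (no K_h! correction)."""
    K = m.size
    if K == 0:
        return -alpha * harmonic_number(N)
    return (K * np.log(alpha) - alpha * harmonic_number(N)
            + float(np.sum(gammaln(N - m + 1) + gammaln(m) - gammaln(N + 1))))


class _RefineScorer:
    """Fast joint-posterior scoring of candidate column sets.

    B-rows (z'X) of boolean column combinations are assembled from cached
    per-column and pairwise-intersection products, so a candidate costs
    O(K^3 + K^2 D_small) instead of a full O(N K D) recompute.
    """

    def __init__(self, X: np.ndarray, sigma_x: float, sigma_a: float,
                 alpha: float):
        self.X = X
        self.N, self.D = X.shape
        self.trXX = float(np.einsum("ij,ij->", X, X))
        self.sx, self.sa, self.alpha = sigma_x, sigma_a, alpha

    def set_base(self, Z: np.ndarray):
        self.Z = Z
        self.b = Z.T @ self.X                       # K x D cached products
        # b_int[k, l] = (z_k AND z_l)' X, for composite-column assembly
        K = Z.shape[1]
        self.b_int = np.empty((K, K, self.X.shape[1]))
        for k in range(K):
            self.b_int[k] = (Z * Z[:, k][:, None]).T @ self.X

    def score(self, cols: list[np.ndarray], rows: list[np.ndarray]) -> float:
        """Joint log posterior of the candidate whose columns are ``cols``
        with pre-assembled B-rows ``rows``."""
        m = np.array([c.sum() for c in cols])
        keep = m > 0
        if not keep.all():
            cols = [c for c, k in zip(cols, keep) if k]
            rows = [r for r, k in zip(rows, keep) if k]
            m = m[keep]
        K = len(cols)
        if K == 0:
            ll = _loglik_fast(np.zeros((0, 0)), np.zeros((0, 0)), self.trXX,
                              self.N, self.D, self.sx, self.sa)
            return ll + _prior_terms(m, self.N, self.alpha)
        Zc = np.column_stack(cols)
        B = np.vstack(rows)
        ll = _loglik_fast(Zc.T @ Zc, B @ B.T, self.trXX, self.N, self.D,
                          self.sx, self.sa)
        return ll + _prior_terms(m, self.N, self.alpha)


def _greedy_refine(Z: np.ndarray, X: np.ndarray, sigma_x: float, sigma_a: float,
                   alpha: float, max_moves: int = 10) -> np.ndarray:
    """Hill-climb the joint posterior with structural column moves.

    Per-bit Gibbs cannot cross between alternative feature bases (e.g. a
    spurious all-ones "baseline" column plus difference patterns versus the
    generative columns), because every single-bit path between them passes
    through states of much lower posterior.  This pass proposes whole-column
    rewrites — drop, merge (OR), carve (AND NOT), XOR, complement, split,
    and the 3-column union/intersection/difference rewrite — and greedily
    applies whichever most improves the *untempered* joint posterior.  It
    runs only during burn-in, as part of initialization; the post-burn-in
    chain is pure collapsed Gibbs.  (The prior here drops the K_h!
    multiplicity correction, immaterial for distinct columns.)
    """
    Z = Z[:, Z.sum(axis=0) > 0].astype(float)
    scorer = _RefineScorer(X, sigma_x, sigma_a, alpha)
    for _ in range(max_moves):
        K = Z.shape[1]
        if K == 0:
            break
        scorer.set_base(Z)
        cols = [Z[:, k] for k in range(K)]
        rows = [scorer.b[k] for k in range(K)]
        ones_b = X.sum(axis=0)
        best = scorer.score(cols, rows)
        best_cand, best_score = None, best + 1e-9

        def consider(cand_cols, cand_rows):
            nonlocal best_cand, best_score
            s = scorer.score(cand_cols, cand_rows)
            if s > best_score:
                best_cand, best_score = ([c.copy() for c in cand_cols]), s

        for k in range(K):
            others_c = cols[:k] + cols[k + 1:]
            others_r = rows[:k] + rows[k + 1:]
            consider(others_c, others_r)                       # drop
            consider(others_c + [1.0 - cols[k]],
                     others_r + [ones_b - rows[k]])            # complement
            for l in range(K):
                if l == k:
                    continue
                or_col = np.maximum(cols[k], cols[l])
                or_row = rows[k] + rows[l] - scorer.b_int[k, l]
                carve_col = cols[k] * (1.0 - cols[l])
                carve_row = rows[k] - scorer.b_int[k, l]
                xor_col = np.abs(cols[k] - cols[l])
                xor_row = rows[k] + rows[l] - 2.0 * scorer.b_int[k, l]
                and_col = cols[k] * cols[l]
                and_row = scorer.b_int[k, l]
                both_out = [c for j, c in enumerate(cols) if j not in (k, l)]
                both_out_r = [r for j, r in enumerate(rows) if j not in (k, l)]
                consider(both_out + [or_col], both_out_r + [or_row])      # merge
                replk = lambda c, r: (others_c[:0] + [c if j == k else cols[j]
                                                      for j in range(K)],
                                      [r if j == k else rows[j]
                                       for j in range(K)])
                consider(*replk(or_col, or_row))                          # or-keep
                consider(*replk(carve_col, carve_row))                    # carve
                consider(*replk(xor_col, xor_row))                        # xor
                consider([c if j != k else carve_col for j, c in enumerate(cols)]
                         + [and_col],
                         [r if j != k else carve_row for j, r in enumerate(rows)]
                         + [and_row])                                     # split
        # union/intersection/difference motif: {p, q, r} -> {q OR r, p AND NOT r}
        # (two exactly-fitting bases differ by a 3-column rewrite that no
        # single-column move reaches without passing through worse states);
        # skipped at large K where the cubic scan would dominate runtime
        for p in range(K if K <= 12 else 0):
            for q in range(K):
                for r in range(K):
                    if len({p, q, r}) < 3:
                        continue
                    keep_c = [cols[j] for j in range(K) if j not in (p, q, r)]
                    keep_r = [rows[j] for j in range(K) if j not in (p, q, r)]
                    new1 = np.maximum(cols[q], cols[r])
                    new1_r = rows[q] + rows[r] - scorer.b_int[q, r]
                    new2 = cols[p] * (1.0 - cols[r])
                    new2_r = rows[p] - scorer.b_int[p, r]
                    consider(keep_c + [new1, new2], keep_r + [new1_r, new2_r])
        if best_cand is None:
            break
        Z = np.column_stack(best_cand) if best_cand else np.zeros((Z.shape[0], 0))
        Z = Z[:, Z.sum(axis=0) > 0]
    return Z


def _default_grids(data_sd: float):
    sx = data_sd * np.geomspace(0.03, 1.0, 12)
    sa = data_sd * np.geomspace(0.1, 3.0, 10)
    return sx, sa


def _fit_ibp_single(X, config: IBPConfig) -> IBPPosterior:
    """Run the collapsed Gibbs sampler and select the highest-posterior Z.

    ``X`` may be a :class:`~endofactor.fingerprints.CohortMatrix` or a plain
    (subjects x edges) array.  Deterministic given config.seed.

    The chain starts from an empty matrix (features are born through the
    MH step) and burn-in uses one of two schedules that keep the sampler
    from freezing in a poor feature basis (the posterior over Z is extremely
    peaked at realistic signal-to-noise):

    - ``"anneal"``: the likelihood is tempered, the inverse temperature
      ramping linearly from ``anneal_start`` to 1 across burn-in.  Suits
      sparse, well-separated feature structure.
    - ``"continuation"``: the noise scale sigma_x is resampled above a
      decreasing floor, so coarse structure is learned before fine
      structure (a large sigma_x literally flattens the likelihood).
      Suits dense, overlapping structure in many dimensions.

    All post-burn-in sweeps run at temperature 1 with freely sampled
    scales, so recorded samples are valid MCMC output either way.
    """
    X = np.asarray(getattr(X, "X", X), dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 subjects")
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    N, D = X.shape
    rng = np.random.default_rng(config.seed)
    a0, b0 = config.alpha_prior
    H_n = harmonic_number(N)

    data_sd = float(X.std()) or 1.0
    grid_x, grid_a = _default_grids(data_sd)
    sigma_x = config.sigma_x if config.sigma_x is not None else float(grid_x[-3])
    sigma_a = config.sigma_a if config.sigma_a is not None else float(grid_a[-3])
    alpha = float(rng.gamma(a0, 1.0 / b0)) + 1e-3

    state = _GibbsState(np.zeros((N, 0)), X)
    cap = config.max_new_features_per_step

    n_rec = config.n_sweeps
    alpha_trace = np.empty(n_rec)
    K_trace = np.empty(n_rec, dtype=int)
    joint_trace = np.empty(n_rec)
    sx_trace = np.empty(n_rec)
    sa_trace = np.empty(n_rec)
    z_samples: list[np.ndarray] = []
    sample_logpost: list[float] = []

    continuation = (config.burnin_schedule == "continuation"
                    and config.sigma_x is None)
    for sweep in range(config.n_sweeps):
        if continuation:
            beta = 1.0
            if sweep < config.burn_in:
                frac = sweep / config.burn_in
                floor = float(data_sd * np.exp(
                    (1 - frac) * np.log(0.9)
                    + frac * np.log(grid_x[0] / data_sd)))
                allowed = grid_x[grid_x >= floor]
                if allowed.size == 0:
                    allowed = grid_x[-1:]
                lls = np.array([state.loglik(s, sigma_a) for s in allowed])
                sigma_x = float(allowed[rng.choice(
                    allowed.size, p=np.exp(lls - logsumexp(lls)))])
        elif config.burn_in:
            beta = min(1.0, config.anneal_start
                       + (1.0 - config.anneal_start) * sweep / config.burn_in)
        else:
            beta = 1.0
        ll_cur = state.loglik(sigma_x, sigma_a)
        for i in range(N):
            # resample existing (shared) features from the collapsed conditional
            for k in range(state.K):
                m_minus = state.ZtZ[k, k] - state.Z[i, k]
                if m_minus <= 0:
                    continue    # singleton of i: handled by the birth/death move
                state.toggle(i, k)
                ll_flip = state.loglik(sigma_x, sigma_a)
                now_one = state.Z[i, k] == 1.0
                ll1, ll0 = (ll_flip, ll_cur) if now_one else (ll_cur, ll_flip)
                logit = (np.log(m_minus) - np.log(N - m_minus)
                         + beta * (ll1 - ll0))
                want_one = rng.random() < expit(logit)
                if now_one != want_one:
                    state.toggle(i, k)
                else:
                    ll_cur = ll_flip

            # birth/death of subject-specific features: MH with truncated
            # Poisson(alpha/N) proposal; prior and proposal cancel, leaving
            # the collapsed likelihood ratio
            col_sums = np.einsum("kk->k", state.ZtZ)
            singles = np.flatnonzero((col_sums == 1.0) & (state.Z[i] == 1.0))
            k_old = singles.size
            k_new = _truncated_poisson(rng, alpha / N, cap)
            if k_new != k_old:
                snap = state.snapshot()
                state.replace_singletons(i, singles, k_new)
                ll_prop = state.loglik(sigma_x, sigma_a)
                if np.log(rng.random() + 1e-300) >= beta * (ll_prop - ll_cur):
                    state.restore(snap)
                else:
                    ll_cur = ll_prop

        state.prune_empty()
        K_plus = state.K
        alpha = float(rng.gamma(a0 + K_plus, 1.0 / (b0 + H_n)))

        if config.sigma_x is None and not (continuation
                                           and sweep < config.burn_in):
            lls = beta * np.array([state.loglik(s, sigma_a) for s in grid_x])
            sigma_x = float(grid_x[rng.choice(grid_x.size,
                                              p=np.exp(lls - logsumexp(lls)))])
        if config.sigma_a is None:
            lls = beta * np.array([state.loglik(sigma_x, s) for s in grid_a])
            sigma_a = float(grid_a[rng.choice(grid_a.size,
                                              p=np.exp(lls - logsumexp(lls)))])
        if sweep < config.burn_in and sweep % 20 == 19:
            # initialization-phase basis cleanup (see _greedy_refine)
            refined = _greedy_refine(state.Z, X, sigma_x, sigma_a, alpha)
            state = _GibbsState(refined, X)
        elif sweep % 50 == 49:
            state.refresh()     # wash out incremental floating-point drift

        ll = state.loglik(sigma_x, sigma_a)
        joint = (ll + ibp_log_pmf(state.Z, alpha)
                 + float(gamma_dist.logpdf(alpha, a0, scale=1.0 / b0)))
        if sweep % 10 == 0:
            _log.debug("sweep %d: K=%d alpha=%.3f sigma_x=%.3f joint=%.1f",
                       sweep, K_plus, alpha, sigma_x, joint)
        alpha_trace[sweep] = alpha
        K_trace[sweep] = K_plus
        joint_trace[sweep] = joint
        sx_trace[sweep] = sigma_x
        sa_trace[sweep] = sigma_a
        if sweep >= config.burn_in and (sweep - config.burn_in) % config.thin == 0:
            z_samples.append(state.Z.astype(np.int8))
            sample_logpost.append(joint)

    posterior = IBPPosterior(
        z_samples=z_samples,
        sample_logpost=np.asarray(sample_logpost),
        alpha_trace=alpha_trace,
        joint_logpost_trace=joint_trace,
        K_trace=K_trace,
        selected_Z=np.zeros((N, 0), dtype=np.int8),
        A_mean=np.zeros((0, D)),
        sigma_x=sigma_x,
        sigma_a=sigma_a,
        sigma_x_trace=sx_trace,
        sigma_a_trace=sa_trace,
    )
    best = int(np.argmax(posterior.sample_logpost))
    posterior.sigma_x = float(sx_trace[config.burn_in + best * config.thin])
    posterior.sigma_a = float(sa_trace[config.burn_in + best * config.thin])
    assignments = select_assignment(posterior)
    posterior.selected_Z = assignments.Z
    if assignments.n_properties:
        posterior.A_mean = posterior_mean_loadings(
            assignments.Z, X, posterior.sigma_x, posterior.sigma_a)
    return posterior


def fit_ibp(X, config: IBPConfig) -> IBPPosterior:
    """Fit the latent-feature model; with ``n_restarts > 1``, run that many
    independent chains from per-restart sub-seeds and keep the chain whose
    best sample has the highest joint log posterior.

    Restart selection is part of initialization/model selection: the
    returned object is one chain's untempered post-burn-in output.
    Deterministic given ``config.seed``.
    """
    if config.n_restarts == 1:
        return _fit_ibp_single(X, config)
    from ._utils import derive_seed
    best = None
    for r in range(config.n_restarts):
        cfg_r = IBPConfig(**{**config.__dict__, "n_restarts": 1,
                             "seed": derive_seed(config.seed, f"restart{r}")})
        post = _fit_ibp_single(X, cfg_r)
        score = (float(np.max(post.sample_logpost))
                 if len(post.sample_logpost) else -np.inf)
        if best is None or score > best[0]:
            best = (score, post)
    return best[1]


def assign_heldout(X_new, A_mean: np.ndarray, sigma_x: float,
                   feature_counts: np.ndarray, n_train: int,
                   n_sweeps: int = 50, seed: int = 0) -> np.ndarray:
    """Condition held-out rows on frozen training loadings.

    For each held-out fingerprint x, z is sampled by per-row Gibbs under
    prior inclusion odds ``m_k : n_train + 1 - m_k`` (the IBP predictive for
    a new customer) and the uncollapsed Gaussian likelihood with the
    training posterior-mean loadings held fixed.  No new features are born:
    the held-out representation lives in the training vocabulary.  The
    returned binary matrix thresholds the inclusion frequency over the last
    half of the sweeps at 0.5.
    """
    X_new = np.asarray(getattr(X_new, "X", X_new), dtype=float)
    K = A_mean.shape[0]
    out = np.zeros((X_new.shape[0], K), dtype=np.int8)
    if K == 0:
        return out
    feature_counts = np.asarray(feature_counts, dtype=float)
    prior_logodds = (np.log(np.clip(feature_counts, 1e-12, None))
                     - np.log(np.clip(n_train + 1 - feature_counts, 1e-12, None)))
    rng = np.random.default_rng(seed)
    keep_from = n_sweeps // 2
    inv2s2 = 1.0 / (2.0 * sigma_x**2)
    for r, x in enumerate(X_new):
        z = np.zeros(K)
        resid = x.copy()
        freq = np.zeros(K)
        for sweep in range(n_sweeps):
            for k in range(K):
                r_off = resid + A_mean[k] * z[k]          # residual with z_k = 0
                r_on = r_off - A_mean[k]                  # residual with z_k = 1
                dll = (np.dot(r_off, r_off) - np.dot(r_on, r_on)) * inv2s2
                logit = prior_logodds[k] + dll
                new = 1.0 if rng.random() < expit(logit) else 0.0
                if new != z[k]:
                    resid = r_on if new == 1.0 else r_off
                    z[k] = new
            if sweep >= keep_from:
                freq += z
        out[r] = (freq / (n_sweeps - keep_from)) > 0.5
    return out
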