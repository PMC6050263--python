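"""Pre-validation: unbiased brain-derived group labels.

The cohort is divided into m stratified splits.  For each split, the
internal model (IBP latent features followed by LDA factors) is trained on
the other m-1 splits only; the held-out subjects' property assignments are
then obtained by conditioning on the frozen training loadings, their factor
weights by fold-in LDA inference, and their brain-derived label as the
dominant factor.  Every subject's label is therefore produced by a model
that never saw that subject's data, so the labels can be used downstream as
if they came from an independent dataset.  Clinical labels enter only the
stratification of the splits — never the internal model.

Factor identity is arbitrary per fold (label switching); fold-specific
factors are aligned to a reference fold by Hungarian matching on their
edge-space projections ``W = phi @ A_mean`` before labels are pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._utils import derive_seed

_log = logging.getLogger("endofactor.prevalidation")
from .fingerprints import CohortMatrix
from .ibp import (IBPConfig, PropertyAssignments, assign_heldout, fit_ibp,
                  select_assignment)
from .lda import LDAConfig, factor_edge_weights, fit_lda, infer_theta_new

__all__ = [
    "PrevalidationConfig",
    "PrevalidationResult",
    "make_stratified_splits",
    "prevalidate",
    "match_factors",
    "standard_prevalidation_config",
]


@dataclass(frozen=True)
class PrevalidationConfig:
    m: int = 10
    seed: int = 0
    ibp_config: IBPConfig = field(default_factory=IBPConfig)
    lda_config: LDAConfig = field(default_factory=LDAConfig)
    refit_ibp_per_fold: bool = True

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least m = 2 splits")


def standard_prevalidation_config(seed: int = 0, m: int = 10,
                                  n_restarts: int = 3) -> "PrevalidationConfig":
    """Pipeline settings used for standard-cohort runs.

    One shared IBP fit (the protocol in which only the mixed-membership
    model is refit per split), continuation burn-in schedule, 150 sweeps /
    75 burn-in with best-of-``n_restarts`` chain selection; LDA with k = 3,
    300 sweeps / 150 burn-in.  These problem sizes are the package's
    desk-scale defaults; see the methods note.
    """
    return PrevalidationConfig(
        m=m, seed=seed, refit_ibp_per_fold=False,
        ibp_config=IBPConfig(n_sweeps=150, burn_in=75,
                             burnin_schedule="continuation",
                             n_restarts=n_restarts),
        lda_config=LDAConfig(k=3, n_sweeps=300, burn_in=150),
    )


@dataclass
class PrevalidationResult:
    labels_prevalidated: np.ndarray
    theta_prevalidated: np.ndarray
    fold_assignment: np.ndarray
    per_fold_models: list[dict]


def make_stratified_splits(labels: np.ndarray, m: int, seed: int) -> np.ndarray:
    """Pseudo-randomized fold assignment with balanced classes.

    Within each class, subjects are shuffled and dealt round-robin to the m
    folds, so per-class counts across folds differ by at most one.
    Deterministic given ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    if m < 2:
        raise ValueError("need at least m = 2 splits")
    rng = np.random.default_rng(seed)
    folds = np.full(labels.shape, -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < m:
            raise ValueError(
                f"class {cls} has only {idx.size} members (< m = {m})")
        idx = rng.permutation(idx)
        # rotate the starting fold per class so fold sizes stay even too
        start = rng.integers(0, m)
        folds[idx] = (np.arange(idx.size) + start) % m
    return folds


def match_factors(W_ref: np.ndarray, W_new: np.ndarray) -> np.ndarray:
    """Permutation ``perm`` such that new factor ``perm[j]`` plays the role of
    reference factor ``j`` (Hungarian matching on row correlations)."""
    k = W_ref.shape[0]
    corr = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            sa, sb = W_ref[a].std(), W_new[b].std()
            if sa > 0 and sb > 0:
                corr[a, b] = float(np.corrcoef(W_ref[a], W_new[b])[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm


def _fit_internal(X_train: np.ndarray, ibp_config: IBPConfig,
                  lda_config: LDAConfig):
    posterior = fit_ibp(X_train, ibp_config)
    assignments = select_assignment(posterior)
    if assignments.n_properties == 0:
        return posterior, assignments, None
    model = fit_lda(assignments, lda_config)
    return posterior, assignments, model


def prevalidate(cohort: CohortMatrix, clinical_labels: np.ndarray,
                config: PrevalidationConfig) -> PrevalidationResult:
    """Generate pre-validated factor weights and labels for every subject.

    For fold f: the IBP (when ``refit_ibp_per_fold``) and LDA are fit on the
    training fingerprints of the other folds; held-out property assignments
    come from conditioning on the training loadings (never re-estimated on
    test data); held-out theta from fold-in inference; the label is the
    dominant factor after cross-fold alignment.  With
    ``refit_ibp_per_fold=False`` the IBP is fit once on the full cohort and
    only the LDA is refit per fold.
    """
    X = np.asarray(getattr(cohort, "X", cohort), dtype=float)
    clinical_labels = np.asarray(clinical_labels, dtype=int)
    n = X.shape[0]
    k = config.lda_config.k
    folds = make_stratified_splits(clinical_labels, config.m,
                                   derive_seed(config.seed, "splits"))

    shared_posterior = None
    shared_assignments = None
    if not config.refit_ibp_per_fold:
        ibp_cfg = IBPConfig(**{**config.ibp_config.__dict__,
                               "seed": derive_seed(config.seed, "ibp-shared")})
        shared_posterior = fit_ibp(X, ibp_cfg)
        shared_assignments = select_assignment(shared_posterior)

    theta_out = np.full((n, k), 1.0 / k)
    labels_out = np.zeros(n, dtype=int)
    per_fold: list[dict] = []
    W_ref = None

    for f in range(config.m):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        if np.unique(clinical_labels[train]).size < 2:
            raise ValueError(f"training set of fold {f} has fewer than 2 classes")

        if config.refit_ibp_per_fold:
            ibp_cfg = IBPConfig(**{**config.ibp_config.__dict__,
                                   "seed": derive_seed(config.seed, f"ibp-fold{f}")})
            lda_cfg = LDAConfig(**{**config.lda_config.__dict__,
                                   "seed": derive_seed(config.seed, f"lda-fold{f}")})
            posterior, assignments, model = _fit_internal(X[train], ibp_cfg, lda_cfg)
            Z_train = assignments.Z
            A_mean = posterior.A_mean
        else:
            posterior = shared_posterior
            Z_train = shared_assignments.Z[train]
            keep = np.flatnonzero(Z_train.sum(axis=0) > 0)
            Z_train = Z_train[:, keep]
            A_mean = posterior.A_mean[keep]
            assignments = PropertyAssignments(
                Z_train, tuple(f"p{j:03d}" for j in range(Z_train.shape[1])))
            lda_cfg = LDAConfig(**{**config.lda_config.__dict__,
                                   "seed": derive_seed(config.seed, f"lda-fold{f}")})
            model = fit_lda(assignments, lda_cfg) if Z_train.shape[1] else None

        if model is None:
            # no structure found: uniform theta, label 0 for the held-out fold
            theta_fold = np.full((test.size, k), 1.0 / k)
            labels_fold = np.zeros(test.size, dtype=int)
            per_fold.append({"fold": f, "n_properties": 0, "model": None,
                             "permutation": np.arange(k)})
        else:
            Z_test = assign_heldout(
                X[test], A_mean, posterior.sigma_x,
                feature_counts=Z_train.sum(axis=0), n_train=train.size,
                seed=derive_seed(config.seed, f"heldout-fold{f}"))
            test_assignments = PropertyAssignments(Z_test, model.property_ids)
            theta_fold = infer_theta_new(
                test_assignments, model,
                seed=derive_seed(config.seed, f"foldin-fold{f}"))

            W = factor_edge_weights(model, A_mean).W
            if W_ref is None:
                W_ref = W
                perm = np.arange(k)
            else:
                perm = match_factors(W_ref, W)
            theta_fold = theta_fold[:, perm]
            labels_fold = np.argmax(theta_fold, axis=1)
            per_fold.append({"fold": f, "n_properties": Z_train.shape[1],
                             "model": model, "A_mean": A_mean,
                             "permutation": perm})

        theta_out[test] = theta_fold
        labels_out[test] = labels_fold
        _log.info("fold %d/%d: %d training subjects, %d properties",
                  f + 1, config.m, train.size, per_fold[-1]["n_properties"])

    return PrevalidationResult(labels_prevalidated=labels_out,
                               theta_prevalidated=theta_out,
                               fold_assignment=folds,
                               per_fold_models=per_fold)
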