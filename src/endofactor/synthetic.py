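"""Synthetic cohorts with planted latent-feature / mixed-membership structure.

The generator emulates the statistical structure the inference pipeline
assumes: every subject draws mixed-membership factor weights theta on the
simplex; factors are distributions phi over binary "hidden properties";
active properties load linearly onto connectivity edges; fingerprints are
the property loadings plus an additive per-site offset and Gaussian noise;
and the clinical label is a noisy corruption of the subject's dominant
biological factor.  Full ground truth travels with the cohort so every
downstream stage is testable without any data download.

The generative chain, per subject i with K_true properties and F factors::

    theta_i ~ Dirichlet(c * 1_F)
    P(Z_ip = 1) = mean_active * sum_f theta_if * phi_fp      (clipped to [0,1])
    X_i = Z_i @ A + site_offset[site_i] + N(0, noise_scale^2)
    clinical_i = corrupt(argmax_f theta_if, flip_rate)

where A has i.i.d. N(0, loading_scale^2) entries and each phi_f is a
Dirichlet draw supported on its own block of properties (disjoint supports).
Because every phi row sums to one, the expected number of active properties
per subject is exactly ``mean_active_properties`` (absent clipping).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import ConfigError, derive_seed
from .fingerprints import CohortMatrix, ConnectivityFingerprint, ROITimeSeries, devectorize

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "corrupt_labels",
    "timeseries_from_fingerprint",
    "standard_cohort_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic generative chain.

    All scales are non-negative; counts positive.  ``mean_active_properties``
    is the expected number of active hidden properties per subject.
    """

    n_subjects: int
    n_edges: int = 210
    n_properties_true: int = 9
    n_factors_true: int = 3
    dirichlet_concentration: float = 0.3
    mean_active_properties: float = 3.0
    loading_scale: float = 1.0
    noise_scale: float = 0.5
    site_count: int = 2
    site_effect_scale: float = 0.1
    label_flip_rate: float = 0.4
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_edges", "n_properties_true",
                     "n_factors_true", "site_count"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        for name in ("dirichlet_concentration", "mean_active_properties",
                     "loading_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("noise_scale", "site_effect_scale"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.label_flip_rate <= 1.0:
            raise ConfigError("label_flip_rate must lie in [0, 1]")
        if self.n_factors_true < 2:
            raise ConfigError("n_factors_true must be >= 2 to generate labels")


@dataclass
class GroundTruth:
    """Generative quantities retained for recovery tests."""

    Z_true: np.ndarray            # binary, subjects x K_true
    A_true: np.ndarray            # K_true x edges loadings
    theta_true: np.ndarray        # subjects x factors, rows on the simplex
    phi_true: np.ndarray          # factors x K_true, rows on the simplex
    biological_labels_true: np.ndarray
    site_labels: np.ndarray


@dataclass
class SyntheticCohort:
    X: np.ndarray                 # subjects x edges fingerprints
    clinical_labels: np.ndarray
    ground_truth: GroundTruth
    config: SyntheticConfig
    symptom_scores: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def subject_ids(self) -> list[str]:
        return [f"sub{i:05d}" for i in range(self.X.shape[0])]

    def as_cohort_matrix(self, correlation_mode: bool = False) -> CohortMatrix:
        """View the fingerprints as a :class:`CohortMatrix`.

        The linear-Gaussian model is unconstrained, so X is emitted raw by
        default; ``correlation_mode=True`` clips entries to [-1, 1] for
        export as correlation-valued fingerprints.
        """
        X = np.clip(self.X, -1.0, 1.0) if correlation_mode else self.X.copy()
        edges = tuple(f"e{j:03d}" for j in range(X.shape[1]))
        return CohortMatrix(X, self.subject_ids, edges,
                            self.ground_truth.site_labels.copy())

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_ids,
            "clinical_label": self.clinical_labels,
            "site": self.ground_truth.site_labels,
            "symptom_score": self.symptom_scores,
        })


def standard_cohort_config(n_subjects: int = 300, seed: int = 0,
                           **overrides) -> SyntheticConfig:
    """The reference study conditions used throughout evaluation.

    300 subjects, 210 edges, 9 hidden properties grouped under 3 factors,
    sparse mixed membership (Dirichlet 0.3, 3 active properties expected per
    subject), moderate signal-to-noise (unit loadings vs 0.5 noise), two
    sites with small additive offsets, and clinical labels that disagree
    with the dominant biological factor for 40% of subjects.  Block sizes
    exceed the expected active count, so a subject's dominant factor can be
    read off their active properties — the premise the label comparison
    rests on.
    """
    cfg = SyntheticConfig(n_subjects=n_subjects, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def corrupt_labels(labels: np.ndarray, flip_rate: float, n_classes: int,
                   seed: int) -> np.ndarray:
    """Independently replace each label, w.p. ``flip_rate``, by a *different* class."""
    if not 0.0 <= flip_rate <= 1.0:
        raise ConfigError("flip_rate must lie in [0, 1]")
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError("labels must lie in {0..n_classes-1}")
    if n_classes < 2:
        raise ValueError("need at least 2 classes to corrupt labels")
    rng = np.random.default_rng(seed)
    flip = rng.random(labels.shape) < flip_rate
    # adding 1..n_classes-1 modulo n_classes guarantees a different class
    shift = rng.integers(1, n_classes, size=labels.shape)
    out = labels.copy()
    out[flip] = (labels[flip] + shift[flip]) % n_classes
    return out


def _block_phi(n_factors: int, n_properties: int, rng: np.random.Generator) -> np.ndarray:
    """Factor->property distributions with disjoint property blocks."""
    if n_properties < n_factors:
        raise ConfigError("need at least one property per factor")
    blocks = np.array_split(np.arange(n_properties), n_factors)
    phi = np.zeros((n_factors, n_properties))
    for f, block in enumerate(blocks):
        # concentration 3 keeps within-block weights uneven but bounded away
        # from zero, so every property of a factor is actually expressed
        phi[f, block] = rng.dirichlet(np.full(block.size, 3.0))
    return phi


def _scale_to_expected_count(mixture: np.ndarray, target: float,
                             tol: float = 1e-10) -> np.ndarray:
    """Per-row scale ``c`` such that ``sum_p min(c * mixture_p, 1) = target``.

    A plain multiplicative scale under-delivers once probabilities saturate
    at 1; bisection on c per subject keeps the expected number of active
    properties exactly at the configured value.
    """
    n, K = mixture.shape
    lo = np.full(n, 0.0)
    hi = np.full(n, max(1e6, 16.0 * target)) / np.maximum(mixture.max(axis=1), 1e-12)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        s = np.minimum(mid[:, None] * mixture, 1.0).sum(axis=1)
        too_low = s < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return np.minimum(0.5 * (lo + hi)[:, None] * mixture, 1.0)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one cohort from the planted generative chain (bit-reproducible)."""
    n, E = config.n_subjects, config.n_edges
    K, F = config.n_properties_true, config.n_factors_true

    rng_theta = np.random.default_rng(derive_seed(config.seed, "theta"))
    rng_phi = np.random.default_rng(derive_seed(config.seed, "phi"))
    rng_z = np.random.default_rng(derive_seed(config.seed, "Z"))
    rng_a = np.random.default_rng(derive_seed(config.seed, "A"))
    rng_site = np.random.default_rng(derive_seed(config.seed, "sites"))
    rng_noise = np.random.default_rng(derive_seed(config.seed, "noise"))
    rng_score = np.random.default_rng(derive_seed(config.seed, "scores"))

    theta = rng_theta.dirichlet(np.full(F, config.dirichlet_concentration), size=n)
    phi = _block_phi(F, K, rng_phi)

    # activation probability per (subject, property): the factor mixture
    # theta @ phi scaled per subject so the expected active count equals
    # mean_active_properties exactly even where probabilities saturate at 1
    p_active = _scale_to_expected_count(theta @ phi,
                                        min(config.mean_active_properties, K))
    Z = (rng_z.random((n, K)) < p_active).astype(np.int8)

    A = rng_a.normal(0.0, config.loading_scale, size=(K, E))
    site_labels = rng_site.permutation(np.arange(n) % config.site_count)
    site_offsets = rng_site.normal(0.0, config.site_effect_scale,
                                   size=(config.site_count, E))
    X = Z @ A + site_offsets[site_labels]
    if config.noise_scale > 0:
        X = X + rng_noise.normal(0.0, config.noise_scale, size=(n, E))

    bio = np.argmax(theta, axis=1)
    clinical = corrupt_labels(bio, config.label_flip_rate, F,
                              derive_seed(config.seed, "labels"))
    scores = 2.0 * theta[:, 0] + rng_score.normal(0.0, 0.5, size=n)

    gt = GroundTruth(Z_true=Z, A_true=A, theta_true=theta, phi_true=phi,
                     biological_labels_true=bio, site_labels=site_labels)
    return SyntheticCohort(X=X, clinical_labels=clinical, ground_truth=gt,
                           config=config, symptom_scores=scores)


def _nearest_psd_correlation(C: np.ndarray, eig_floor: float = 1e-8):
    """Clip eigenvalues at ``eig_floor`` and re-normalize the diagonal to 1."""
    w, V = np.linalg.eigh(C)
    projected = bool((w < eig_floor).any())
    if projected:
        w = np.clip(w, eig_floor, None)
        C = (V * w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        C = (C + C.T) / 2.0
        np.fill_diagonal(C, 1.0)
    return C, projected


def timeseries_from_fingerprint(fingerprint: ConnectivityFingerprint,
                                n_timepoints: int, seed: int) -> ROITimeSeries:
    """Sample Gaussian ROI time-series whose population correlation is the fingerprint.

    The fingerprint is devectorized into a correlation matrix, projected to
    the nearest positive-semidefinite correlation matrix if needed (flagged
    in ``metadata["psd_projected"]``), and ``n_timepoints`` i.i.d. draws are
    taken from the corresponding zero-mean multivariate Gaussian.
    """
    values = np.asarray(fingerprint.values, dtype=float)
    if (np.abs(values) > 1.0).any():
        raise ValueError("fingerprint entries must lie in [-1, 1]")
    n_rois = len(fingerprint.roi_order)
    if n_timepoints < 2 * n_rois:
        raise ValueError("need n_timepoints >= 2 x number of ROIs")
    C = devectorize(values, n_rois)
    C, projected = _nearest_psd_correlation(C)
    rng = np.random.default_rng(seed)
    # jittered Cholesky keeps sampling stable at the PSD boundary
    L = np.linalg.cholesky(C + 1e-10 * np.eye(n_rois))
    data = rng.standard_normal((n_timepoints, n_rois)) @ L.T
    ts = ROITimeSeries(data, fingerprint.roi_order,
                       subject_id=fingerprint.subject_id)
    ts.metadata["psd_projected"] = projected
    return ts
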