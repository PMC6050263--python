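"""Validation experiments: linear-SVM fold accuracies, fold-level t-tests,
factor-symptom associations, and property-occurrence tables.

Four classification experiments probe what the brain-derived phenotypes buy:

1. ``biolabel_from_fingerprint`` — predict the pre-validated neurobiological
   label from the connectivity fingerprint (how well does the fingerprint
   encode the brain-derived grouping?).
2. ``clinical_from_fingerprint`` — predict the categorical clinical label
   from the fingerprint alone.
3. ``clinical_from_fingerprint_plus_theta`` — fingerprint augmented with the
   k factor weights.
4. ``clinical_from_theta_only`` — the k factor weights alone.

All use one-vs-rest linear SVMs (hinge loss, C fixed), per-fold features
standardized with training-fold statistics only, and report one accuracy per
fold; experiment pairs are compared by a two-sided Welch t-test on the fold
accuracy vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from ._utils import derive_seed
from .ibp import PropertyAssignments, select_assignment
from .lda import factor_edge_weights, fit_lda
from .prevalidation import PrevalidationConfig, prevalidate
from .synthetic import SyntheticConfig, generate_cohort

__all__ = [
    "ClassificationReport",
    "AssociationResult",
    "svm_cv_accuracy",
    "compare_experiments",
    "factor_associations",
    "property_occurrence_by_group",
    "run_full_pipeline",
    "EXPERIMENT_IDS",
]

EXPERIMENT_IDS = (
    "biolabel_from_fingerprint",
    "clinical_from_fingerprint",
    "clinical_from_fingerprint_plus_theta",
    "clinical_from_theta_only",
)


@dataclass
class ClassificationReport:
    """Per-fold out-of-sample accuracies (fractions in [0, 1])."""

    per_fold_accuracy: np.ndarray
    chance_level: float
    experiment_id: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.per_fold_accuracy, ddof=1))

    def summary(self) -> str:
        return (f"{self.experiment_id}: {100 * self.mean_accuracy:.2f} "
                f"± {100 * self.sd_accuracy:.2f}% "
                f"(chance {100 * self.chance_level:.2f}%)")


@dataclass
class AssociationResult:
    factor_id: int
    score_name: str
    r: float
    p: float
    n: int
    undefined: bool = False
    q: float | None = None


def svm_cv_accuracy(features: np.ndarray, labels: np.ndarray,
                    fold_assignment: np.ndarray, regularization: float = 1.0,
                    experiment_id: str = "") -> ClassificationReport:
    """One-vs-rest linear SVM accuracy per fold.

    Features are standardized per fold using training-fold means and scales
    only.  Hinge loss, fixed C, no tuning; deterministic given inputs.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    folds = np.asarray(fold_assignment, dtype=int)
    accs = []
    for f in np.unique(folds):
        train, test = folds != f, folds == f
        if np.unique(y[train]).size < 2:
            raise ValueError(f"training set of fold {f} contains a single class")
        scaler = StandardScaler().fit(X[train])
        clf = LinearSVC(C=regularization, loss="hinge", max_iter=20000,
                        random_state=0)
        clf.fit(scaler.transform(X[train]), y[train])
        accs.append(float(np.mean(clf.predict(scaler.transform(X[test])) == y[test])))
    return ClassificationReport(np.asarray(accs), 1.0 / np.unique(y).size,
                                experiment_id)


def compare_experiments(report_a: ClassificationReport,
                        report_b: ClassificationReport) -> tuple[float, float]:
    """Two-sided Welch t-test on the two per-fold accuracy vectors."""
    a, b = report_a.per_fold_accuracy, report_b.per_fold_accuracy
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 folds per report")
    if np.allclose(a, b) and np.std(a) == 0 and np.std(b) == 0:
        return 0.0, 1.0     # identical constant vectors: no evidence of a difference
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def factor_associations(theta: np.ndarray, scores_table: pd.DataFrame,
                        benjamini_hochberg: bool = False) -> list[AssociationResult]:
    """Pearson r and two-sided p per (factor, score) pair, pairwise-complete.

    Scores with zero variance (after removing missing values) yield a result
    flagged ``undefined`` rather than being silently dropped.  With
    ``benjamini_hochberg=True``, FDR-adjusted q-values are attached.
    """
    theta = np.asarray(theta, dtype=float)
    results: list[AssociationResult] = []
    for score_name in scores_table.columns:
        score = pd.to_numeric(scores_table[score_name], errors="coerce").to_numpy()
        for f in range(theta.shape[1]):
            ok = np.isfinite(score) & np.isfinite(theta[:, f])
            n = int(ok.sum())
            if n < 3 or np.std(score[ok]) == 0 or np.std(theta[ok, f]) == 0:
                results.append(AssociationResult(f, str(score_name),
                                                 np.nan, np.nan, n, undefined=True))
                continue
            r, p = stats.pearsonr(theta[ok, f], score[ok])
            results.append(AssociationResult(f, str(score_name),
                                             float(r), float(p), n))
    if benjamini_hochberg:
        defined = [res for res in results if not res.undefined]
        if defined:
            from statsmodels.stats.multitest import multipletests
            _, q, _, _ = multipletests([res.p for res in defined], method="fdr_bh")
            for res, qv in zip(defined, q):
                res.q = float(qv)
    return results


def property_occurrence_by_group(assignments: PropertyAssignments,
                                 labels: np.ndarray) -> pd.DataFrame:
    """Count, per hidden property and group, the subjects expressing it.

    Adds an ``exclusive_to`` column naming the single group a property is
    confined to, or -1 when the property occurs in several groups (the
    shared-structure case).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size != assignments.Z.shape[0]:
        raise ValueError("labels must align with assignment rows")
    groups = np.unique(labels)
    rows = []
    for j, pid in enumerate(assignments.property_ids):
        counts = {f"group{g}": int(assignments.Z[labels == g, j].sum())
                  for g in groups}
        present = [g for g in groups if counts[f"group{g}"] > 0]
        counts["exclusive_to"] = int(present[0]) if len(present) == 1 else -1
        rows.append({"property": pid, **counts})
    return pd.DataFrame(rows)


def run_full_pipeline(synthetic_config: SyntheticConfig,
                      prevalidation_config: PrevalidationConfig,
                      regularization: float = 1.0,
                      remove_sites: bool = False) -> dict:
    """Simulate -> fingerprints -> IBP -> LDA -> pre-validate -> evaluate.

    Returns a report bundle with the four classification experiments, their
    pairwise Welch comparisons, factor-symptom associations, the
    property-occurrence table, and references to the fitted objects.  Fully
    reproducible from the two config seeds.
    """
    stage = "simulate"
    try:
        cohort = generate_cohort(synthetic_config)
        matrix = cohort.as_cohort_matrix()
        if remove_sites:
            stage = "fingerprints"
            from .fingerprints import remove_site_effects
            matrix = remove_site_effects(matrix)

        stage = "prevalidate"
        result = prevalidate(matrix, cohort.clinical_labels, prevalidation_config)

        stage = "evaluate"
        folds = result.fold_assignment
        X = matrix.X
        theta = result.theta_prevalidated
        reports = {
            "biolabel_from_fingerprint": svm_cv_accuracy(
                X, result.labels_prevalidated, folds, regularization,
                "biolabel_from_fingerprint"),
            "clinical_from_fingerprint": svm_cv_accuracy(
                X, cohort.clinical_labels, folds, regularization,
                "clinical_from_fingerprint"),
            "clinical_from_fingerprint_plus_theta": svm_cv_accuracy(
                np.hstack([X, theta]), cohort.clinical_labels, folds,
                regularization, "clinical_from_fingerprint_plus_theta"),
            "clinical_from_theta_only": svm_cv_accuracy(
                theta, cohort.clinical_labels, folds, regularization,
                "clinical_from_theta_only"),
        }
        comparisons = {
            "biolabel_vs_clinical": compare_experiments(
                reports["biolabel_from_fingerprint"],
                reports["clinical_from_fingerprint"]),
            "plus_theta_vs_fingerprint": compare_experiments(
                reports["clinical_from_fingerprint_plus_theta"],
                reports["clinical_from_fingerprint"]),
            "theta_only_vs_fingerprint": compare_experiments(
                reports["clinical_from_theta_only"],
                reports["clinical_from_fingerprint"]),
        }

        # associations and occurrence tables use a cohort-level internal model
        stage = "associations"
        from .ibp import IBPConfig, fit_ibp
        ibp_cfg = IBPConfig(**{**prevalidation_config.ibp_config.__dict__,
                               "seed": derive_seed(prevalidation_config.seed,
                                                   "ibp-full")})
        posterior = fit_ibp(X, ibp_cfg)
        assignments = select_assignment(posterior)
        associations = factor_associations(
            theta, pd.DataFrame({"symptom_score": cohort.symptom_scores}))
        occurrence = property_occurrence_by_group(assignments,
                                                  cohort.clinical_labels)
        full_model = (fit_lda(assignments, prevalidation_config.lda_config)
                      if assignments.n_properties else None)
        W = (factor_edge_weights(full_model, posterior.A_mean).W
             if full_model is not None else None)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    return {
        "cohort": cohort,
        "prevalidation": result,
        "reports": reports,
        "comparisons": comparisons,
        "associations": associations,
        "property_occurrence": occurrence,
        "full_posterior": posterior,
        "full_model": full_model,
        "factor_edge_weights": W,
    }
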