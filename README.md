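# endofactor

Mixed-membership neurobiological factors from resting-state
functional-connectivity fingerprints.

Categorical psychiatric diagnoses (e.g. ADHD vs autism-spectrum vs typically
developing) sit uneasily on top of brain data that shows *shared*,
*graded* network dysfunction.  `endofactor` implements a transdiagnostic
hierarchical Bayesian pipeline for this problem: each subject's resting-state
signal in a 21-region default-mode / dorsal-attention / salience network is
reduced to a 210-edge correlation fingerprint; an Indian-Buffet-Process
latent-feature model infers, with the number of components determined by
the data, which binary *hidden properties* of connectivity each subject
expresses; latent Dirichlet allocation compresses the properties into k
*factors* so each subject is a point θ on the k-simplex (mixed membership,
not hard clusters); *pre-validation* turns the factors into brain-derived
group labels that are, for every subject, produced by a model never trained
on that subject's data split; and linear SVMs quantify whether those
brain-derived labels are more predictable from connectivity than the
categorical diagnoses are.

It is aimed at computational-psychiatry researchers who want a tested,
reproducible implementation of this IBP→LDA→pre-validation→SVM chain, with
a synthetic-cohort generator that makes every stage testable without any
data download.

## The model in brief

Fingerprints `X` (subjects × 210 edges) follow a linear-Gaussian
latent-feature model with an IBP prior,

    X = Z A + E,   Z ~ IBP(α),   A_kj ~ N(0, σ_a²),   E_ij ~ N(0, σ_x²),

whose collapsed marginal p(X|Z) (loadings integrated out) drives a
collapsed Gibbs sampler over binary matrices with a data-adapted number of
columns K.  The selected assignment matrix feeds a k-factor LDA (subjects =
documents, active properties = tokens), giving factor→property
distributions φ and subject factor weights θ; per-factor edge maps are
W = φ·A.  Pre-validation with m = 10 stratified splits yields per-subject
labels argmax θ inferred out-of-split; one-vs-rest linear SVMs (hinge loss,
C = 1) evaluate each label set out of sample, and fold accuracies are
compared by Welch t-tests.  See `docs/methods.md` for the full treatment.

## Worked example

The package ships a generator whose cohorts have the exact structure the
pipeline assumes — planted binary properties under a 3-factor
mixed-membership layer, site offsets, noise, and clinical labels that are
40%-corrupted versions of each subject's dominant biological factor.  The
snippet below simulates the standard 300-subject cohort, pre-validates
brain-derived labels, and runs the two headline classification experiments:

```python
import numpy as np
from endofactor import generate_cohort, standard_cohort_config, svm_cv_accuracy
from endofactor.prevalidation import prevalidate, standard_prevalidation_config

cohort = generate_cohort(standard_cohort_config(n_subjects=300, seed=1))
result = prevalidate(cohort.as_cohort_matrix(), cohort.clinical_labels,
                     standard_prevalidation_config(seed=7))

X, folds = cohort.X, result.fold_assignment
bio  = svm_cv_accuracy(X, result.labels_prevalidated, folds,
                       experiment_id="biolabel_from_fingerprint")
clin = svm_cv_accuracy(X, cohort.clinical_labels, folds,
                       experiment_id="clinical_from_fingerprint")
only = svm_cv_accuracy(result.theta_prevalidated, cohort.clinical_labels,
                       folds, experiment_id="clinical_from_theta_only")
for rep in (bio, clin, only):
    print(rep.summary())
```

```
biolabel_from_fingerprint: 83.01 ± 5.96% (chance 33.33%)
clinical_from_fingerprint: 43.00 ± 10.55% (chance 33.33%)
clinical_from_theta_only: 49.31 ± 7.54% (chance 33.33%)
```

Reading the numbers: the brain-derived labels are predicted from unseen
subjects' connectivity far better than the corrupted categorical labels
(83.0% vs 43.0% against a 33.3% three-class chance level) — by
construction, the diagnoses here disagree with the underlying biology for
40% of subjects, and the pipeline's labels recover that biology — while
the three factor weights alone predict the clinical labels at least as well
as all 210 connectivity values (49.3% vs 43.0%), i.e. three numbers per
subject carry the diagnosis-relevant content of the whole fingerprint.

The same pipeline is scriptable from the shell:

```bash
endofactor simulate   --config run.yaml --out sim/  --seed 1
endofactor fit-ibp    --fingerprints sim/fingerprints.tsv --out ibp/ --seed 1
endofactor fit-lda    --assignments ibp/assignments.tsv --k 3 --out lda/
endofactor prevalidate --fingerprints sim/fingerprints.tsv \
                       --meta sim/metadata.tsv --out prev/ --seed 1
endofactor evaluate   --prevalidated prev/prevalidated_labels.tsv \
                      --fingerprints sim/fingerprints.tsv \
                      --meta sim/metadata.tsv --out eval/
# or everything at once:
endofactor run-all --out out/ --seed 1
```

Real data enter through `endofactor fingerprint` (4-D NIfTI images plus ROI
masks → fingerprint TSV, optional edge-level site removal) or by
constructing a `CohortMatrix` from any subjects × edges table.

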