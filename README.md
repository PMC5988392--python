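# netsynchrony

Network synchrony analysis of resting-state functional connectivity:
spectral decomposition of region-by-region connectivity matrices into
ranked, spatially overlapping brain networks, eigenvalue-based synchrony
statistics, brain–behavior correlation screening, and out-of-sample
prediction of cognition from eigenvalue-product "network interaction"
features.

## The scientific problem

Individual differences in cognition — fluid intelligence in particular —
have been linked to the brain's intrinsic functional architecture as
measured with resting-state fMRI. Rather than treating individual
region-pair connections as features, this package takes a systems view:
a subject's Fisher-z connectivity matrix **C** (R × R over a cortical +
subcortical + cerebellar parcellation) is decomposed as

    C ≈ Σₖ λₖ vₖ vₖᵀ,

where the eigenvectors vₖ are spatially overlapping network maps
(principal components, PCs) and each eigenvalue λₖ measures *network
synchrony* — the persistence of within-network covariation. PC 1 is the
global synchrony component; the *scaled eigenvalue* λₖ/λ₁ expresses a
network's prominence relative to an individual's global synchrony (so
scaled element 1 is identically 1). Subject components are aligned to
group components by maximal spatial correlation under eigenvector sign
ambiguity.

Downstream, cognitive measures are screened against (scaled) eigenvalues
with Spearman correlations (bootstrap CIs, multiple-comparison control),
and the interaction of a subset S of screened networks is quantified as
the eigenvalue product Πₖ∈S λₖ (the hypervolume of the spanned
eigensubspace). All 2^k subsets of the k screened components form the
candidate features of a LASSO fitted on a 70%/30% train/test partition;
prediction quality is the Pearson r between predicted and measured
scores in the held-out set.

Because suitable consortium data are access-restricted, the package
ships a first-class synthetic cohort generator with planted low-rank
eigenstructure and planted brain–behavior coupling, giving every stage a
recoverable ground truth.

## Worked example

```python
import pandas as pd
from netsynchrony import (
    draw_subject_spectra, generate_behavior, make_truth,
    run_prediction_experiment, screen,
)

# simulate a cohort at the study's scale: 830 subjects, 10 components
truth = make_truth(n_subjects=830, n_regions=60, seed=7)
spectra = draw_subject_spectra(truth)                  # planted eigenvalues
behavior = generate_behavior(truth, spectra)           # 12-measure battery
eigs = pd.DataFrame(spectra, index=truth.subject_ids, columns=range(1, 11))

# screen eigenvalue-behavior correlations in a 600-subject training set
grid, selected = screen(eigs.iloc[:600], behavior.iloc[:600], n_boot=500, seed=7)
print("components selected for fluid intelligence:", selected["fluid_intelligence"])

# predict fluid intelligence from eigenvalue products in a held-out test set
report = run_prediction_experiment(
    eigs, eigs.div(eigs[1], axis=0), behavior, "fluid_intelligence",
    screened_components=list(range(3, 11)), n_train=600, seed=7,
)
print(f"candidate subsets: {report.n_candidate_subsets}, "
      f"selected: {report.model.n_selected}, "
      f"test r = {report.test_result.r:.2f} (n_test = {report.n_test})")
```

Output:

```
components selected for fluid intelligence: [3, 4, 5, 7]
candidate subsets: 256, selected: 11, test r = 0.24 (n_test = 230)
```

The screen picks up a subset of the planted components 3–10 (at the
planted marginal Spearman ≈ 0.12, power after correction is partial by
design); the eigenvalue-product LASSO then predicts the held-out
fluid-intelligence scores with r = 0.24 across the 230 test subjects.
A target planted only through the global component (the
cognitive-flexibility analog) yields a near-zero interaction-model
test r — global synchrony, not network interactions, carries that
signal.

## Command line

Each stage is also a subcommand of the `netsynchrony` CLI:

```sh
netsynchrony simulate   --config cohort.yaml --out cohort/ --seed 1
netsynchrony connect    --timeseries cohort/timeseries --out matrices/
netsynchrony decompose  --matrices matrices/ --m 10 --subject-m 20 --out spectral/
netsynchrony correlate  --profiles spectral/matched_profiles.tsv --behavior cohort/behavior.tsv --out corr/
netsynchrony predict    --profiles spectral/matched_profiles.tsv --behavior cohort/behavior.tsv \
                        --target fluid_intelligence --out report.json
netsynchrony run-all    --config pipeline.yaml --seed 1
```

All formats are plain TSV/JSON; `run-all` stamps every artifact with the
configuration hash and derives every per-stage random stream from the
single master seed.

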