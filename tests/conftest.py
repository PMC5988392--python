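import numpy as np
import pandas as pd
import pytest

from netsynchrony._seeds import derive_seed
from netsynchrony.synthetic import draw_subject_spectra, generate_behavior, make_truth


@pytest.fixture(scope="session")
def small_truth():
    """Desk-scale truth: 30 regions, 5 components, null behavior only."""
    return make_truth(
        n_regions=30,
        n_components=5,
        n_subjects=20,
        n_runs=2,
        n_timepoints=80,
        group_spectrum=[5.0, 4.0, 3.0, 2.0, 1.0],
        subject_spectrum_sd=[0.05] * 5,
        noise_sd=0.02,
        behavior_coefficients={},
        seed=42,
    )


@pytest.fixture(scope="session")
def training_cohort():
    """One n=600 cohort with the default planted behavior battery.

    Spectra are drawn directly from the truth (no connectivity stage),
    which is the ground-truth path for screening/prediction tests.
    """
    truth = make_truth(n_regions=60, n_subjects=600, seed=derive_seed(1234, "cohort"))
    spectra = draw_subject_spectra(truth)
    behavior = generate_behavior(truth, spectra)
    eigs = pd.DataFrame(
        spectra, index=truth.subject_ids, columns=np.arange(1, truth.n_components + 1)
    )
    eigs.index.name = "subject_id"
    return truth, eigs, behavior
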