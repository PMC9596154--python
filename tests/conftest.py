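import pytest

import threathelp as th


@pytest.fixture(scope="session")
def toy_design():
    """Single-run 6-trial design: 3 distal / 3 imminent, 2 per level."""
    return th.TaskDesign(
        n_runs=1,
        trials_per_run=6,
        n_distal_per_run=3,
        n_imminent_per_run=3,
        n_per_level_per_run=2,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A 6-subject, 2-ROI cohort at the default task design (shared, read-only)."""
    neural = th.NeuralParams(
        rois=("amygdala_left", "insula_right"),
        n_voxels=30,
        target_roi="amygdala_left",
    )
    return th.simulate_experiment(n_subjects=6, seed=123, neural_params=neural)


@pytest.fixture(scope="session")
def default_cohort():
    """A full default cohort (49 subjects, 13 ROIs) used by pipeline-level tests."""
    return th.simulate_experiment(n_subjects=49, seed=20240901)
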