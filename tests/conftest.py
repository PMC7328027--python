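import numpy as np
import pytest

import socialpls as sp


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study: 29/27 subjects, 12^3 grid, two planted LVs."""
    return sp.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def analysis_subjects(default_dataset):
    """Subjects with the famous condition excluded, analysis-ready."""
    return sp.exclude_conditions(list(default_dataset.subjects), ("famous",))


@pytest.fixture(scope="session")
def space():
    return sp.default_space()


@pytest.fixture(scope="session")
def fitted_task_pls(analysis_subjects):
    """One fitted task PLS (small resampling counts) reused across tests."""
    model = sp.MeanCenteredPLS(analysis_subjects)
    return model.fit(n_perm=50, n_boot=30, rng=7)


def make_subjects(matrices, groups, conditions):
    """Build SubjectActivity objects from raw (voxels x conditions) arrays."""
    return [
        sp.SubjectActivity(
            subject_id=f"s{i}",
            group=g,
            conditions=tuple(conditions),
            matrix=np.asarray(m, dtype=float),
        )
        for i, (m, g) in enumerate(zip(matrices, groups))
    ]
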