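import warnings

import pytest

from adductomics import CohortParams, StudyDesign, default_modifications, simulate_cohort


@pytest.fixture(scope="session")
def mods():
    return default_modifications()


@pytest.fixture(scope="session")
def high_exposure_cohort():
    """15 exposed (Q, 5 mM) vs 15 control, 2000 background + 150 sites."""
    design = StudyDesign(
        agents=("Q",),
        exposure_levels=(5e-3,),
        replicates=15,
        control_replicates=15,
        seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(design, CohortParams())


@pytest.fixture(scope="session")
def three_agent_cohort():
    """HD/Q/T at 5 mM, 3 replicates each, with agent-favoured sites."""
    design = StudyDesign(
        agents=("HD", "Q", "T"),
        exposure_levels=(5e-3,),
        replicates=3,
        control_replicates=3,
        seed=5,
    )
    return simulate_cohort(design, CohortParams(n_background_features=500))
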