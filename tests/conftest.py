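import pytest

from pcnatrace.cycle import CyclePopulationParams, sample_timeline
from pcnatrace.io import mitosis_from_timelines
from pcnatrace.phases import call_phases
from pcnatrace.scene import SceneSpec, generate_scene
from pcnatrace.traces import extract_traces

COHORT_SEED = 42
COHORT_SIZE = 50


@pytest.fixture(scope="session")
def det_params():
    """Degenerate population parameters: every phase at its mean duration."""
    return CyclePopulationParams(g1_sd=0.0, s_sd=0.0, g2_sd=0.0, m_sd=0.0)


@pytest.fixture(scope="session")
def det_timeline(det_params):
    return sample_timeline(det_params, 0)


@pytest.fixture(scope="session")
def single_cell_scene(det_params):
    """One deterministic cell rendered at default imaging conditions."""
    spec = SceneSpec(n_cells=1, cycle_params=det_params, seed=3)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def single_cell_traces(single_cell_scene):
    return extract_traces(single_cell_scene.stack, single_cell_scene.masks,
                          single_cell_scene.spec.frame_interval_min)


@pytest.fixture(scope="session")
def cohort_scene():
    """The 50-cell default-condition scene used for blind phase recovery."""
    return generate_scene(SceneSpec(n_cells=COHORT_SIZE, seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_traces(cohort_scene):
    return extract_traces(cohort_scene.stack, cohort_scene.masks,
                          cohort_scene.spec.frame_interval_min)


@pytest.fixture(scope="session")
def cohort_calls(cohort_scene, cohort_traces):
    calls, undetected = call_phases(
        cohort_traces, mitosis_from_timelines(cohort_scene.timelines))
    assert not undetected, f"S phase not detected for cells {undetected}"
    return calls
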