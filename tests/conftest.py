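import pytest

from chromolin import get_preset
from chromolin.simulate import apply_edu_pulse_chase, simulate


@pytest.fixture(scope="session")
def wt_pad_sim():
    return simulate(get_preset("WT"), layout="pad", n_lineages=120, duration=330, seed=101)


@pytest.fixture(scope="session")
def dmatp_pad_sim():
    return simulate(get_preset("dmatP"), layout="pad", n_lineages=120, duration=330, seed=202)


@pytest.fixture(scope="session")
def dmukb_mm_sim():
    return simulate(
        get_preset("dmukB"), layout="mother_machine", n_lineages=40, duration=1080, seed=303
    )


@pytest.fixture(scope="session")
def wt_pulse_sim():
    sim = simulate(get_preset("WT"), layout="pad", n_lineages=120, duration=400, seed=404)
    return apply_edu_pulse_chase(sim, pulse_start=20, pulse_duration=15, chase_duration=190)


@pytest.fixture(scope="session")
def wt_forest(wt_pad_sim):
    from chromolin.lineage import build_forest

    return build_forest(wt_pad_sim.cell_table)


@pytest.fixture(scope="session")
def wt_traces(wt_forest, wt_pad_sim):
    from chromolin.flipping import build_traces

    traces, _ = build_traces(wt_forest, wt_pad_sim.focus_table)
    return traces
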