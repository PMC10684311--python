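import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fi_by_gks():
    """Frequency-current curves across the modelled gKs range (cached)."""
    from achnet.neuron import NeuronParams, fi_curve

    gks_values = (0.0, 0.3, 0.6, 0.9, 1.2, 1.5)
    currents = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
    out = {}
    for g in gks_values:
        out[g] = fi_curve(NeuronParams(gKs=g), currents, duration=1500.0)
    return out


@pytest.fixture(scope="session")
def onset_frequencies():
    """Smallest sustained firing frequency just above rheobase.

    gKs = 0 (Type 1) is probed on a fine grid of weak hyperpolarizing to
    zero currents (its rheobase is negative: the cell is spontaneously
    active); gKs = 1.5 (Type 2) near its rheobase of ~1.2 uA/cm^2.
    """
    from achnet.neuron import NeuronParams, fi_curve

    def onset(gks, currents):
        res = fi_curve(NeuronParams(gKs=gks), currents, duration=3000.0)
        f = res["frequency"]
        nz = f[f > 0]
        assert nz.size, f"no firing found near rheobase for gKs={gks}"
        return float(nz[0])

    return {
        0.0: onset(0.0, np.arange(-0.2, 0.05, 0.05)),
        1.5: onset(1.5, np.arange(1.0, 1.65, 0.05)),
    }


@pytest.fixture(scope="session")
def sfa_run():
    """Adapting spike train: low-ACh cell (gKs=1.5) at 1.5 uA/cm^2."""
    from achnet.neuron import NeuronParams, simulate_single_neuron

    return simulate_single_neuron(NeuronParams(gKs=1.5), 1.5, 1200.0,
                                  record_traces=True)
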