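import numpy as np
import pytest

import coralight as cl
from coralight import pipeline
from coralight import photosynthesis as ps


@pytest.fixture(scope="session")
def morphotypes():
    return cl.load_default_morphotypes()


@pytest.fixture(scope="session")
def optical_scenarios():
    return pipeline.load_optical_scenarios()


@pytest.fixture(scope="session")
def pe_sets():
    return ps.load_default_pe()


@pytest.fixture(scope="session")
def irradiances():
    return ps.load_default_irradiances()


class FluenceBank:
    """Caches geometry tiles and transport runs shared across tests.

    Every run is checked for energy-ledger closure on retrieval, so the
    conservation invariant is exercised on every transport run the suite
    performs.
    """

    def __init__(self, morphotypes, optics):
        self.morphotypes = morphotypes
        self.optics = optics
        self._vols = {}
        self._runs = {}

    def volume(self, morphotype, variant="default"):
        key = (morphotype, variant)
        if key not in self._vols:
            p = self.morphotypes[morphotype]
            if variant == "default":
                self._vols[key] = cl.build_tile(p)
            elif variant.startswith("knockout:"):
                self._vols[key] = cl.knockout_tile(p, variant.split(":", 1)[1])
            else:
                raise ValueError(variant)
        return self._vols[key]

    def fluence(self, morphotype, variant="default", scenario=1, seed=0, n_photons=1_000_000):
        key = (morphotype, variant, scenario, seed, n_photons)
        if key not in self._runs:
            vol = self.volume(morphotype, variant)
            flu = cl.run_mc(
                vol,
                self.optics[scenario],
                cl.TransportConfig(n_photons=n_photons, seed=seed, lateral_boundary="absorbing"),
            )
            total = flu.escaped_top + flu.escaped_other + flu.absorbed_total + flu.roulette_net
            assert abs(total - 1.0) <= 1e-6, f"energy ledger open by {total - 1.0:.2e}"
            self._runs[key] = flu
        return self._runs[key]


@pytest.fixture(scope="session")
def bank(morphotypes, optical_scenarios):
    return FluenceBank(morphotypes, optical_scenarios)
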