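"""Shared fixtures: the standard assay configuration used throughout.

The defaults reproduce the measurement protocol — 60 μL of purified
liposome stock (3.5 mg/mL lipid, 200 nm vesicles, 4.059 nm bilayer)
mixed with 1140 μL of PBS, release at 40 °C, bilayer melting at
41.5 °C.
"""

import numpy as np
import pytest

import lipoperm as lp


@pytest.fixture(scope="session")
def pop() -> lp.LiposomePopulation:
    return lp.LiposomePopulation()


@pytest.fixture(scope="session")
def protocol() -> lp.MixingProtocol:
    return lp.MixingProtocol()


@pytest.fixture(scope="session")
def calib() -> lp.CalibrationCurve:
    return lp.CalibrationCurve()


@pytest.fixture(scope="session")
def geom(pop, protocol) -> lp.AssayGeometry:
    return lp.assay_geometry(pop, protocol)


@pytest.fixture(scope="session")
def kin() -> lp.KineticParams:
    """Probe-alone reference kinetics: P(40 °C) = 1.4e-8 cm/s, K = 2.9e4."""
    return lp.reference_kinetics()


@pytest.fixture(scope="session")
def clean_trace(kin, pop, protocol, calib) -> lp.FluorescenceTrace:
    """Noise-free four-stage probe-alone trace (shared; do not mutate)."""
    recipe = lp.ExperimentRecipe("CF alone", noise_sd=0.0)
    return lp.generate_trace(recipe, kin, pop, protocol, calib)
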