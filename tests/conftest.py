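"""Shared fixtures: session-scoped transport ensembles.

Transport is the expensive step, so the ensembles are simulated once
per session at sizes chosen to keep the whole suite within a desktop
coffee break while leaving enough detected photons per gate for stable
gate-level statistics.  The annular detector is used for these shared
ensembles (same path-length statistics as the disk, far higher yield).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tddcs.gating import apparent_tofs, build_tpsf
from tddcs.inversion import fit_tpsf_optical_props
from tddcs.irf import DeltaIRF
from tddcs.media import homogeneous_slab, thicken_extracerebral, two_layer_slab
from tddcs.transport import ProbeSpec, simulate_histories

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

#: phantom optical properties (intralipid liquid phantom)
PHANTOM_MUA, PHANTOM_MUSP = 0.14, 4.1
SD_MM = 10.0


@pytest.fixture(scope="session")
def ring_probe() -> ProbeSpec:
    return ProbeSpec(SD_MM, 0.5, "ring")


@pytest.fixture(scope="session")
def phantom_large(ring_probe):
    """Homogeneous phantom, 1e7 launched packets (transport oracle scale)."""
    medium = homogeneous_slab(PHANTOM_MUA, PHANTOM_MUSP, D=6e-6)
    return simulate_histories(medium, ring_probe, 10_000_000, seed=12345)


@pytest.fixture(scope="session")
def two_layer_base(ring_probe):
    """Superficial-over-brain slab (10-mm top layer), 1.5e6 packets."""
    return simulate_histories(two_layer_slab(), ring_probe, 1_500_000, seed=7)


@pytest.fixture(scope="session")
def two_layer_thick(ring_probe):
    """The same slab with the extracerebral layer thickened by 3 mm."""
    medium = thicken_extracerebral(two_layer_slab(), 3.0)
    return simulate_histories(medium, ring_probe, 1_500_000, seed=17)


@pytest.fixture(scope="session")
def homog_fit_ensemble(two_layer_base, ring_probe):
    """Homogeneous fitting histories at the TPSF-recovered properties."""
    tpsf = build_tpsf(
        two_layer_base,
        two_layer_base.medium.mua_cm(),
        apparent_ps=apparent_tofs(two_layer_base, DeltaIRF(), 1),
    )
    mua_f, musp_f = fit_tpsf_optical_props(tpsf, SD_MM, ring_halfwidth_mm=0.5)
    return simulate_histories(
        homogeneous_slab(mua_f, musp_f), ring_probe, 1_500_000, seed=8
    )
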