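"""Shared fixtures: a coarse-but-faithful study setup reused across tests.

The heavy pieces (phantom voxelization, one full simulated acquisition with
its corrected reconstructions) are session-scoped so each test file reuses
them instead of re-simulating.
"""

from __future__ import annotations

import pytest

from petiq.cli_report import StudyConfig, simulate_iq_sinograms
from petiq.corrections import correct_emission
from petiq.iq_metrics import compute_iq_report
from petiq.pgf_sensitivity import PGFTable
from petiq.phantom_geometry import IQPhantomSpec, VoxelGrid
from petiq.reconstruction import fbp_reconstruct
from petiq.synthetic_acquisition import AcquisitionConfig, EnergyWindow


@pytest.fixture(scope="session")
def grid() -> VoxelGrid:
    # 4 mm slices keep the suite fast; in-plane sampling matches the study.
    return VoxelGrid.centered((64, 64, 14), (0.776, 0.776, 4.0))


@pytest.fixture(scope="session")
def iq_spec() -> IQPhantomSpec:
    return IQPhantomSpec(activity_concentration=StudyConfig().iq_activity_bq_per_ml)


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    return AcquisitionConfig(sensitivity_scale=0.1)


@pytest.fixture(scope="session")
def window_750() -> EnergyWindow:
    return EnergyWindow(350, 750)


@pytest.fixture(scope="session")
def simulated_iq(iq_spec, grid, acq, window_750):
    """One noisy IQ acquisition at 350~750 plus its attenuation factors."""
    pgf = PGFTable.reference().lookup(window_750)
    sset, att = simulate_iq_sinograms(
        iq_spec, grid, window_750, pgf, acq, duration_s=4700.0, seed=20160322
    )
    return sset, att, pgf


@pytest.fixture(scope="session")
def corrected_reports(simulated_iq, iq_spec, grid, acq, window_750):
    """IQ reports for the nested correction sets on the shared acquisition."""
    sset, att, pgf = simulated_iq
    reports = {}
    for name, flags in (
        ("AC", dict(apply_scatter=False, apply_prompt_gamma=False)),
        ("AC+SC", dict(apply_scatter=True, apply_prompt_gamma=False)),
        ("AC+SC+PGF", dict(apply_scatter=True, apply_prompt_gamma=True)),
    ):
        emission, ledger = correct_emission(sset, att, pgf, **flags)
        image = fbp_reconstruct(emission, grid, acq, window=window_750)
        reports[name] = compute_iq_report(
            image, iq_spec, window_750, corrections=ledger.names()
        )
    return reports
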