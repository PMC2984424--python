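import numpy as np
import pytest

from segclock.model import Kymograph, ModelParams, simulate

FIG_PARAMS = dict(A=0.5, B=5.0, T0=1.0, z_max=10.0, L0=2.0, t_end=50.0)


@pytest.fixture(scope="session")
def fig_params() -> ModelParams:
    """The published parameter set for the distributed-proliferation run."""
    return ModelParams(**FIG_PARAMS)


@pytest.fixture(scope="session")
def fig_kymo(fig_params) -> Kymograph:
    """One full distributed-variant simulation at default resolution."""
    return simulate(fig_params)


@pytest.fixture(scope="session")
def localized_kymo() -> Kymograph:
    """Progress-zone (age) variant run at reduced cell count."""
    return simulate(ModelParams(**FIG_PARAMS, variant="localized_age", n_cells=400))


def make_synthetic_kymograph(
    rho: np.ndarray,
    z_frozen: np.ndarray,
    freeze_time: np.ndarray,
    params: ModelParams | None = None,
) -> Kymograph:
    """Hand-built kymograph carrying only a cell-level freeze record.

    Synthetic: used to exercise segment analysis on profiles with known
    structure, independently of the simulator.
    """
    p = params or ModelParams(**FIG_PARAMS)
    times = np.array([0.0, p.t_end])
    edges = np.linspace(0.0, p.t_end + p.L0, p.n_space_bins + 1)
    return Kymograph(
        times=times,
        space_edges=edges,
        z_grid=np.full((2, p.n_space_bins), np.nan),
        lengths=times + p.L0,
        front_lo=np.array([np.nan, 0.0]),
        front_hi=np.array([np.nan, np.nanmax(rho) * (p.t_end + p.L0)]),
        frozen_span_cycles=np.zeros(2),
        params=p,
        cell_rho=rho,
        cell_x=rho * (p.t_end + p.L0),
        cell_freeze_time=freeze_time,
        cell_freeze_phase=np.full_like(rho, np.nan),
        cell_z_frozen=z_frozen,
    )
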