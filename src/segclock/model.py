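"""Cellular phase oscillators on a uniformly growing 1D tissue.

The tissue is a one-dimensional continuum of material cells spanning
``[0, L(t)]`` with the anterior end pinned at ``x = 0``.  Growth is uniform
(every material element proliferates at the same relative rate), so under the
linear growth law ``L(t) = t + L0`` each cell's *relative* coordinate
``rho = x / L(t)`` is conserved exactly: cells are advected as
``x(t) = rho * L(t)``.

Each cell carries a phase oscillator whose state is ``z = z_max * cos(phi)``.
Two variants of the period rule are implemented:

``distributed_distance``
    The oscillation period grows linearly with distance ``d = L(t) - x`` from
    the posterior end, ``T(d) = T0 * (1 + A * d)``, so the posterior oscillates
    fastest.  Cells proliferate everywhere (the conserved-``rho`` advection
    above).

``localized_age``
    The classic progress-zone picture: a posterior zone of width ``pz_width``
    oscillates in phase at the base period ``T0``; growth adds new in-phase
    material at the posterior end only, and once a cell is left behind by the
    zone its period grows with its age since exit, ``T(a) = T0 * (1 + A * a)``.

In both variants a cell *freezes* — its state stops oscillating and is held at
the value it had at the freezing instant — when its period reaches the
critical period ``B``.  The frozen region advances anterior-to-posterior and
its alternating-sign state profile is read as a sequence of segments.

For the distributed variant with linear growth the freeze time and the phase
accumulated at freezing admit closed forms (:func:`closed_form_freeze_time`,
:func:`closed_form_freeze_phase`); the simulator is checked against them but
never uses them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "TissueState",
    "Kymograph",
    "FrozenCellError",
    "domain_length",
    "growth_rate",
    "initial_state",
    "advect",
    "oscillation_period",
    "oscillation_period_age",
    "phase_step",
    "freeze_update",
    "cell_state",
    "current_state",
    "simulate",
    "closed_form_freeze_time",
    "closed_form_freeze_phase",
]

VARIANTS = ("distributed_distance", "localized_age")


class FrozenCellError(ValueError):
    """Raised when an oscillator quantity is requested for a frozen cell."""


@dataclass(frozen=True)
class ModelParams:
    """All constants of the oscillator / growth model.

    Parameters
    ----------
    A : float
        Period-gradient coefficient: per unit tissue length (distance variant)
        or per unit age (age variant).
    B : float
        Critical period; a cell freezes when its period reaches ``B``.
    T0 : float
        Base oscillation period at the posterior end (or inside the progress
        zone).
    z_max : float
        Cell-state amplitude bound; ``z = z_max * cos(phi)``.
    L0 : float
        Initial tissue length; the linear growth law is ``L(t) = t + L0``.
    t_end : float
        Simulation horizon.
    dt : float
        Integration timestep; must satisfy ``dt <= T0 / 20``.
    n_cells : int
        Number of material cells at ``t = 0`` (spatial resolution).
    variant : str
        ``"distributed_distance"`` or ``"localized_age"``.
    pz_width : float, optional
        Progress-zone width; only used by the age variant (defaults to ``L0``).
    phi0 : float
        Common initial phase of all cells (radians).
    sample_dt : float
        Kymograph sampling interval.
    n_space_bins : int
        Number of fixed lab-coordinate kymograph bins spanning
        ``[0, L(t_end)]``.
    """

    A: float = 0.5
    B: float = 5.0
    T0: float = 1.0
    z_max: float = 10.0
    L0: float = 2.0
    t_end: float = 50.0
    dt: float = 0.01
    n_cells: int = 4000
    variant: str = "distributed_distance"
    pz_width: float | None = None
    phi0: float = 0.0
    sample_dt: float = 0.1
    n_space_bins: int = 520

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not self.A > 0:
            raise ValueError("A must be positive")
        if not (self.B > self.T0 > 0):
            raise ValueError("need B > T0 > 0")
        if not self.z_max > 0:
            raise ValueError("z_max must be positive")
        if not self.L0 > 0:
            raise ValueError("L0 must be positive")
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")
        if not (0 < self.dt <= self.T0 / 20):
            raise ValueError("need 0 < dt <= T0/20")
        if self.n_cells < 50:
            raise ValueError("n_cells must be >= 50")
        if self.pz_width is None and self.variant == "localized_age":
            object.__setattr__(self, "pz_width", self.L0)
        if self.variant == "localized_age" and not self.pz_width > 0:
            raise ValueError("pz_width must be positive for the localized_age variant")
        if self.n_space_bins < 2:
            raise ValueError("n_space_bins must be >= 2")

    @property
    def d_star(self) -> float:
        """Distance from the posterior at which the period reaches B."""
        return (self.B - self.T0) / (self.A * self.T0)

    @property
    def a_star(self) -> float:
        """Age at which the period reaches B (age variant)."""
        return (self.B - self.T0) / (self.A * self.T0)


@dataclass
class TissueState:
    """Lagrangian cell arrays at one instant.

    ``rho`` is the conserved relative coordinate (distributed variant; NaN for
    the age variant, whose material points do not move).  ``t_exit`` is the
    progress-zone exit time (age variant; cells still inside the zone carry
    their future exit time, which under the linear growth law is known at
    creation).  ``freeze_time``/``freeze_phase``/``z_frozen`` are NaN until a
    cell freezes and immutable afterwards.
    """

    t: float
    rho: np.ndarray
    x: np.ndarray
    phi: np.ndarray
    frozen: np.ndarray
    z_frozen: np.ndarray
    freeze_time: np.ndarray
    freeze_phase: np.ndarray
    t_exit: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.x.size

    def copy(self) -> "TissueState":
        return TissueState(
            t=self.t,
            rho=self.rho.copy(),
            x=self.x.copy(),
            phi=self.phi.copy(),
            frozen=self.frozen.copy(),
            z_frozen=self.z_frozen.copy(),
            freeze_time=self.freeze_time.copy(),
            freeze_phase=self.freeze_phase.copy(),
            t_exit=self.t_exit.copy(),
        )


@dataclass
class Kymograph:
    """Space-time record of a simulation.

    ``z_grid`` holds the cell state on a fixed lab-coordinate grid (rows =
    sample times, columns = space bins spanning ``[0, L(t_end)]``); bins whose
    centre lies outside the tissue at that time carry NaN.  ``front_lo`` /
    ``front_hi`` bound the frozen region per sample time (NaN while nothing is
    frozen); ``frozen_span_cycles`` is the span of frozen phase, in cycles, per
    sample time.  The per-cell ``cell_*`` arrays are the final Lagrangian
    freeze record, kept at full resolution for segment analysis.
    """

    times: np.ndarray
    space_edges: np.ndarray
    z_grid: np.ndarray
    lengths: np.ndarray
    front_lo: np.ndarray
    front_hi: np.ndarray
    frozen_span_cycles: np.ndarray
    params: ModelParams
    cell_rho: np.ndarray
    cell_x: np.ndarray
    cell_freeze_time: np.ndarray
    cell_freeze_phase: np.ndarray
    cell_z_frozen: np.ndarray

    @property
    def space_centers(self) -> np.ndarray:
        return 0.5 * (self.space_edges[:-1] + self.space_edges[1:])

    @property
    def n_bins(self) -> int:
        return self.space_edges.size - 1


# ---------------------------------------------------------------------------
# growth


def domain_length(t, params: ModelParams):
    """Tissue length under the linear uniform-growth law, ``L(t) = t + L0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = t + params.L0
    return float(out) if out.ndim == 0 else out


def growth_rate(t, params: ModelParams):
    """Relative proliferation rate ``r(t) = L'(t)/L(t) = 1/(t + L0)``.

    Uniform in space: every material element grows at this same rate, which is
    what makes ``rho = x/L`` a conserved Lagrangian label.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = 1.0 / (t + params.L0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# state construction and kinematics


def initial_state(params: ModelParams) -> TissueState:
    """All cells in phase ``phi0``, evenly spaced over ``[0, L0]``."""
    n = params.n_cells
    x = np.linspace(0.0, params.L0, n)
    nan = np.full(n, np.nan)
    if params.variant == "distributed_distance":
        rho = x / params.L0
        t_exit = nan.copy()
    else:
        rho = nan.copy()
        # under posterior-only growth a cell at lab position x is overtaken by
        # the zone's anterior edge L(t) - pz_width at t = x + pz_width - L0
        t_exit = np.maximum(0.0, x + params.pz_width - params.L0)
    return TissueState(
        t=0.0,
        rho=rho,
        x=x,
        phi=np.full(n, params.phi0),
        frozen=np.zeros(n, dtype=bool),
        z_frozen=nan.copy(),
        freeze_time=nan.copy(),
        freeze_phase=nan.copy(),
        t_exit=t_exit,
    )


def advect(state: TissueState, dt: float, params: ModelParams) -> TissueState:
    """Advance time by ``dt`` and move cells with the uniform growth flow.

    Distributed variant only: each cell's relative coordinate is conserved
    exactly, ``x_new = rho * L(t + dt)``, with the anterior end fixed at 0.
    Order and cell count are unchanged.
    """
    if params.variant != "distributed_distance":
        raise ValueError("advect applies to the distributed_distance variant")
    new = state.copy()
    new.t = state.t + dt
    new.x = state.rho * domain_length(new.t, params)
    return new


def _grow_posterior(state: TissueState, dt: float, params: ModelParams) -> TissueState:
    """Advance time and append new in-phase cells at the posterior (age variant).

    Material points are fixed in the lab frame; new cells are added so the
    spacing never exceeds the initial spacing ``L0 / (n_cells - 1)``.
    """
    new = state.copy()
    new.t = state.t + dt
    h = params.L0 / (params.n_cells - 1)
    L = domain_length(new.t, params)
    n_add = int(math.floor((L - new.x[-1]) / h))
    if n_add > 0:
        x_add = new.x[-1] + h * np.arange(1, n_add + 1)
        # zone cells are in phase: phase of the zone at creation time
        phi_add = np.full(n_add, params.phi0 + 2.0 * np.pi * new.t / params.T0)
        nan = np.full(n_add, np.nan)
        new.x = np.concatenate([new.x, x_add])
        new.rho = np.concatenate([new.rho, nan])
        new.phi = np.concatenate([new.phi, phi_add])
        new.frozen = np.concatenate([new.frozen, np.zeros(n_add, dtype=bool)])
        new.z_frozen = np.concatenate([new.z_frozen, nan.copy()])
        new.freeze_time = np.concatenate([new.freeze_time, nan.copy()])
        new.freeze_phase = np.concatenate([new.freeze_phase, nan.copy()])
        new.t_exit = np.concatenate(
            [new.t_exit, np.maximum(new.t, x_add + params.pz_width - params.L0)]
        )
    return new


# ---------------------------------------------------------------------------
# oscillator dynamics


def oscillation_period(state: TissueState, cell_index: int, params: ModelParams) -> float:
    """Period of an unfrozen cell in the distance variant, ``T0 * (1 + A*d)``.

    ``d = L(t) - x`` is the distance from the posterior end; the posterior cell
    oscillates at the base period ``T0``.
    """
    if params.variant != "distributed_distance":
        raise ValueError("distance-dependent period applies to distributed_distance")
    if state.frozen[cell_index]:
        raise FrozenCellError("oscillation period is undefined for a frozen cell")
    d = domain_length(state.t, params) - state.x[cell_index]
    return params.T0 * (1.0 + params.A * d)


def oscillation_period_age(age, params: ModelParams):
    """Period as a function of age since progress-zone exit, ``T0 * (1 + A*a)``."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    out = params.T0 * (1.0 + params.A * age)
    return float(out) if out.ndim == 0 else out


def _phase_rate(state: TissueState, t: float, params: ModelParams) -> np.ndarray:
    """Instantaneous ``d(phi)/dt = 2*pi / T`` for every cell at clock time t.

    For the distributed variant the cell trajectory is known exactly
    (``d(t') = u * L(t')`` with ``u = 1 - rho``), so the rate can be evaluated
    at any quadrature node; likewise for the age variant via the precomputed
    zone-exit times (rate is the zone rate before exit).
    """
    if params.variant == "distributed_distance":
        d = (1.0 - state.rho) * domain_length(t, params)
    else:
        d = np.maximum(0.0, t - state.t_exit)  # age, reusing the linear rule
    return 2.0 * np.pi / (params.T0 * (1.0 + params.A * d))


def phase_step(state: TissueState, dt: float, params: ModelParams) -> TissueState:
    """Advance unfrozen phases over ``[t, t + dt]``; frozen cells unchanged.

    The rate ``2*pi/T`` is a known function of clock time along each cell's
    exactly-advected trajectory, so the step reduces to quadrature; Simpson's
    rule on the three nodes (equivalently RK4 for a phi-independent rate) gives
    4th-order accuracy.  Does not advance ``state.t`` (kinematics do).
    """
    t = state.t
    r0 = _phase_rate(state, t, params)
    r1 = _phase_rate(state, t + 0.5 * dt, params)
    r2 = _phase_rate(state, t + dt, params)
    dphi = dt / 6.0 * (r0 + 4.0 * r1 + r2)
    new = state.copy()
    new.phi = np.where(state.frozen, state.phi, state.phi + dphi)
    return new


def freeze_update(state: TissueState, params: ModelParams) -> TissueState:
    """Freeze every unfrozen cell whose period has reached ``B``.

    The threshold crossing generally happens inside the preceding step; its
    exact time is recovered from the linear-in-time threshold condition
    (``d = d_star`` or ``age = a_star``), and the cell's phase is corrected
    back to the crossing instant by Simpson quadrature over the overshoot.
    Frozen values are immutable; re-applying is a no-op.
    """
    if params.variant == "distributed_distance":
        u = 1.0 - state.rho
        d = u * domain_length(state.t, params)
        newly = (~state.frozen) & (d >= params.d_star)
        with np.errstate(divide="ignore"):
            t_cross = np.where(u > 0, params.d_star / np.where(u > 0, u, 1.0) - params.L0, np.inf)
    else:
        age = np.maximum(0.0, state.t - state.t_exit)
        newly = (~state.frozen) & (age >= params.a_star)
        t_cross = state.t_exit + params.a_star
    if not np.any(newly):
        return state

    new = state.copy()
    tc = np.minimum(np.maximum(0.0, t_cross[newly]), new.t)
    delta = new.t - tc
    # phase accumulated between the crossing and now is removed from phi;
    # Simpson over [tc, t] per newly-frozen cell (per-cell node times)
    if params.variant == "distributed_distance":
        u_n = (1.0 - state.rho[newly])

        def rate_at(tq):
            dq = u_n * (tq + params.L0)
            return 2.0 * np.pi / (params.T0 * (1.0 + params.A * dq))

    else:
        te = state.t_exit[newly]

        def rate_at(tq):
            aq = np.maximum(0.0, tq - te)
            return 2.0 * np.pi / (params.T0 * (1.0 + params.A * aq))

    overshoot = delta / 6.0 * (rate_at(tc) + 4.0 * rate_at(tc + 0.5 * delta) + rate_at(tc + delta))
    phi_c = state.phi[newly] - overshoot
    new.frozen[newly] = True
    new.phi[newly] = phi_c
    new.freeze_phase[newly] = phi_c
    new.freeze_time[newly] = tc
    new.z_frozen[newly] = cell_state(phi_c, params)
    return new


def cell_state(phi, params: ModelParams):
    """Observable cell state ``z = z_max * cos(phi)``; bounded by ±z_max."""
    out = params.z_max * np.cos(np.asarray(phi, dtype=float))
    return float(out) if out.ndim == 0 else out


def current_state(state: TissueState, params: ModelParams) -> np.ndarray:
    """Per-cell z: the frozen value where frozen, the oscillating value elsewhere."""
    return np.where(state.frozen, state.z_frozen, cell_state(state.phi, params))


# ---------------------------------------------------------------------------
# simulation loop


def simulate(params: ModelParams) -> Kymograph:
    """Run the model from ``t = 0`` to ``t_end`` and return the space-time record.

    Per step: phase quadrature over the step, kinematics (exact advection, or
    posterior cell addition for the age variant), then the freezing sweep.
    Deterministic for fixed params.
    """
    state = initial_state(params)
    state = freeze_update(state, params)

    n_steps = int(round(params.t_end / params.dt))
    sample_every = max(1, int(round(params.sample_dt / params.dt)))
    L_end = domain_length(params.t_end, params)
    edges = np.linspace(0.0, L_end, params.n_space_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    times, lengths, rows, flo, fhi, spans = [], [], [], [], [], []

    def record(st: TissueState) -> None:
        L = domain_length(st.t, params)
        z = current_state(st, params)
        row = np.interp(centers, st.x, z)
        row[centers > L] = np.nan
        times.append(st.t)
        lengths.append(L)
        rows.append(row)
        if np.any(st.frozen):
            xf = st.x[st.frozen]
            flo.append(float(xf.min()))
            fhi.append(float(xf.max()))
            ph = st.freeze_phase[st.frozen]
            spans.append(float((ph.max() - ph.min()) / (2.0 * np.pi)))
        else:
            flo.append(np.nan)
            fhi.append(np.nan)
            spans.append(0.0)

    record(state)
    for k in range(n_steps):
        dt = params.dt
        state.t = k * dt  # guard against float drift
        state = phase_step(state, dt, params)
        if params.variant == "distributed_distance":
            state = advect(state, dt, params)
        else:
            state = _grow_posterior(state, dt, params)
        state = freeze_update(state, params)
        if (k + 1) % sample_every == 0:
            record(state)

    z_grid = np.vstack(rows)
    inside = ~np.isnan(z_grid)
    if np.any(np.abs(z_grid[inside]) > params.z_max * (1.0 + 1e-9)):
        raise RuntimeError("amplitude bound violated: |z| exceeded z_max")

    return Kymograph(
        times=np.asarray(times),
        space_edges=edges,
        z_grid=z_grid,
        lengths=np.asarray(lengths),
        front_lo=np.asarray(flo),
        front_hi=np.asarray(fhi),
        frozen_span_cycles=np.asarray(spans),
        params=params,
        cell_rho=state.rho.copy(),
        cell_x=state.x.copy(),
        cell_freeze_time=state.freeze_time.copy(),
        cell_freeze_phase=state.freeze_phase.copy(),
        cell_z_frozen=state.z_frozen.copy(),
    )


# ---------------------------------------------------------------------------
# closed-form oracles (distributed variant, linear growth)


def closed_form_freeze_time(u, params: ModelParams):
    """Freeze time of the material cell at relative posterior distance ``u``.

    With conserved ``u = 1 - rho`` the cell's distance from the posterior is
    ``d(t) = u * (t + L0)``, so it reaches the critical distance
    ``d* = (B - T0)/(A*T0)`` at ``t_f(u) = d*/u - L0``.  The posterior end
    (``u -> 0``) never freezes.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u > 1):
        raise ValueError("u must lie in (0, 1]")
    out = params.d_star / u - params.L0
    return float(out) if out.ndim == 0 else out


def closed_form_freeze_phase(u, params: ModelParams):
    """Cycles accumulated at freezing by the cell at relative distance ``u``.

    Integrating ``1/T(d(t))`` with ``d(t) = u*(t + L0)`` from 0 to the freeze
    time gives ``N(u) = ln((B/T0) / (1 + A*L0*u)) / (T0*A*u)``; note
    ``B/T0 = 1 + A*d*``.  Strictly decreasing in ``u``: posterior cells cycle
    more before arrest.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u > 1):
        raise ValueError("u must lie in (0, 1]")
    out = np.log((params.B / params.T0) / (1.0 + params.A * params.L0 * u)) / (
        params.T0 * params.A * u
    )
    return float(out) if out.ndim == 0 else out
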