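"""Time-domain master-equation kinetics of the eight-state gating model.

The paper-constrained quantity is the equilibrium landscape; transition
rates are a kinetic realization chosen here. Each of the twelve cube edges
connects two states differing in one module (gate, voltage sensor or
temperature sensor). With ``ΔG_ij = ln w_j − ln w_i`` the log equilibrium
constant of the edge (statistical weights from the gating module, so the
allosteric factors are included), the activating rate is
``k_ref·exp(phi·ΔG)`` and the deactivating rate ``k_ref·exp((phi−1)·ΔG)``.
Deriving both rates from the state free energies makes every closed cycle
satisfy detailed balance by construction, and the stationary distribution
of the generator is exactly the equilibrium state-weight vector.

Propagation is by matrix exponential: exact on piecewise-constant (V, T)
segments, with temperature ramps discretized at the sample interval and
evaluated at the interval midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .constants import celsius_to_kelvin
from .gating import log_state_weights, state_weights
from .parameters import GatingParameters

#: Validity bound on the temperature slew rate implied by a protocol (°C/s).
MAX_SLEW_C_PER_S = 120.0


@dataclass(frozen=True)
class RateRules:
    """Reference rates (s⁻¹) per transition class and the equilibrium split.

    ``phi`` apportions an edge's equilibrium constant between forward and
    backward rates (forward = k_ref·Keq^phi, backward = k_ref·Keq^(phi−1)).
    Defaults put voltage-step relaxations in the tens-of-milliseconds range
    observed for whole-cell TRPA1 currents.

    ``k_max`` caps the faster rate of every edge (default 1e8 s⁻¹ — faster
    transitions are unphysical for conformational changes). The cap rescales
    forward and backward rates together, so each edge's equilibrium ratio,
    and with it detailed balance and the stationary distribution, is exact;
    only the relaxation speed of the saturated edge is reduced.
    """

    k_gate: float = 100.0
    k_vsensor: float = 400.0
    k_tsensor: float = 400.0
    phi: float = 0.5
    k_max: float = 1e8

    def __post_init__(self):
        if min(self.k_gate, self.k_vsensor, self.k_tsensor) <= 0:
            raise ValueError("reference rates must be > 0")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.k_max <= 0:
            raise ValueError("k_max must be > 0")


@dataclass(frozen=True)
class Segment:
    """One protocol segment: constant voltage, linear temperature course."""

    duration_s: float
    voltage_mv: float
    temp_start_c: float
    temp_end_c: float

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("segment duration must be > 0")
        slew = abs(self.temp_end_c - self.temp_start_c) / self.duration_s
        if slew > MAX_SLEW_C_PER_S:
            raise ValueError(
                f"implied temperature slew {slew:.1f} °C/s exceeds "
                f"{MAX_SLEW_C_PER_S} °C/s"
            )


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise voltage/temperature stimulus sampled at interval ``dt_s``."""

    segments: tuple
    dt_s: float

    def __post_init__(self):
        if self.dt_s <= 0:
            raise ValueError("dt must be > 0")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        shortest = min(s.duration_s for s in self.segments)
        if self.dt_s > shortest + 1e-12:
            raise ValueError(
                f"dt={self.dt_s} s exceeds the shortest segment ({shortest} s)"
            )

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    def sample(self):
        """Return (times, voltage, temperature, T_mid) on the dt grid.

        ``times``/``voltage``/``temperature`` are instantaneous values at
        the N+1 sample instants including the closing right edge (used for
        current synthesis and trigger logic); ``T_mid`` and ``dts`` (length
        N) give each propagation interval's midpoint temperature and exact
        width (segments whose duration is not an integer multiple of dt use
        the nearest uniform subdivision), which keeps step segments
        propagator-exact and ramps second-order accurate.
        """
        times, volts, temps, t_mid, dts = [], [], [], [], []
        t0 = 0.0
        for seg in self.segments:
            n = max(1, int(round(seg.duration_s / self.dt_s)))
            k = np.arange(n)
            dT = seg.temp_end_c - seg.temp_start_c
            times.append(t0 + k * (seg.duration_s / n))
            volts.append(np.full(n, seg.voltage_mv))
            temps.append(seg.temp_start_c + (k / n) * dT)
            t_mid.append(seg.temp_start_c + ((k + 0.5) / n) * dT)
            dts.append(np.full(n, seg.duration_s / n))
            t0 += seg.duration_s
        last = self.segments[-1]
        times.append([t0])
        volts.append([last.voltage_mv])
        temps.append([last.temp_end_c])
        return (
            np.concatenate(times),
            np.concatenate(volts),
            np.concatenate(temps),
            np.concatenate(t_mid),
            np.concatenate(dts),
        )


def protocol_from_rows(rows: Sequence[Sequence[float]], dt_s: float) -> StimulusProtocol:
    """Build a protocol from (duration_s, voltage_mV, temp_start_C, temp_end_C) rows."""
    return StimulusProtocol(
        segments=tuple(Segment(*map(float, r)) for r in rows), dt_s=dt_s
    )


# Cube edges: (state i, state j, flag index) with j = i plus one active
# module; flag 0 = voltage sensor, 1 = temperature sensor, 2 = gate.
_EDGES = []
for o in (0, 1):
    for vbit in (0, 1):
        for tbit in (0, 1):
            i = 4 * o + vbit + 2 * tbit
            if not vbit:
                _EDGES.append((i, i + 1, 0))
            if not tbit:
                _EDGES.append((i, i + 2, 1))
            if not o:
                _EDGES.append((i, i + 4, 2))
assert len(_EDGES) == 12


def build_generator(p: GatingParameters, r: RateRules, v_mv: float, t_k: float):
    """8×8 transition-rate matrix Q (q[i, j] = rate i→j, rows sum to 0)."""
    lw = log_state_weights(v_mv, t_k, p)
    kref = (r.k_vsensor, r.k_tsensor, r.k_gate)
    lkmax = np.log(r.k_max)
    q = np.zeros((8, 8))
    for i, j, flag in _EDGES:
        dg = lw[j] - lw[i]
        lkf = np.log(kref[flag]) + r.phi * dg
        lkb = np.log(kref[flag]) + (r.phi - 1.0) * dg
        # cap the faster rate, shifting both log-rates equally (edge
        # equilibrium ratio — hence detailed balance — preserved exactly)
        excess = max(lkf, lkb) - lkmax
        if excess > 0:
            lkf -= excess
            lkb -= excess
        q[i, j] = np.exp(lkf)
        q[j, i] = np.exp(lkb)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@dataclass(frozen=True)
class OccupancyTrace:
    """Time series of the eight state probabilities under a protocol."""

    times_s: np.ndarray
    occupancy: np.ndarray  # (n, 8)
    po: np.ndarray
    voltage_mv: np.ndarray
    temperature_c: np.ndarray
    protocol: StimulusProtocol
    regime: np.ndarray | None = None  # per-sample regime label, if scheduled
    switch_times_s: tuple = field(default=())

    def __post_init__(self):
        if np.any(np.abs(self.occupancy.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("state probabilities must sum to 1 at every step")


def _propagate(m, vec):
    """One propagator application with a guarded float-drift projection.

    The matrix exponential conserves probability analytically; accumulated
    rounding (large stiffness ratios) is projected back onto the simplex,
    and any drift beyond 1e-6 — which would indicate a genuinely broken
    propagator — raises instead of being silently normalized away.
    """
    out = m @ vec
    s = out.sum()
    if not np.isfinite(s) or abs(s - 1.0) > 1e-6:
        raise FloatingPointError(
            f"propagation lost probability mass (sum={s!r}); "
            "the generator is numerically unstable at these parameters"
        )
    np.clip(out, 0.0, None, out=out)
    return out / out.sum()


def _resolve_initial(initial, p, v0, t0_k):
    if isinstance(initial, str):
        if initial != "equilibrium":
            raise ValueError(f"unknown initial condition {initial!r}")
        return state_weights(v0, t0_k, p)
    vec = np.asarray(initial, dtype=float)
    if vec.shape != (8,) or abs(vec.sum() - 1.0) > 1e-9 or np.any(vec < 0):
        raise ValueError("initial occupancy must be a probability 8-vector")
    return vec


class _PropagatorCache(dict):
    """Memoize expm(Qᵀ·dt) keyed by (regime, V, T, dt rounded)."""

    def __init__(self, rates: RateRules):
        super().__init__()
        self.rates = rates

    def get_matrix(self, regime, p, v, t_k, dt):
        key = (regime, round(float(v), 9), round(float(t_k), 9), round(float(dt), 12))
        m = self.get(key)
        if m is None:
            m = expm(build_generator(p, self.rates, v, t_k).T * dt)
            self[key] = m
        return m


def simulate(
    p: GatingParameters,
    r: RateRules,
    protocol: StimulusProtocol,
    initial="equilibrium",
) -> OccupancyTrace:
    """Evolve the master equation under a protocol.

    Propagation within each dt interval uses the matrix exponential of the
    generator evaluated at the segment voltage and the midpoint temperature,
    which is exact for piecewise-constant (V, T).
    """
    times, volts, temps, t_mid, dts = protocol.sample()
    t_mid_k = celsius_to_kelvin(t_mid)
    occ = np.empty((len(times), 8))
    occ[0] = _resolve_initial(initial, p, volts[0], celsius_to_kelvin(temps[0]))
    cache = _PropagatorCache(r)
    for k in range(len(t_mid)):
        occ[k + 1] = _propagate(cache.get_matrix(None, p, volts[k], t_mid_k[k], dts[k]), occ[k])
    po = occ[:, 4:].sum(axis=1)
    return OccupancyTrace(
        times_s=times,
        occupancy=occ,
        po=po,
        voltage_mv=volts,
        temperature_c=temps,
        protocol=protocol,
    )


@dataclass(frozen=True)
class RegimeTrigger:
    """Latch rule: switch to ``regime`` once the condition holds for ``dwell_s``.

    The condition is a conjunction of the thresholds that are not None.
    """

    regime: str
    t_min_c: float | None = None
    v_min_mv: float | None = None
    dwell_s: float = 0.0

    def holds(self, v_mv: float, t_c: float) -> bool:
        ok = True
        if self.t_min_c is not None:
            ok &= t_c >= self.t_min_c
        if self.v_min_mv is not None:
            ok &= v_mv >= self.v_min_mv
        return bool(ok)


@dataclass(frozen=True)
class RegimeSchedule:
    """Ordered latch rules; later rules escalate over earlier ones.

    Once a rule fires its regime stays latched; a rule can only fire after
    all preceding rules have latched (the blue→green→red sequence is an
    escalation, not a free switch).
    """

    initial_regime: str = "blue"
    triggers: tuple = ()

    def validate(self, defined: set):
        labels = [self.initial_regime] + [t.regime for t in self.triggers]
        unknown = [x for x in labels if x not in defined]
        if unknown:
            raise ValueError(f"schedule references undefined regimes: {unknown}")


def default_schedule() -> RegimeSchedule:
    """Heat latch (green) above 60 °C; concurrent V+heat latch (red) ≥ 0.5 s.

    Thresholds mirror the experimental observations that heat steps above
    60 °C irreversibly reduce subsequent depolarization responses, and that
    concurrent depolarization + noxious heat renders the channel
    cold-sensitized. Both are configurable.
    """
    return RegimeSchedule(
        initial_regime="blue",
        triggers=(
            RegimeTrigger(regime="green", t_min_c=60.0),
            RegimeTrigger(regime="red", t_min_c=60.0, v_min_mv=80.0, dwell_s=0.5),
        ),
    )


def simulate_with_regimes(
    params_by_regime: dict,
    schedule: RegimeSchedule,
    r: RateRules,
    protocol: StimulusProtocol,
    initial="equilibrium",
) -> OccupancyTrace:
    """Master-equation simulation with latched regime (parameter-set) switches.

    The occupancy vector is carried across each switch unchanged — only the
    generator changes — so state probabilities are continuous and transient
    P_o excursions at switches arise from relaxation toward the new
    landscape's equilibrium.
    """
    schedule.validate(set(params_by_regime))
    times, volts, temps, t_mid, dts = protocol.sample()
    t_mid_k = celsius_to_kelvin(t_mid)

    regime_idx = 0  # position in the escalation chain
    chain = [schedule.initial_regime] + [t.regime for t in schedule.triggers]
    dwell = np.zeros(len(schedule.triggers))
    occ = np.empty((len(times), 8))
    regimes = np.empty(len(times), dtype=object)
    switches = []
    p = params_by_regime[chain[0]]
    occ[0] = _resolve_initial(initial, p, volts[0], celsius_to_kelvin(temps[0]))
    cache = _PropagatorCache(r)
    for k in range(len(times)):
        # advance the escalation chain as latch conditions accumulate dwell
        while regime_idx < len(schedule.triggers):
            trig = schedule.triggers[regime_idx]
            if trig.holds(volts[k], temps[k]):
                dwell[regime_idx] += dts[k - 1] if k > 0 else 0.0
                if dwell[regime_idx] >= trig.dwell_s:
                    regime_idx += 1
                    switches.append(times[k])
                    continue
            else:
                dwell[regime_idx] = 0.0
            break
        regime = chain[regime_idx]
        regimes[k] = regime
        if k < len(times) - 1:
            p = params_by_regime[regime]
            m = cache.get_matrix(regime, p, volts[k], t_mid_k[k], dts[k])
            occ[k + 1] = _propagate(m, occ[k])
    po = occ[:, 4:].sum(axis=1)
    return OccupancyTrace(
        times_s=times,
        occupancy=occ,
        po=po,
        voltage_mv=volts,
        temperature_c=temps,
        protocol=protocol,
        regime=regimes,
        switch_times_s=tuple(switches),
    )


def occupancy_to_current(
    trace: OccupancyTrace, n_channels: int, g_ns: float, vrev_mv: float = 0.0
):
    """Macroscopic current I(t) = N·g·P_o(t)·(V(t) − Vrev), in pA (g in nS, V in mV)."""
    if n_channels < 1:
        raise ValueError("channel count must be ≥ 1")
    if g_ns <= 0:
        raise ValueError("single-channel conductance must be > 0")
    return n_channels * g_ns * trace.po * (trace.voltage_mv - vrev_mv)
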