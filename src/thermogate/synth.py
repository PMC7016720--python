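"""Synthetic whole-cell recordings under the study's stimulation protocols.

The generator is a forward model of a voltage/temperature-clamp experiment:
gating from the eight-state master equation, ohmic conduction
(I = N·g·P_o·(V − Vrev)), additive Gaussian recording noise shaped by a
single-pole low-pass filter emulating the 2 kHz Bessel character of the
amplifier chain. Every recording embeds its ground truth so estimation
stages can be validated without any external data.

What it does not emulate: series-resistance and capacitance transients,
seal leak (optionally injectable as a constant conductance), 1/f noise,
Ca²⁺-dependent potentiation/inactivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import (
    OccupancyTrace,
    RateRules,
    RegimeSchedule,
    Segment,
    StimulusProtocol,
    default_schedule,
    occupancy_to_current,
    simulate,
    simulate_with_regimes,
)
from .parameters import GatingParameters
from .regimes import blue_parameters


@dataclass(frozen=True)
class RecordingSpec:
    """Acquisition model: channel count, conductance, noise and filtering.

    Defaults: 5000 channels × 0.1 nS with Vrev = 0 mV (symmetric monovalent
    solutions), 5 pA r.m.s. noise before filtering, 10 kHz sampling with a
    2 kHz single-pole low-pass — a typical whole-cell acquisition chain.
    Absolute current amplitudes are not data-constrained (channel counts
    are unpublished); shapes and ratios are the meaningful outputs.
    """

    n_channels: int = 5000
    g_ns: float = 0.1
    vrev_mv: float = 0.0
    noise_sd_pa: float = 5.0
    filter_cutoff_khz: float = 2.0
    sample_rate_khz: float = 10.0
    leak_ns: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.noise_sd_pa < 0:
            raise ValueError("noise sd must be ≥ 0")
        if self.sample_rate_khz < 2 * self.filter_cutoff_khz:
            raise ValueError("sample rate must be ≥ 2× the filter cutoff")

    @property
    def dt_s(self) -> float:
        return 1.0 / (self.sample_rate_khz * 1000.0)


@dataclass(frozen=True)
class SyntheticRecording:
    """A noisy current trace with embedded ground truth."""

    time_s: np.ndarray
    voltage_mv: np.ndarray
    temperature_c: np.ndarray
    current_pa: np.ndarray
    ground_truth: dict = field(compare=False)
    occupancy_trace: OccupancyTrace | None = field(default=None, compare=False)

    def __post_init__(self):
        n = len(self.time_s)
        if not (len(self.voltage_mv) == len(self.temperature_c) == len(self.current_pa) == n):
            raise ValueError("all series must have equal length")


# --------------------------------------------------------------------------
# Stimulation protocols
# --------------------------------------------------------------------------

def protocol_voltage_steps(
    variant: str, temperature_c: float = 25.0, dt_s: float = 1e-4
) -> list[StimulusProtocol]:
    """The two I–V families, one :class:`StimulusProtocol` per sweep.

    Variant "A": 400-ms steps −150→+100 mV in +25 mV increments, each
    followed by a 400-ms tail at −150 mV, holding 0 mV (11 sweeps).
    Variant "B": 100-ms steps −80→+200 mV in +20 mV increments, holding
    −70 mV (15 sweeps).
    """
    tc = float(temperature_c)
    if variant == "A":
        steps = np.arange(-150.0, 101.0, 25.0)
        hold, step_s, tail = 0.0, 0.4, (-150.0, 0.4)
        pre = 0.1
    elif variant == "B":
        steps = np.arange(-80.0, 201.0, 20.0)
        hold, step_s, tail = -70.0, 0.1, None
        pre = 0.05
    else:
        raise ValueError(f"unknown voltage-step variant {variant!r}")
    sweeps = []
    for v in steps:
        segs = [Segment(pre, hold, tc, tc), Segment(step_s, float(v), tc, tc)]
        if tail is not None:
            segs.append(Segment(tail[1], tail[0], tc, tc))
        segs.append(Segment(pre, hold, tc, tc))
        sweeps.append(StimulusProtocol(segments=tuple(segs), dt_s=dt_s))
    return sweeps


def protocol_temperature(
    variant: str,
    voltage_mv: float = 80.0,
    dt_s: float = 2e-3,
    order: str = "voltage_first",
    peak_temp_c: float = 61.0,
    base_temp_c: float = 6.0,
) -> StimulusProtocol:
    """Temperature-stimulation protocols.

    * ``"staircase"`` — increasing 3-s temperature steps ~11→~52 °C at a
      constant +80 mV holding potential.
    * ``"ramp"`` — 25→60 °C at 35 °C/s (1-s rise) and back, at a fixed
      holding potential (±80 mV).
    * ``"interleaved"`` — interleaved 10-s depolarizations (−70→+80 mV) and ~5-s
      heat steps at a cold base temperature, ending with a concurrent
      depolarization + heat episode and a cold repolarization; ``order``
      selects whether depolarization or heat comes first in the concurrent
      episode, and ``peak_temp_c`` sets the heat-step ceiling.
    """
    if variant == "staircase":
        temps = np.linspace(11.0, 52.0, 12)
        segs = [Segment(1.0, voltage_mv, temps[0], temps[0])]
        for prev, nxt in zip(temps[:-1], temps[1:]):
            segs.append(Segment(0.2, voltage_mv, prev, nxt))
            segs.append(Segment(2.8, voltage_mv, nxt, nxt))
        return StimulusProtocol(segments=tuple(segs), dt_s=dt_s)

    if variant == "ramp":
        v = voltage_mv
        segs = (
            Segment(1.0, v, 25.0, 25.0),
            Segment(1.0, v, 25.0, 60.0),   # 35 °C/s
            Segment(0.5, v, 60.0, 60.0),
            Segment(1.0, v, 60.0, 25.0),
            Segment(1.0, v, 25.0, 25.0),
        )
        return StimulusProtocol(segments=segs, dt_s=dt_s)

    if variant == "interleaved":
        b, pk = base_temp_c, peak_temp_c
        rise = max(abs(pk - b) / 100.0, dt_s)  # ≤ ~110 °C/s heating hardware
        hold = lambda d, v: Segment(d, v, b, b)
        heat_up = lambda v: Segment(rise, v, b, pk)
        heat_dn = lambda v: Segment(rise, v, pk, b)
        segs = [hold(2.0, -70.0), hold(10.0, 80.0), hold(3.0, -70.0)]
        # solitary heat step at rest
        segs += [heat_up(-70.0), Segment(5.0, -70.0, pk, pk), heat_dn(-70.0)]
        segs += [hold(3.0, -70.0), hold(10.0, 80.0), hold(3.0, -70.0)]
        # concurrent depolarization + heat
        if order == "voltage_first":
            segs += [hold(2.0, 80.0), heat_up(80.0),
                     Segment(5.0, 80.0, pk, pk), heat_dn(80.0), hold(2.0, 80.0)]
        elif order == "heat_first":
            segs += [heat_up(-70.0), Segment(1.0, -70.0, pk, pk),
                     Segment(5.0, 80.0, pk, pk), heat_dn(80.0), hold(2.0, 80.0)]
        else:
            raise ValueError(f"unknown order {order!r}")
        segs += [hold(8.0, -70.0)]  # cold repolarization
        return StimulusProtocol(segments=tuple(segs), dt_s=dt_s)

    raise ValueError(f"unknown temperature-protocol variant {variant!r}")


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------

def _lowpass(x: np.ndarray, cutoff_khz: float, dt_s: float) -> np.ndarray:
    """Single-pole low-pass (bilinear alpha) along the last axis."""
    from scipy.signal import lfilter

    alpha = 1.0 - np.exp(-2.0 * np.pi * cutoff_khz * 1000.0 * dt_s)
    return lfilter([alpha], [1.0, -(1.0 - alpha)], x)


def synthesize(
    params: GatingParameters | dict,
    protocol: StimulusProtocol,
    spec: RecordingSpec = RecordingSpec(),
    rates: RateRules | None = None,
    schedule: RegimeSchedule | None = None,
    initial="equilibrium",
) -> SyntheticRecording:
    """Generate one noisy whole-cell recording.

    ``params`` may be a single :class:`GatingParameters` (no regime
    switching) or a ``{label: GatingParameters}`` mapping with a
    :class:`RegimeSchedule`. Bit-reproducible for a given ``spec.seed``.
    """
    rates = rates or RateRules()
    if isinstance(params, dict):
        sched = schedule or default_schedule()
        trace = simulate_with_regimes(params, sched, rates, protocol, initial=initial)
        truth_params = {k: v.to_dict() for k, v in params.items()}
        truth_schedule = {
            "initial_regime": sched.initial_regime,
            "triggers": [
                {"regime": t.regime, "t_min_c": t.t_min_c,
                 "v_min_mv": t.v_min_mv, "dwell_s": t.dwell_s}
                for t in sched.triggers
            ],
        }
    else:
        if schedule is not None:
            raise ValueError("a schedule requires a mapping of regime parameter sets")
        trace = simulate(params, rates, protocol, initial=initial)
        truth_params = params.to_dict()
        truth_schedule = None

    current = occupancy_to_current(trace, spec.n_channels, spec.g_ns, spec.vrev_mv)
    if spec.leak_ns:
        current = current + spec.leak_ns * (trace.voltage_mv - spec.vrev_mv)
    if spec.noise_sd_pa > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd_pa, size=current.shape)
        current = current + _lowpass(noise, spec.filter_cutoff_khz, protocol.dt_s)

    truth = {
        "params": truth_params,
        "schedule": truth_schedule,
        "rates": {"k_gate": rates.k_gate, "k_vsensor": rates.k_vsensor,
                  "k_tsensor": rates.k_tsensor, "phi": rates.phi},
        "recording_spec": {
            "n_channels": spec.n_channels, "g_ns": spec.g_ns,
            "vrev_mv": spec.vrev_mv, "noise_sd_pa": spec.noise_sd_pa,
            "filter_cutoff_khz": spec.filter_cutoff_khz,
            "sample_rate_khz": spec.sample_rate_khz, "leak_ns": spec.leak_ns,
            "seed": spec.seed,
        },
    }
    return SyntheticRecording(
        time_s=trace.times_s,
        voltage_mv=trace.voltage_mv,
        temperature_c=trace.temperature_c,
        current_pa=current,
        ground_truth=truth,
        occupancy_trace=trace,
    )


# --------------------------------------------------------------------------
# Orthologue presets
# --------------------------------------------------------------------------

def orthologue_presets(name: str) -> tuple[GatingParameters, RateRules]:
    """Gating parameters + kinetics for the channel variants studied.

    ``hTRPA1`` is the calibrated blue landscape with rate constants tuned so
    the −150 mV tail relaxation is bi-exponential on the published 5/28 ms
    scale. ``mTRPA1`` differs only in a larger intrinsic gating equilibrium
    ``L`` (visible basal conductance at negative potentials) and faster
    sensor kinetics that collapse the tail to a mono-exponential (~9 ms).
    ``hTRPA1-S804N`` models the slow-gating mutant (drastically reduced
    gate rate, left-shifted activation through a larger L). Only the
    features described above are data-constrained; the remaining numbers
    are package choices (see docs/methods.md).
    """
    blue = blue_parameters()
    presets = {
        # hTRPA1: slow voltage sensor comparable to the gate -> the -150 mV
        # tail resolves two components (~2.6/16 ms at 25 C)
        "hTRPA1": (
            blue.replace(label="hTRPA1"),
            RateRules(k_gate=10.0, k_vsensor=100.0, k_tsensor=400.0, k_max=1500.0),
        ),
        # mTRPA1: 6x L gives ~12% basal at (-150 mV, 25 C) vs 2.3% for
        # hTRPA1; fast sensors collapse the tail to one ~11 ms exponential
        "mTRPA1": (
            blue.replace(L=blue.L * 6.0, label="mTRPA1"),
            RateRules(k_gate=30.0, k_vsensor=3000.0, k_tsensor=400.0, k_max=1500.0),
        ),
        # S804N-like slow-gating mutant: large basal, ~200 ms deactivation
        "hTRPA1-S804N": (
            blue.replace(L=blue.L * 12.0, label="hTRPA1-S804N"),
            RateRules(k_gate=2.0, k_vsensor=40.0, k_tsensor=400.0, k_max=1500.0),
        ),
    }
    try:
        return presets[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None
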