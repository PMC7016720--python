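"""Equilibrium thermodynamics of the eight-state allosteric gating model.

The channel's eight states are the product of gate × voltage-sensor ×
temperature-sensor configurations. Each state carries a Boltzmann
statistical weight that is a product of the module equilibrium constants
(L, K, J) and the coupling factors (C, D, E) of whichever modules are
simultaneously active:

===========  =============================
state        weight
===========  =============================
C··          1
C·V          K
C·T          J
C·VT         J·K·E
O··          L
O·V          L·K·D
O·T          L·J·C
O·VT         L·J·K·C·D·E
===========  =============================

The open probability is the open-state mass over the partition function.
All weights are handled in log space (log-sum-exp) because ΔH° = 91
kcal·mol⁻¹ drives exponents far beyond float range at modest temperature
excursions; P_o saturates to 0/1 instead of overflowing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .constants import F, R_J, R_KCAL, celsius_to_kelvin
from .parameters import (
    CouplingParams,
    GatingParameters,
    ThermoSensorParams,
    VoltageSensorParams,
)

#: State ordering used throughout the package (closed quartet then open
#: quartet; within a quartet: both sensors resting, V active, T active, both).
STATE_NAMES = ("C", "C_V", "C_T", "C_VT", "O", "O_V", "O_T", "O_VT")

#: Index of the open-state block.
OPEN_STATES = (4, 5, 6, 7)


def _check_temperature(t_k):
    t = np.asarray(t_k, dtype=float)
    if np.any(t <= 0):
        raise ValueError("absolute temperature must be > 0 K")
    return t


def log_sensor_J(t_k, p: ThermoSensorParams):
    """ln J(T) = −(ΔH° − TΔS°)/RT, R in kcal units."""
    t = _check_temperature(t_k)
    return -(p.dH - t * p.dS) / (R_KCAL * t)


def sensor_J(t_k, p: ThermoSensorParams):
    """Temperature-sensor equilibrium constant J(T) = exp[−(ΔH° − TΔS°)/RT]."""
    return np.exp(log_sensor_J(t_k, p))


def log_sensor_K(v_mv, t_k, p: VoltageSensorParams):
    """ln K(V) = ln K0 + zFV/RT (V in mV)."""
    t = _check_temperature(t_k)
    v = np.asarray(v_mv, dtype=float)
    return np.log(p.K0) + p.z * F * (v / 1000.0) / (R_J * t)


def sensor_K(v_mv, t_k, p: VoltageSensorParams):
    """Voltage-sensor equilibrium constant K(V) = K0·exp(zFV/RT)."""
    return np.exp(log_sensor_K(v_mv, t_k, p))


def log_coupling_C(t_k, p: CouplingParams):
    """ln C(T) = −(ΔH°c − TΔS°c)/RT."""
    t = _check_temperature(t_k)
    return -(p.dHc - t * p.dSc) / (R_KCAL * t)


def coupling_C(t_k, p: CouplingParams):
    """Temperature-dependent sensor↔gate coupling C(T) = exp[−(ΔH°c − TΔS°c)/RT]."""
    return np.exp(log_coupling_C(t_k, p))


def log_state_weights(v_mv, t_k, p: GatingParameters):
    """Unnormalized log statistical weights, shape ``broadcast(V,T) + (8,)``."""
    lnJ = log_sensor_J(t_k, p.tsensor)
    lnK = log_sensor_K(v_mv, t_k, p.vsensor)
    lnC = log_coupling_C(t_k, p.coupling)
    lnJ, lnK, lnC = np.broadcast_arrays(lnJ, lnK, lnC)
    lnL = np.log(p.L)
    lnD = np.log(p.coupling.D)
    lnE = np.log(p.coupling.E)
    zero = np.zeros_like(lnJ)
    return np.stack(
        [
            zero,
            lnK,
            lnJ,
            lnJ + lnK + lnE,
            zero + lnL,
            lnL + lnK + lnD,
            lnL + lnJ + lnC,
            lnL + lnJ + lnK + lnC + lnD + lnE,
        ],
        axis=-1,
    )


def state_weights(v_mv, t_k, p: GatingParameters):
    """Normalized equilibrium occupancies of the 8 states (sum to 1).

    The open-state mass (last four entries) equals :func:`open_probability`.
    """
    return softmax(log_state_weights(v_mv, t_k, p), axis=-1)


def open_probability(v_mv, t_k, p: GatingParameters):
    """Closed-form equilibrium open probability of the eight-state model.

    P_o = L(1 + KD + JC + JKCDE) / [(1 + K + J + JKE) + L(1 + KD + JC + JKCDE)],
    evaluated by log-sum-exp so that extreme exponents saturate to 0/1.
    """
    lw = log_state_weights(v_mv, t_k, p)
    lse_open = logsumexp(lw[..., 4:], axis=-1)
    lse_all = logsumexp(lw, axis=-1)
    return np.exp(lse_open - lse_all)


@dataclass(frozen=True)
class PoLandscape:
    """Open probability evaluated on a voltage × temperature grid.

    ``po[i, j]`` is P_o at ``temperatures_c[i]`` and ``voltages_mv[j]``.
    """

    voltages_mv: np.ndarray
    temperatures_c: np.ndarray
    po: np.ndarray
    params: GatingParameters

    def __post_init__(self):
        if self.po.shape != (len(self.temperatures_c), len(self.voltages_mv)):
            raise ValueError("po matrix shape does not match the grids")


def _validated_grid(values, name):
    g = np.asarray(values, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError(f"{name} grid must be a non-empty 1-D array")
    if g.size > 1:
        d = np.diff(g)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError(f"{name} grid must be strictly monotone")
    return g


def landscape(p: GatingParameters, voltages_mv, temperatures_c) -> PoLandscape:
    """Evaluate P_o on monotone (mV, °C) grids; temperatures converted to K internally."""
    v = _validated_grid(voltages_mv, "voltage")
    t = _validated_grid(temperatures_c, "temperature")
    t_k = celsius_to_kelvin(t)
    po = open_probability(v[np.newaxis, :], t_k[:, np.newaxis], p)
    return PoLandscape(voltages_mv=v, temperatures_c=t, po=po, params=p)
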