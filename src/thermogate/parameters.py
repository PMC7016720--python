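"""Parameter containers for the eight-state allosteric gating model.

The model factorizes the channel into three two-state modules — the pore
gate (closed/open, intrinsic equilibrium constant ``L``), a voltage sensor
(resting/active, equilibrium constant ``K(V) = K0·exp(zFV/RT)``) and a
temperature sensor (resting/active, ``J(T) = exp[−(ΔH° − TΔS°)/RT]``) —
joined by three allosteric coupling factors: ``D`` (voltage sensor ↔ gate),
``C(T) = exp[−(ΔH°c − TΔS°c)/RT]`` (temperature sensor ↔ gate, itself
temperature dependent so that the coupling can invert sign with warming)
and ``E`` (voltage sensor ↔ temperature sensor).

Sign convention: ``z > 0`` means the voltage sensor is activated by
depolarization. Parameter files using the opposite exponent convention
(negative ``z`` for a depolarization-activated sensor) are normalized on
load; see :meth:`GatingParameters.from_dict`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Sanity bound on the apparent gating charge (elementary charges).
Z_MAX = 4.0


class ParameterError(ValueError):
    """Raised when a gating-parameter set violates its invariants."""


@dataclass(frozen=True)
class ThermoSensorParams:
    """Temperature-sensor equilibrium: ΔH° and ΔS° of the resting→active step.

    dH : kcal·mol⁻¹; dS : kcal·mol⁻¹·K⁻¹. For dH, dS > 0 the sensor
    half-activates at T½ = dH/dS and J(T) increases with temperature.
    """

    dH: float
    dS: float

    def __post_init__(self):
        if not (self.dH == self.dH and self.dS == self.dS):  # NaN guard
            raise ParameterError("thermo-sensor dH/dS must be finite numbers")

    @property
    def half_activation_temperature_k(self) -> float:
        """T at which J = 1 (K); inf if dS == 0."""
        return self.dH / self.dS if self.dS != 0 else float("inf")


@dataclass(frozen=True)
class VoltageSensorParams:
    """Voltage-sensor equilibrium: K(V) = K0·exp(zFV/RT).

    K0 : dimensionless equilibrium constant at 0 mV (> 0);
    z : apparent gating charge in elementary charges, |z| ≤ 4.
    """

    K0: float
    z: float

    def __post_init__(self):
        if self.K0 <= 0:
            raise ParameterError(f"K0 must be > 0, got {self.K0}")
        if abs(self.z) > Z_MAX:
            raise ParameterError(f"|z| must be ≤ {Z_MAX}, got {self.z}")


@dataclass(frozen=True)
class CouplingParams:
    """Allosteric couplings: D (V-sensor↔gate), E (V↔T sensors), C(T) (T-sensor↔gate).

    dHc, dSc parameterize C(T) = exp[−(dHc − T·dSc)/RT] (kcal units);
    C < 1 is an unfavorable ("inverted") coupling, C > 1 favorable.
    """

    D: float
    E: float
    dHc: float
    dSc: float

    def __post_init__(self):
        if self.D <= 0 or self.E <= 0:
            raise ParameterError("coupling factors D and E must be > 0")


@dataclass(frozen=True)
class GatingParameters:
    """Complete parameter set defining one P_o(V, T) landscape."""

    L: float
    tsensor: ThermoSensorParams
    vsensor: VoltageSensorParams
    coupling: CouplingParams
    label: str = ""
    #: True if the serialized source used the opposite z-sign convention.
    z_sign_normalized: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.L <= 0:
            raise ParameterError(f"L must be > 0, got {self.L}")

    # -- flat serialization ------------------------------------------------
    _FLAT_KEYS = ("L", "K0", "z", "dH", "dS", "dHc", "dSc", "D", "E")

    def to_dict(self) -> dict:
        """Flat key/value form (keys L, K0, z, dH, dS, dHc, dSc, D, E, label)."""
        return {
            "L": self.L,
            "K0": self.vsensor.K0,
            "z": self.vsensor.z,
            "dH": self.tsensor.dH,
            "dS": self.tsensor.dS,
            "dHc": self.coupling.dHc,
            "dSc": self.coupling.dSc,
            "D": self.coupling.D,
            "E": self.coupling.E,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict, normalize_z: bool = True) -> "GatingParameters":
        """Build from a flat mapping.

        A negative ``z`` is interpreted as the opposite exponent-sign
        convention for a depolarization-activated sensor and flipped when
        ``normalize_z`` is true; the flip is recorded in
        ``z_sign_normalized`` rather than applied silently.
        """
        missing = [k for k in cls._FLAT_KEYS if k not in d]
        if missing:
            raise ParameterError(f"missing parameter keys: {missing}")
        z = float(d["z"])
        flipped = False
        if z < 0 and normalize_z:
            z, flipped = -z, True
        return cls(
            L=float(d["L"]),
            tsensor=ThermoSensorParams(dH=float(d["dH"]), dS=float(d["dS"])),
            vsensor=VoltageSensorParams(K0=float(d["K0"]), z=z),
            coupling=CouplingParams(
                D=float(d["D"]),
                E=float(d["E"]),
                dHc=float(d["dHc"]),
                dSc=float(d["dSc"]),
            ),
            label=str(d.get("label", "")),
            z_sign_normalized=flipped,
        )

    def replace(self, **flat_updates) -> "GatingParameters":
        """Return a copy with flat keys (L, K0, z, ... , label) updated."""
        d = self.to_dict()
        unknown = set(flat_updates) - set(d)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        d.update(flat_updates)
        out = GatingParameters.from_dict(d, normalize_z=False)
        return out
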