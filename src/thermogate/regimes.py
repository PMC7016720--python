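"""The blue/green/red gating regimes and their constrained sequential refits.

The hTRPA1 activation profile is modeled as three parameter sets sharing
one eight-state topology:

* **blue** — the naive channel. K(0) = 0.003, |z| = 0.74, ΔH° = 91
  kcal·mol⁻¹, ΔS° = 0.317 kcal·mol⁻¹·K⁻¹ and ΔH°c = 6.1 kcal·mol⁻¹ are the
  published fit values; the remaining constants (L, D, E, ΔS°c) are not
  published and are calibrated here against the published 25 °C Boltzmann
  parameters (V50 = 66.5 mV, z = 0.76, Gmin/Gmax = 0.8/23.5 nS), the
  2.3%-of-Gmax basal conductance at (−150 mV, 25 °C), and the requirement
  of a mild U-shaped P_o–temperature relation at +80 mV.
* **green** — after exposure to heat > 60 °C (irreversible switch that
  blunts subsequent depolarization responses). Refit of {L, E, D, ΔH°c,
  ΔS°c} with everything else frozen at blue, against four P_o pins.
* **red** — after concurrent depolarization + noxious heat (cold-sensitized,
  inwardly rectifying). Joint refit of {L, E, D, ΔS°, ΔH°c, ΔS°c} with
  K(0), z, ΔH° frozen, against four P_o pins, initialized from green.

The pin targets are the published normalized-activation values. Note that
the red 5 °C pins (0.998 at −70 mV vs 0.23 at +80 mV) demand a larger
open-probability odds ratio across 150 mV than a |z| = 0.74 voltage sensor
can produce, so the red optimum carries a few-percent residual on those
two pins by construction; see docs/methods.md.
"""

from __future__ import annotations

from .estimation import AllostericGlobalFit, GlobalFitResult
from .parameters import GatingParameters

#: P_o pin targets, (V mV, T °C) -> P_o, for the green and red refits.
GREEN_PINS = (
    (-70.0, 60.0, 0.15),
    (-70.0, 5.0, 0.005),
    (80.0, 5.0, 0.21),
    (80.0, 60.0, 0.71),
)

RED_PINS = (
    (-70.0, 60.0, 0.91),
    (-70.0, 5.0, 0.998),
    (80.0, 5.0, 0.23),
    (80.0, 60.0, 0.74),
)

#: Parameters frozen during the green-stage refit (blue values kept).
GREEN_FROZEN = ("K0", "z", "dH", "dS")

#: Red stage, step 1: only {D, L, ΔH°c, ΔS°c} free.
RED_STEP1_FROZEN = ("K0", "z", "dH", "dS", "E")

#: Red stage, step 2: {E, ΔS°, ΔH°c, ΔS°c} free, D and L held at step-1 values.
RED_STEP2_FROZEN = ("K0", "z", "dH", "L", "D")

# Calibrated blue parameter set (see module docstring; L, D, E, dSc are
# package-chosen, the rest are published values). With these values the
# 25 °C normalized G–V has V50 ≈ 72 mV shifting down on warming, the basal
# open fraction at (−150 mV, 25 °C) is 2.3% of maximum, the cold basal at
# −70 mV stays at P_o ≈ 0.08, and P_o(+80 mV, T) has its interior minimum
# near 22 °C (mild U-shape).
_BLUE_DICT = {
    "L": 0.00398107,
    "K0": 0.003,
    "z": 0.74,
    "dH": 91.0,
    "dS": 0.317,
    "dHc": 6.1,
    "dSc": 0.0238592,
    "D": 61059.1,
    "E": 0.0310523,
    "label": "blue",
}


def blue_parameters() -> GatingParameters:
    """The calibrated naive-channel ("blue") parameter set."""
    return GatingParameters.from_dict(_BLUE_DICT)


#: Refit solver defaults: near-minimax pin penalty (power 4), a weak
#: proximity pull toward the preceding stage (selects the
#: minimal-perturbation solution on the under-determined pin manifold so
#: repeated seeded fits converge to the same landscape), and best-of-three
#: optimizer restarts.
_REFIT_DEFAULTS = dict(pin_power=4, reg_weight=1e-7, n_restarts=3)


def refit_green(
    blue: GatingParameters | None = None, seed: int = 0, **fit_kw
) -> GlobalFitResult:
    """Green-stage constrained refit: free {L, E, D, ΔH°c, ΔS°c} against
    the four green pins, everything else frozen at the blue values."""
    base = (blue or blue_parameters()).replace(label="green")
    kw = {**_REFIT_DEFAULTS, **fit_kw}
    est = AllostericGlobalFit(base_params=base, frozen=GREEN_FROZEN, seed=seed, **kw)
    est.fit(pins=GREEN_PINS)
    return est.result_


def refit_red(
    green: GatingParameters, seed: int = 0, **fit_kw
) -> GlobalFitResult:
    """Red-stage refit against the four red pins, in the two sequential
    steps of the constraint scheme: first {D, L, ΔH°c, ΔS°c} are freed with
    E and ΔS° held at their green values, then {E, ΔS°, ΔH°c, ΔS°c} are
    freed with D and L held at the step-1 solution.

    Note: the two 5 °C pins (0.998 at −70 mV vs 0.23 at +80 mV) demand a
    larger open-probability odds ratio across 150 mV than a |z| = 0.74
    voltage sensor can express, so a few-percent residual on the worst pin
    is intrinsic to the pin set, not an optimizer failure.
    """
    kw = {**_REFIT_DEFAULTS, **fit_kw}
    step1 = AllostericGlobalFit(
        base_params=green.replace(label="red"),
        frozen=RED_STEP1_FROZEN, seed=seed, **kw,
    )
    step1.fit(pins=RED_PINS)
    step2 = AllostericGlobalFit(
        base_params=step1.params_, frozen=RED_STEP2_FROZEN, seed=seed + 1, **kw,
    )
    step2.fit(pins=RED_PINS)
    return step2.result_
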