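"""Radioactive decay of the phantom's two tracers.

The dual-isotope design drives the contrast sweep: hot spheres (and the
reference source) carry a long-lived tracer while the background carries a
short-lived one, so the true sphere-to-background ratio grows with time from
its initial value purely by differential decay — no refilling or scanning
tricks required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Isotope",
    "F18",
    "C11",
    "decayed_concentration",
    "frame_mean_concentration",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Isotope:
    """A radionuclide characterized by its half-life.

    Parameters
    ----------
    name : str
        Display label, e.g. ``"F-18"``.
    half_life : float
        Physical half-life in minutes; must be positive.
    """

    name: str
    half_life: float

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValueError(f"half_life must be > 0, got {self.half_life}")

    @property
    def decay_constant(self) -> float:
        """Decay constant λ = ln2 / T½ in 1/minutes."""
        return LN2 / self.half_life


#: Fluorine-18 (spheres and reference source).
F18 = Isotope("F-18", 109.77)
#: Carbon-11 (background medium).
C11 = Isotope("C-11", 20.36)


def decayed_concentration(c0: float, isotope: Isotope, t: float) -> float:
    """Activity concentration at time ``t`` from ``c0`` at t=0.

    Implements the decay law ``c(t) = c0 · 2^(−t/T½)``.

    Parameters
    ----------
    c0 : float
        Concentration at t=0 (Bq/mL), ≥ 0.
    isotope : Isotope
        Decaying nuclide.
    t : float
        Elapsed time in minutes, ≥ 0.
    """
    if c0 < 0:
        raise ValueError(f"c0 must be >= 0, got {c0}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return c0 * 2.0 ** (-t / isotope.half_life)


def frame_mean_concentration(
    c0: float, isotope: Isotope, t0: float, dt: float
) -> float:
    """Time-averaged concentration over the frame ``[t0, t0 + dt]``.

    This is what an ideal scanner frame measures: the mean of the decay curve
    over the frame, in closed form

    ``c̄ = c0 · 2^(−t0/T½) · (1 − 2^(−dt/T½)) · T½ / (dt · ln 2)``.

    Parameters
    ----------
    c0 : float
        Concentration at t=0 (Bq/mL), ≥ 0.
    isotope : Isotope
        Decaying nuclide.
    t0 : float
        Frame start time in minutes, ≥ 0.
    dt : float
        Frame duration in minutes, > 0.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if c0 < 0:
        raise ValueError(f"c0 must be >= 0, got {c0}")
    if t0 < 0:
        raise ValueError(f"t0 must be >= 0, got {t0}")
    th = isotope.half_life
    start = c0 * 2.0 ** (-t0 / th)
    return start * (1.0 - 2.0 ** (-dt / th)) * th / (dt * LN2)
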