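"""Passive sampler sub-models: PUF (air) and SPME (water).

A polyurethane foam (PUF) cylinder in the flask headspace accumulates
gas-phase PCBs; a polydimethylsiloxane-coated SPME fiber immersed in the
liquid accumulates freely dissolved PCBs. Both are modelled as
first-order relaxations toward a partition-defined equilibrium and both
REMOVE mass from their source compartments, so they participate in the
whole-system mass balance rather than acting as massless probes.

The SPME observation model additionally supports biofouling: when
degrader cells sorb PCBs in the water column, a fraction of that
cell-bound pool can ride along on a fouled fiber and be extracted with
it. This enters the OBSERVATION only (:func:`apparent_spme_mass`), never
the dynamics — it is a measurement artefact, not a transport process —
and it can make apparent aqueous PCBs in bioaugmented treatments exceed
controls even while airborne PCBs drop.

Units: concentrations ng/L, masses ng (PUF) and ng/cm (SPME), time d,
velocities cm/d; 1 L = 1000 cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PufSpec",
    "SpmeSpec",
    "apparent_spme_mass",
    "puf_uptake_rate",
    "spme_uptake_rate",
]

CM3_PER_L = 1000.0


@dataclass(frozen=True)
class PufSpec:
    """PUF cylinder geometry and uptake parameters.

    height, radius  cylinder dimensions, cm (2.5 × 1.9 cm sampler)
    k_puf           air-side uptake velocity, cm/d
    k_puf_a         PUF–air partition coefficient, dimensionless
                    (ng/L foam per ng/L air at equilibrium)
    """

    height: float = 2.5
    radius: float = 1.9
    k_puf: float = 50.0
    k_puf_a: float = 1e5

    def __post_init__(self) -> None:
        for name in ("height", "radius", "k_puf", "k_puf_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def face_area_cm2(self) -> float:
        """Exposed circular face area, cm^2."""
        return math.pi * self.radius**2

    @property
    def volume_l(self) -> float:
        """Foam volume, L (from cylinder geometry)."""
        return math.pi * self.radius**2 * self.height / CM3_PER_L


@dataclass(frozen=True)
class SpmeSpec:
    """SPME fiber coating and uptake parameters.

    coating_thickness_um  PDMS layer thickness, μm (10 μm fiber)
    fiber_length_total    deployed fiber length, cm (~30 cm per flask)
    k_fw                  fiber(PDMS)–water partition coefficient,
                          dimensionless
    k_sp                  water-side first-order uptake rate, 1/d
    v_coat_per_cm         coating volume per cm of fiber, L/cm
    """

    coating_thickness_um: float = 10.0
    fiber_length_total: float = 30.0
    k_fw: float = 1e4
    k_sp: float = 2.0
    v_coat_per_cm: float = 3.8e-8

    def __post_init__(self) -> None:
        for name in (
            "coating_thickness_um",
            "fiber_length_total",
            "k_fw",
            "k_sp",
            "v_coat_per_cm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def equilibrium_mass_per_cm(self, c_free: float) -> float:
        """Equilibrium fiber load (ng/cm) at free concentration ng/L."""
        return self.k_fw * self.v_coat_per_cm * c_free


def puf_uptake_rate(spec: PufSpec, c_a: float, m_puf: float) -> float:
    """Net PUF uptake, ng/d.

    Air-side-limited flux toward the PUF–air equilibrium::

        k_puf * A_face * (c_a - m_puf / (V_puf * k_puf_a)) / 1000

    Zero exactly at equilibrium; negative when the foam outgasses.
    """
    if c_a < 0 or m_puf < 0:
        raise ValueError("c_a and m_puf must be >= 0")
    c_eq_air = m_puf / (spec.volume_l * spec.k_puf_a)
    return spec.k_puf * spec.face_area_cm2 * (c_a - c_eq_air) / CM3_PER_L


def spme_uptake_rate(spec: SpmeSpec, c_free: float, m_spme: float) -> float:
    """Net SPME coating uptake, (ng/cm)/d.

    First-order relaxation toward ``k_fw * v_coat_per_cm * c_free``.
    """
    if c_free < 0 or m_spme < 0:
        raise ValueError("c_free and m_spme must be >= 0")
    return spec.k_sp * (spec.equilibrium_mass_per_cm(c_free) - m_spme)


def apparent_spme_mass(
    m_spme: float,
    c_w: float,
    b: float,
    alpha_fiber: float,
    v_w: float,
    spec: SpmeSpec,
) -> float:
    """Reported fiber load including the cell-fouling contribution, ng/cm.

    ``m_spme`` is the true coating load; ``c_w`` the TOTAL aqueous
    concentration (ng/L) of which ``(1 - b)`` is cell-sorbed (``b`` the
    bioavailability factor); ``alpha_fiber`` the fraction of that
    cell-sorbed pool attributed to fouled fiber, spread over the deployed
    length::

        m_spme + alpha_fiber * (1 - b) * c_w * v_w / fiber_length_total

    With ``alpha_fiber = 0`` or ``b = 1`` the true load is returned
    unchanged.
    """
    if min(m_spme, c_w, v_w) < 0:
        raise ValueError("m_spme, c_w, v_w must be >= 0")
    if not 0 <= b <= 1 or not 0 <= alpha_fiber <= 1:
        raise ValueError("b and alpha_fiber must be in [0, 1]")
    fouling = alpha_fiber * (1.0 - b) * c_w * v_w / spec.fiber_length_total
    return m_spme + fouling
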