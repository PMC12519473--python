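"""Per-congener compartmental reactive transport model (RTM) for sealed
sediment microcosms.

Each 250-mL flask holds a sediment bed, ~100 mL of liquid, headspace and
two passive samplers. Every compartment is one ODE in mass-consistent
units; a flask is integrated one congener at a time (no congener–congener
interaction).

Shaken regime — sediment is a well-mixed two-site sorbent: fast and slow
sorbed pools exchange with the freely dissolved phase by a linear driving
force toward ``f_site * f_avail * K_d * B * c_w``. Nonshaken regime —
sediment is a bed of spherical particles releasing PCB by retarded radial
pore diffusion into porewater, which exchanges with the overlying water
across a liquid boundary layer film.

Bioaugmented cells sorb PCBs; the bioavailability factor
``B = 1 / (1 + k_cell * x_cells)`` is the freely dissolved fraction of
the total aqueous concentration ``c_w``. Air–water exchange, SPME uptake,
sediment exchange and biodegradation all see ``B * c_w``; cells are
present only in the overlying water (porewater has B = 1), and
biodegradation (first order, rate ``k_bio``) acts only on the freely
dissolved pool of the aerobic overlying water. The degraded mass is
accumulated in ``m_degraded`` so that total mass is conserved exactly
even with active degradation.

Unit convention throughout: water/air concentrations ng/L, sediment
ng/g, sampler loads ng (PUF) and ng/cm (SPME), masses ng, time d,
velocities cm/d with areas cm² (1 L = 1000 cm³).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .congener_registry import Congener
from .particle_diffusion import (
    ParticleGrid,
    make_diffusion_operator,
    particle_capacity_l,
)
from .samplers import (
    PufSpec,
    SpmeSpec,
    apparent_spme_mass,
    puf_uptake_rate,
    spme_uptake_rate,
)

__all__ = [
    "MicrocosmConfig",
    "RTMParams",
    "RTMState",
    "RTMSystem",
    "Trajectory",
    "assemble_nonshaken_system",
    "assemble_shaken_system",
    "bioavailability_factor",
    "equilibrium_state",
    "initial_state_from_sediment",
    "n_particles_for_sediment_mass",
    "simulate",
    "total_mass",
]

CM3_PER_L = 1000.0
G_PER_KG = 1000.0

SHAKEN = "shaken"
NONSHAKEN = "nonshaken"


@dataclass(frozen=True)
class MicrocosmConfig:
    """Geometry and phase inventories of one microcosm flask.

    Defaults mirror the experimental design: 10 g dry sediment and 100 mL
    of K1 medium (1:10 sediment:liquid) in a 250-mL Erlenmeyer flask,
    leaving ~150 mL headspace. ``v_pw`` is the sediment porewater volume
    (pore space of the settled bed, nonshaken regime only). ``x_cells``
    is the added degrader biomass in the liquid, g dry cells / L (0 for
    controls).
    """

    m_sed: float = 10.0
    v_w: float = 0.1
    v_a: float = 0.15
    v_pw: float = 0.004
    regime: str = SHAKEN
    x_cells: float = 0.0
    temp_note: str = "room temperature, ~21 C"

    def __post_init__(self) -> None:
        for name in ("m_sed", "v_w", "v_a", "v_pw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.x_cells < 0:
            raise ValueError("x_cells must be >= 0")
        if self.regime not in (SHAKEN, NONSHAKEN):
            raise ValueError(f"regime must be {SHAKEN!r} or {NONSHAKEN!r}")


@dataclass(frozen=True)
class RTMParams:
    """Rate and partition parameters of the RTM.

    k_bio        first-order biodegradation rate of the freely dissolved
                 pool, 1/d (17 for shaken LB400 treatments, 0.4–0.6
                 nonshaken; 0–1 covers native activity in controls)
    k_cell       cell–water partition coefficient, L/g; defines B
    f_avail      fraction of the sediment inventory available for
                 sorption/desorption exchange, [0, 1]
    f_fast       fraction of the available pool in the fast site, [0, 1]
    k_fast, k_slow  site desorption rate constants, 1/d (shaken)
    v_aw         air–water mass-transfer velocity, cm/d
    a_aw         air–water interfacial area, cm²
    k_bl         liquid boundary-layer mass-transfer velocity across the
                 sediment–water interface, cm/d (nonshaken)
    a_int        sediment–water interfacial area, cm² (nonshaken)
    alpha_fiber  fraction of the cell-sorbed aqueous pool counted by the
                 SPME observation model (fiber fouling), [0, 1]
    particle     intraparticle diffusion parameters (nonshaken)
    puf, spme    passive sampler sub-model parameters
    """

    k_bio: float = 0.0
    k_cell: float = 0.0
    f_avail: float = 0.5
    f_fast: float = 0.6
    k_fast: float = 0.5
    k_slow: float = 0.02
    v_aw: float = 100.0
    a_aw: float = 40.0
    k_bl: float = 0.5
    a_int: float = 40.0
    alpha_fiber: float = 0.0
    particle: ParticleGrid = field(default_factory=ParticleGrid)
    puf: PufSpec = field(default_factory=PufSpec)
    spme: SpmeSpec = field(default_factory=SpmeSpec)

    def __post_init__(self) -> None:
        for name in ("k_bio", "k_cell", "k_fast", "k_slow", "v_aw", "a_aw",
                     "k_bl", "a_int"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("f_avail", "f_fast", "alpha_fiber"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def bioavailability_factor(k_cell: float, x_cells: float) -> float:
    """Freely dissolved fraction B = 1 / (1 + k_cell * x_cells).

    Linear sorption isotherm on suspended cells: ``k_cell`` in L/g,
    ``x_cells`` in g/L. B = 1 without cells; B in (0, 1] always.
    """
    if k_cell < 0 or x_cells < 0:
        raise ValueError("k_cell and x_cells must be >= 0")
    return 1.0 / (1.0 + k_cell * x_cells)


@dataclass
class RTMState:
    """State of every compartment for one congener.

    Sediment pools ``s_fast``/``s_slow`` (ng/g) are used in the shaken
    regime; ``c_pw`` and ``c_shell`` (porewater and intraparticle pore
    concentrations, ng/L) in the nonshaken regime. ``c_w`` is the TOTAL
    aqueous concentration (dissolved + cell-sorbed), ng/L; ``c_a`` the
    headspace concentration, ng/L; ``m_puf`` ng per PUF; ``m_spme`` ng
    per cm of fiber; ``m_degraded`` the cumulative degraded mass, ng.
    """

    s_fast: float = 0.0
    s_slow: float = 0.0
    c_w: float = 0.0
    c_pw: float = 0.0
    c_shell: np.ndarray | None = None
    c_a: float = 0.0
    m_puf: float = 0.0
    m_spme: float = 0.0
    m_degraded: float = 0.0


# fixed tail layout shared by both regimes
_TAIL = ("c_w", "c_a", "m_puf", "m_spme", "m_degraded")


def _state_to_vector(state: RTMState, regime: str, n_shells: int) -> np.ndarray:
    tail = [getattr(state, name) for name in _TAIL]
    if regime == SHAKEN:
        return np.array([state.s_fast, state.s_slow, *tail], dtype=float)
    shells = state.c_shell
    if shells is None:
        shells = np.zeros(n_shells)
    shells = np.asarray(shells, dtype=float)
    if shells.shape != (n_shells,):
        raise ValueError(f"c_shell must have shape ({n_shells},)")
    return np.concatenate([shells, [state.c_pw], tail])


def _vector_to_state(y: np.ndarray, regime: str, n_shells: int) -> RTMState:
    if regime == SHAKEN:
        s_fast, s_slow, c_w, c_a, m_puf, m_spme, m_deg = y
        return RTMState(s_fast=float(s_fast), s_slow=float(s_slow),
                        c_w=float(c_w), c_a=float(c_a), m_puf=float(m_puf),
                        m_spme=float(m_spme), m_degraded=float(m_deg))
    shells = np.array(y[:n_shells], dtype=float)
    c_pw, c_w, c_a, m_puf, m_spme, m_deg = y[n_shells:]
    return RTMState(c_shell=shells, c_pw=float(c_pw), c_w=float(c_w),
                    c_a=float(c_a), m_puf=float(m_puf), m_spme=float(m_spme),
                    m_degraded=float(m_deg))


@dataclass(frozen=True)
class RTMSystem:
    """Assembled right-hand side plus the metadata needed to interpret the
    state vector. Callable as ``system(t, y) -> dy/dt`` (scipy order)."""

    cfg: MicrocosmConfig
    params: RTMParams
    congener: Congener
    rhs: Callable[[float, np.ndarray], np.ndarray]

    @property
    def regime(self) -> str:
        return self.cfg.regime

    @property
    def n_shells(self) -> int:
        return self.params.particle.n_shells if self.regime == NONSHAKEN else 0

    @property
    def n_state(self) -> int:
        return (2 if self.regime == SHAKEN else self.n_shells + 1) + len(_TAIL)

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.rhs(t, y)

    def pack(self, state: RTMState) -> np.ndarray:
        return _state_to_vector(state, self.regime, self.n_shells)

    def unpack(self, y: np.ndarray) -> RTMState:
        return _vector_to_state(y, self.regime, self.n_shells)


def _common_fluxes(
    cfg: MicrocosmConfig,
    p: RTMParams,
    c: Congener,
    b: float,
    c_w: float,
    c_a: float,
    m_puf: float,
    m_spme: float,
) -> tuple[float, float, float, float, float]:
    """Air exchange, degradation and sampler fluxes shared by both
    regimes. Returns (F_aw, F_deg, F_puf, dm_spme, F_spme), ng/d except
    dm_spme in (ng/cm)/d."""
    free = b * c_w
    f_aw = p.v_aw * p.a_aw * (free - c_a / c.k_h) / CM3_PER_L
    f_deg = p.k_bio * free * cfg.v_w
    f_puf = puf_uptake_rate(p.puf, max(c_a, 0.0), max(m_puf, 0.0))
    dm_spme = spme_uptake_rate(p.spme, max(free, 0.0), max(m_spme, 0.0))
    f_spme = dm_spme * p.spme.fiber_length_total
    return f_aw, f_deg, f_puf, dm_spme, f_spme


def assemble_shaken_system(
    cfg: MicrocosmConfig, p: RTMParams, c: Congener
) -> RTMSystem:
    """ODE system for a shaken (well-mixed slurry) microcosm.

    State: [s_fast, s_slow, c_w, c_a, m_puf, m_spme, m_degraded]. Sorbed
    pools relax by a linear driving force toward their equilibrium with
    the freely dissolved phase; the aqueous balance couples sediment
    exchange, two-film air–water exchange, SPME uptake and first-order
    degradation of the freely dissolved pool; headspace feeds the PUF.
    """
    if cfg.regime != SHAKEN:
        raise ValueError(
            "config regime is nonshaken; use assemble_nonshaken_system"
        )
    b = bioavailability_factor(p.k_cell, cfg.x_cells)
    kd_g = c.k_d / G_PER_KG  # L/g: s (ng/g) = kd_g * c (ng/L)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        s_fast, s_slow, c_w, c_a, m_puf, m_spme, _ = y
        free = b * c_w
        ds_fast = -p.k_fast * (s_fast - p.f_fast * p.f_avail * kd_g * free)
        ds_slow = -p.k_slow * (
            s_slow - (1.0 - p.f_fast) * p.f_avail * kd_g * free
        )
        f_sed = -(ds_fast + ds_slow) * cfg.m_sed  # ng/d into water
        f_aw, f_deg, f_puf, dm_spme, f_spme = _common_fluxes(
            cfg, p, c, b, c_w, c_a, m_puf, m_spme
        )
        return np.array(
            [
                ds_fast,
                ds_slow,
                (f_sed - f_aw - f_deg - f_spme) / cfg.v_w,
                (f_aw - f_puf) / cfg.v_a,
                f_puf,
                dm_spme,
                f_deg,
            ]
        )

    return RTMSystem(cfg=cfg, params=p, congener=c, rhs=rhs)


def assemble_nonshaken_system(
    cfg: MicrocosmConfig, p: RTMParams, c: Congener
) -> RTMSystem:
    """ODE system for a nonshaken (settled bed) microcosm.

    State: [c_shell[0..n-1], c_pw, c_w, c_a, m_puf, m_spme, m_degraded].
    Particles release PCB by retarded radial pore diffusion with the
    porewater concentration as surface boundary; porewater exchanges with
    the overlying water across a boundary-layer film
    ``k_bl * a_int * (c_pw - B * c_w)`` (cells, hence B, only in the
    overlying water); air exchange, samplers and degradation as in the
    shaken system, degradation in the overlying water only.
    """
    if cfg.regime != NONSHAKEN:
        raise ValueError("config regime is shaken; use assemble_shaken_system")
    grid = p.particle
    if grid.n_shells < 3:
        raise ValueError("particle grid needs at least 3 shells")
    op = make_diffusion_operator(grid)
    b = bioavailability_factor(p.k_cell, cfg.x_cells)
    n = grid.n_shells

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        shells = y[:n]
        c_pw, c_w, c_a, m_puf, m_spme, _ = y[n:]
        dshells, flux_particle = op(shells, c_pw)
        f_bed = flux_particle * grid.n_particles_equiv  # ng/d into porewater
        f_bl = p.k_bl * p.a_int * (c_pw - b * c_w) / CM3_PER_L
        f_aw, f_deg, f_puf, dm_spme, f_spme = _common_fluxes(
            cfg, p, c, b, c_w, c_a, m_puf, m_spme
        )
        return np.concatenate(
            [
                dshells,
                [
                    (f_bed - f_bl) / cfg.v_pw,
                    (f_bl - f_aw - f_deg - f_spme) / cfg.v_w,
                    (f_aw - f_puf) / cfg.v_a,
                    f_puf,
                    dm_spme,
                    f_deg,
                ],
            ]
        )

    return RTMSystem(cfg=cfg, params=p, congener=c, rhs=rhs)


def assemble_system(cfg: MicrocosmConfig, p: RTMParams, c: Congener) -> RTMSystem:
    """Dispatch on ``cfg.regime``."""
    if cfg.regime == SHAKEN:
        return assemble_shaken_system(cfg, p, c)
    return assemble_nonshaken_system(cfg, p, c)


@dataclass(frozen=True)
class Trajectory:
    """Time-resolved solution for one congener in one flask."""

    times: np.ndarray
    states: tuple[RTMState, ...]
    system: RTMSystem

    def series(self, name: str) -> np.ndarray:
        """Extract one scalar compartment over time (e.g. ``"m_puf"``)."""
        return np.array([getattr(s, name) for s in self.states], dtype=float)

    def apparent_spme(self) -> np.ndarray:
        """Observed fiber load incl. cell-fouling, ng/cm, over time."""
        p, cfg = self.system.params, self.system.cfg
        b = bioavailability_factor(p.k_cell, cfg.x_cells)
        return np.array(
            [
                apparent_spme_mass(
                    s.m_spme, s.c_w, b, p.alpha_fiber, cfg.v_w, p.spme
                )
                for s in self.states
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: time_d, compartment, value, units."""
        units = {
            "s_fast": "ng/g", "s_slow": "ng/g", "c_w": "ng/L",
            "c_pw": "ng/L", "c_a": "ng/L", "m_puf": "ng",
            "m_spme": "ng/cm", "m_degraded": "ng",
        }
        names = (
            ("s_fast", "s_slow") if self.system.regime == SHAKEN
            else ("c_pw",)
        ) + _TAIL
        rows = []
        for t, s in zip(self.times, self.states):
            for name in dict.fromkeys(names):
                rows.append((t, name, getattr(s, name), units[name]))
            if self.system.regime == NONSHAKEN and s.c_shell is not None:
                for i, v in enumerate(s.c_shell):
                    rows.append((t, f"c_shell_{i}", v, "ng/L"))
        return pd.DataFrame(
            rows, columns=["time_d", "compartment", "value", "units"]
        )


class IntegrationError(RuntimeError):
    """Integrator failed or produced inadmissibly negative states."""

    def __init__(self, message: str, last_good_time: float | None = None):
        super().__init__(message)
        self.last_good_time = last_good_time


def simulate(
    system: RTMSystem,
    y0: RTMState,
    times: Sequence[float],
    tol: float = 1e-8,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the flask ODEs and sample at ``times`` (days).

    Stiff-capable (LSODA default; shaken treatments mix k_bio = 17/d with
    slow-site desorption at 0.02/d). Small negative excursions — those
    within ``10 * tol * max|y|`` of zero — are clipped to 0; larger ones
    raise :class:`IntegrationError`, as does integrator failure (carrying
    the last successfully reached time).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be non-empty and strictly increasing")
    y0v = system.pack(y0)
    if np.any(y0v < 0):
        raise ValueError("initial state must be non-negative")
    t0 = min(0.0, t[0])
    scale = max(1.0, float(np.max(np.abs(y0v))))
    sol = solve_ivp(
        system,
        (t0, t[-1]),
        y0v,
        method=method,
        t_eval=t,
        rtol=tol,
        atol=tol * scale * 1e-3,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else t0
        raise IntegrationError(
            f"integration failed at t={last:g} d: {sol.message}",
            last_good_time=last,
        )
    y = sol.y.T.copy()
    threshold = 10.0 * tol * max(scale, float(np.max(np.abs(y))))
    worst = float(y.min(initial=0.0))
    if worst < -threshold:
        raise IntegrationError(
            f"state went negative beyond tolerance (min {worst:.3e}, "
            f"threshold {threshold:.3e})"
        )
    np.clip(y, 0.0, None, out=y)
    states = tuple(system.unpack(row) for row in y)
    return Trajectory(times=t, states=states, system=system)


def total_mass(state: RTMState, cfg: MicrocosmConfig, p: RTMParams) -> float:
    """Whole-flask inventory in ng, including samplers and m_degraded."""
    spme_mass = state.m_spme * p.spme.fiber_length_total
    mass = (
        state.c_w * cfg.v_w
        + state.c_a * cfg.v_a
        + state.m_puf
        + spme_mass
        + state.m_degraded
    )
    if cfg.regime == SHAKEN:
        mass += (state.s_fast + state.s_slow) * cfg.m_sed
    else:
        grid = p.particle
        mass += state.c_pw * cfg.v_pw
        if state.c_shell is not None:
            from .particle_diffusion import build_grid

            geo = build_grid(grid)
            cap = grid.porosity * grid.retardation * geo.volumes / CM3_PER_L
            mass += float(np.dot(cap, state.c_shell)) * grid.n_particles_equiv
    return float(mass)


def _capacity_per_free(
    cfg: MicrocosmConfig, p: RTMParams, c: Congener, b: float
) -> float:
    """Litre-equivalents of capacity per unit freely dissolved
    concentration, all phases."""
    cap = (
        cfg.v_w / b
        + cfg.v_a * c.k_h
        + p.puf.volume_l * p.puf.k_puf_a * c.k_h
        + p.spme.fiber_length_total * p.spme.k_fw * p.spme.v_coat_per_cm
    )
    if cfg.regime == SHAKEN:
        cap += cfg.m_sed * p.f_avail * c.k_d / G_PER_KG
    else:
        cap += cfg.v_pw
        cap += particle_capacity_l(p.particle) * p.particle.n_particles_equiv
    return cap


def equilibrium_state(
    cfg: MicrocosmConfig, p: RTMParams, c: Congener, total: float
) -> RTMState:
    """Closed-form no-degradation equilibrium partitioning of ``total`` ng.

    All phases share one freely dissolved concentration ``x``: sorbed
    sediment pools at ``f_site * f_avail * K_d * x``, total aqueous
    ``x / B``, air ``k_h * x``, samplers at their partition equilibria;
    phase masses sum to ``total`` exactly. Requires ``k_bio = 0``.
    """
    if p.k_bio != 0:
        raise ValueError("equilibrium_state requires k_bio = 0")
    if total < 0:
        raise ValueError("total mass must be >= 0")
    b = bioavailability_factor(p.k_cell, cfg.x_cells)
    cap = _capacity_per_free(cfg, p, c, b)
    if cap <= 0:
        raise ValueError("all phase capacities are zero")
    x = total / cap  # freely dissolved, ng/L
    kd_g = c.k_d / G_PER_KG
    state = RTMState(
        c_w=x / b,
        c_a=c.k_h * x,
        m_puf=p.puf.volume_l * p.puf.k_puf_a * c.k_h * x,
        m_spme=p.spme.k_fw * p.spme.v_coat_per_cm * x,
    )
    if cfg.regime == SHAKEN:
        state.s_fast = p.f_fast * p.f_avail * kd_g * x
        state.s_slow = (1.0 - p.f_fast) * p.f_avail * kd_g * x
    else:
        state.c_pw = x
        state.c_shell = np.full(p.particle.n_shells, x)
    return state


def n_particles_for_sediment_mass(
    grid: ParticleGrid, m_sed: float, particle_density: float = 2.5
) -> float:
    """Number of representative particles whose solid mass equals the dry
    sediment mass (``particle_density`` g/cm³ of solids)."""
    v_solid = (1.0 - grid.porosity) * 4.0 / 3.0 * math.pi * grid.radius**3
    return m_sed / (particle_density * v_solid)


def initial_state_from_sediment(
    cfg: MicrocosmConfig, p: RTMParams, s0: float
) -> RTMState:
    """Initial condition with the whole inventory ``s0`` (ng/g dry
    sediment) in the sediment, as in a freshly assembled microcosm.

    Shaken: the available-pool split puts ``f_fast`` of the inventory in
    the fast site. Nonshaken: uniform intraparticle pore concentration
    reproducing the same total bed inventory.
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    if cfg.regime == SHAKEN:
        return RTMState(s_fast=p.f_fast * s0, s_slow=(1.0 - p.f_fast) * s0)
    grid = p.particle
    bed_capacity = particle_capacity_l(grid) * grid.n_particles_equiv
    if bed_capacity <= 0:
        raise ValueError("nonshaken initial state needs a particle inventory")
    c0 = s0 * cfg.m_sed / bed_capacity
    return RTMState(c_shell=np.full(grid.n_shells, c0))


def params_with(p: RTMParams, **updates: float) -> RTMParams:
    """Return a copy of ``p`` with scalar fields replaced (calibration
    hook)."""
    return replace(p, **updates)


def load_microcosm_config(path) -> MicrocosmConfig:
    """Read a MicrocosmConfig from a flat YAML mapping whose keys mirror
    the field names (units as documented on the class)."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in fields(MicrocosmConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    return MicrocosmConfig(**raw)


def load_rtm_params(path) -> RTMParams:
    """Read RTMParams from YAML; ``particle``, ``puf`` and ``spme`` are
    nested mappings with their sub-model field names."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "particle" in raw:
        raw["particle"] = ParticleGrid(**raw["particle"])
    if "puf" in raw:
        raw["puf"] = PufSpec(**raw["puf"])
    if "spme" in raw:
        raw["spme"] = SpmeSpec(**raw["spme"])
    valid = {f.name for f in fields(RTMParams)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown parameter keys {sorted(unknown)}")
    return RTMParams(**raw)
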