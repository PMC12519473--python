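"""Synthetic microcosm experiments with the statistical structure the
analysis pipeline assumes.

A :class:`SynthDesign` describes one study arm — sediment inventory,
flask configuration and true rate parameters per group, sacrificial
sampling days, triplicate replication, and multiplicative lognormal
measurement noise — and :func:`generate_experiment` turns it into the
congener table a lab would produce, together with a noise-free truth
record for parameter-recovery tests. Blank sets (for LOQ computation)
and surrogate recoveries are generated alongside, so the full
simulate → reduce → compare → calibrate chain runs with no external
data.

Scenario factories mirror the three study arms: shaken Altavista Lake
sediment (``AVL_S``, sampled days 3/11/16/35, bioaugmented PCB 4
degradation at 17 1/d), nonshaken Altavista (``AVL_NS``, days 16/35/75,
0.6 1/d) and nonshaken New Bedford Harbor (``NBH_NS``, same days, ~9×
more contaminated sediment). Sediment inventories are partitioned over
the illustrative three-congener registry so that the LC-PCB share of the
total matches each sediment (51% AVL, 44% NBH). Noise CVs default to
0.25 (PUF) and 0.35 (SPME) — calibration knobs representing the spread
of triplicate field measurements, not literature constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .congener_registry import Congener, default_congeners
from .measurement_pipeline import TABLE_COLUMNS, BlankSet, SurrogateRecovery
from .rtm_core import (
    NONSHAKEN,
    SHAKEN,
    MicrocosmConfig,
    RTMParams,
    assemble_system,
    initial_state_from_sediment,
    n_particles_for_sediment_mass,
    simulate,
)
from .particle_diffusion import ParticleGrid

__all__ = [
    "SynthDesign",
    "design_for_scenario",
    "generate_blanks",
    "generate_experiment",
    "generate_recoveries",
    "lc_fraction_percent",
]

SCENARIOS = ("AVL_S", "AVL_NS", "NBH_NS")

#: sediment inventories, ng per g dry sediment, chosen so totals and the
#: LC share match the two sediments (AVL: 6350 ng/g, 51% LC; NBH:
#: 59000 ng/g, 44% LC) with the mass split over the illustrative
#: three-congener set
SEDIMENT_S0 = {
    "AVL": {"PCB4": 1800.0, "PCB19": 1450.0, "PCB52": 3100.0},
    "NBH": {"PCB4": 14000.0, "PCB19": 11800.0, "PCB52": 33200.0},
}

#: added degrader biomass, g dry cells / L, for bioaugmented treatments
X_CELLS_TREATMENT = 0.25

#: true biodegradation rates, 1/d, per scenario and congener: PCB 4 is
#: well degraded (17 1/d shaken, 0.6 1/d nonshaken), PCB 19 resists
#: degradation, PCB 52 is intermediate
K_BIO_TREATMENT = {
    "AVL_S": {"PCB4": 17.0, "PCB19": 0.0, "PCB52": 2.0},
    "AVL_NS": {"PCB4": 0.6, "PCB19": 0.0, "PCB52": 0.2},
    "NBH_NS": {"PCB4": 0.6, "PCB19": 0.0, "PCB52": 0.2},
}

SAMPLING_DAYS = {
    "AVL_S": (3.0, 11.0, 16.0, 35.0),
    "AVL_NS": (16.0, 35.0, 75.0),
    "NBH_NS": (16.0, 35.0, 75.0),
}


@dataclass(frozen=True)
class SynthDesign:
    """Complete recipe for one synthetic experiment (both groups)."""

    scenario: str
    congeners: tuple[Congener, ...]
    s0: Mapping[str, float]
    cfg_control: MicrocosmConfig
    cfg_treatment: MicrocosmConfig
    params_control: RTMParams
    params_treatment: RTMParams
    k_bio_control: Mapping[str, float]
    k_bio_treatment: Mapping[str, float]
    sampling_days: tuple[float, ...]
    n_replicates: int = 3
    noise_cv: Mapping[str, float] = field(
        default_factory=lambda: {"PUF": 0.25, "SPME": 0.35}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for matrix, cv in self.noise_cv.items():
            if not 0 <= cv < 2:
                raise ValueError(f"noise_cv[{matrix}] must be in [0, 2)")
        missing = {c.peak_id for c in self.congeners} - set(self.s0)
        if missing:
            raise ValueError(f"no sediment inventory for peaks {sorted(missing)}")


def _nonshaken_particle(cfg: MicrocosmConfig) -> ParticleGrid:
    grid = ParticleGrid(radius=5e-3, n_shells=12, d_eff=0.4,
                        retardation=1000.0, porosity=0.5)
    return replace(grid,
                   n_particles_equiv=n_particles_for_sediment_mass(grid, cfg.m_sed))


def design_for_scenario(
    scenario: str,
    seed: int = 0,
    noise_cv: Mapping[str, float] | None = None,
    alpha_fiber: float | None = None,
) -> SynthDesign:
    """Default design for one of the three study arms.

    ``alpha_fiber`` (SPME fouling fraction) defaults to 0.15 in nonshaken
    treatments — fouling was a feature of undisturbed fibers — and 0 when
    shaken.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    sediment = "NBH" if scenario.startswith("NBH") else "AVL"
    regime = SHAKEN if scenario.endswith("_S") else NONSHAKEN
    if alpha_fiber is None:
        alpha_fiber = 0.15 if regime == NONSHAKEN else 0.0
    cfg_control = MicrocosmConfig(regime=regime, x_cells=0.0)
    cfg_treatment = MicrocosmConfig(regime=regime, x_cells=X_CELLS_TREATMENT)
    base = RTMParams(
        k_cell=8.0,
        v_aw=100.0 if regime == SHAKEN else 20.0,
        particle=_nonshaken_particle(cfg_control),
    )
    params_control = replace(base, alpha_fiber=0.0)
    params_treatment = replace(base, alpha_fiber=alpha_fiber)
    congeners = tuple(default_congeners())
    return SynthDesign(
        scenario=scenario,
        congeners=congeners,
        s0=dict(SEDIMENT_S0[sediment]),
        cfg_control=cfg_control,
        cfg_treatment=cfg_treatment,
        params_control=params_control,
        params_treatment=params_treatment,
        k_bio_control={c.peak_id: 0.0 for c in congeners},
        k_bio_treatment=dict(K_BIO_TREATMENT[scenario]),
        sampling_days=SAMPLING_DAYS[scenario],
        noise_cv=dict(noise_cv) if noise_cv is not None else
        {"PUF": 0.25, "SPME": 0.35},
        seed=seed,
    )


def lc_fraction_percent(
    s0: Mapping[str, float], congeners: Sequence[Congener]
) -> float:
    """LC-PCB share of a sediment inventory, percent."""
    by_peak = {c.peak_id: c for c in congeners}
    total = sum(s0.values())
    if total <= 0:
        raise ValueError("empty inventory")
    lc = sum(v for p, v in s0.items() if by_peak[p].is_lc)
    return lc / total * 100.0


def _mean_preserving_factors(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    """Multiplicative lognormal noise with E[factor] = 1."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def generate_experiment(
    design: SynthDesign, tol: float = 1e-8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate both groups and sample them as a lab would.

    For every group and congener the RTM is integrated from an
    all-in-sediment initial condition; at each sacrificial sampling day
    the PUF load (ng) and the APPARENT SPME load (ng/cm, including any
    fiber fouling) are read off and each replicate is drawn as
    ``truth × LogNormal`` with unit mean at the matrix's CV.

    Returns ``(table, truth)``: the long congener table
    (:data:`TABLE_COLUMNS`) and a noise-free truth record with the same
    keys plus ``truth_ng`` — identical tables for identical seeds.
    """
    rng = np.random.default_rng(design.seed)
    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    groups = {
        "control": (design.cfg_control, design.params_control,
                    design.k_bio_control),
        "treatment": (design.cfg_treatment, design.params_treatment,
                      design.k_bio_treatment),
    }
    days = np.asarray(design.sampling_days, dtype=float)
    for group, (cfg, base_params, k_bio_map) in groups.items():
        for congener in design.congeners:
            p = replace(base_params, k_bio=k_bio_map.get(congener.peak_id, 0.0))
            system = assemble_system(cfg, p, congener)
            y0 = initial_state_from_sediment(cfg, p, design.s0[congener.peak_id])
            traj = simulate(system, y0, days, tol=tol)
            truth = {"PUF": traj.series("m_puf"), "SPME": traj.apparent_spme()}
            for matrix in ("PUF", "SPME"):
                cv = float(design.noise_cv.get(matrix, 0.0))
                for i_day, day in enumerate(days):
                    factors = _mean_preserving_factors(
                        rng, cv, design.n_replicates
                    )
                    t_val = float(truth[matrix][i_day])
                    truth_rows.append(
                        (design.scenario, day, group, matrix,
                         congener.peak_id, t_val)
                    )
                    for rep in range(1, design.n_replicates + 1):
                        rows.append(
                            (design.scenario, day, rep, group, matrix,
                             congener.peak_id, t_val * factors[rep - 1])
                        )
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["experiment_id", "day", "group", "matrix", "peak_id",
                 "truth_ng"],
    )
    return table, truth_df


def generate_blanks(
    matrix: str,
    n: int,
    level: float,
    cv: float,
    seed: int,
    peaks: Sequence[str],
) -> BlankSet:
    """Laboratory blank set: per-peak positive lognormal draws around
    ``level`` (ng). The study ran n=19 PUF and n=3 SPME blanks."""
    if n < 2:
        raise ValueError("need at least 2 blanks")
    if level < 0 or cv < 0:
        raise ValueError("level and cv must be >= 0")
    rng = np.random.default_rng(seed)
    masses = {
        peak: level * _mean_preserving_factors(rng, cv, n) for peak in peaks
    }
    return BlankSet(matrix=matrix, masses=masses)


def generate_recoveries(
    homologues: Sequence[int],
    mean_by_homologue: Mapping[int, float],
    sd: float,
    seed: int,
    truncation: tuple[float, float] = (1e-6, 1.5),
) -> list[SurrogateRecovery]:
    """Surrogate recoveries per homologue: truncated-normal draws around
    the homologue means (study range 64±14% to 92±15%), truncated to
    (0, 1.5]."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    lo, hi = truncation
    if not 0 < lo < hi <= 1.5:
        raise ValueError("truncation must satisfy 0 < lo < hi <= 1.5")
    rng = np.random.default_rng(seed)
    out = []
    for h in homologues:
        mean = mean_by_homologue[h]
        if not lo <= mean <= hi:
            raise ValueError(f"mean for homologue {h} outside truncation")
        if sd == 0:
            rec = mean
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            rec = float(
                truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
            )
        out.append(SurrogateRecovery(homologue=h, recovery=rec))
    return out
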