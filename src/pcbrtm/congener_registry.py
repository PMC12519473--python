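"""PCB congener registry.

A *congener* here is one chromatographic peak: either a single PCB
structure or a set of coeluting structures that share a chlorine count
(homologue). Every downstream module — the reactive transport model, the
samplers, the measurement pipeline — looks partitioning properties up here.

Lower-chlorinated PCBs (LC-PCBs, ≤3 chlorines) are the volatile,
inhalation-relevant fraction and the primary substrates of aerobic
biphenyl-dioxygenase degraders, so the registry exposes that
classification directly.

The default property set shipped with :func:`default_congeners` is
*illustrative*: round-number partition coefficients of the right order of
magnitude for a di-, tri- and tetrachlorobiphenyl, intended for synthetic
experiments and tests. Site-specific work should load its own CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Congener",
    "CongenerError",
    "default_congeners",
    "is_lc",
    "load_congeners",
    "registry_by_peak",
    "write_congeners",
]

#: CSV header expected by :func:`load_congeners` (``member_n_cl`` optional).
CSV_COLUMNS = ("peak_id", "n_cl", "log_kow", "k_h", "k_d", "mw")

LC_MAX_CHLORINES = 3


class CongenerError(ValueError):
    """Invalid congener definition or congener file."""


@dataclass(frozen=True)
class Congener:
    """One PCB congener or coeluting peak.

    Parameters
    ----------
    peak_id:
        Label such as ``"PCB4"`` or ``"PCB20+28"`` for coeluting peaks.
    n_cl:
        Chlorine count (1–10). For a coeluting peak all members must share
        it; ``member_n_cl`` can list the members' counts for validation.
    log_kow:
        log10 octanol–water partition coefficient (dimensionless).
    k_h:
        Dimensionless Henry's law constant, air/water concentration ratio.
    k_d:
        Sediment–water distribution coefficient, L/kg.
    mw:
        Molar mass, g/mol.
    """

    peak_id: str
    n_cl: int
    log_kow: float
    k_h: float
    k_d: float
    mw: float
    member_n_cl: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.peak_id:
            raise CongenerError("peak_id must be non-empty")
        if not 1 <= self.n_cl <= 10:
            raise CongenerError(
                f"{self.peak_id}: n_cl must be in 1..10, got {self.n_cl}"
            )
        if self.k_h <= 0:
            raise CongenerError(f"{self.peak_id}: k_h must be > 0")
        if self.k_d < 0:
            raise CongenerError(f"{self.peak_id}: k_d must be >= 0")
        if self.mw <= 0:
            raise CongenerError(f"{self.peak_id}: mw must be > 0")
        bad = [m for m in self.member_n_cl if m != self.n_cl]
        if bad:
            raise CongenerError(
                f"{self.peak_id}: coeluting members with chlorine counts "
                f"{sorted(set(bad))} differ from declared homologue "
                f"{self.n_cl}; mixed-homologue coelutions are not supported"
            )

    @property
    def homologue(self) -> int:
        """Homologue group = shared chlorine count of the peak's members."""
        return self.n_cl

    @property
    def is_lc(self) -> bool:
        """True for lower-chlorinated congeners (≤3 chlorines)."""
        return self.n_cl <= LC_MAX_CHLORINES


def is_lc(c: Congener) -> bool:
    """Whether ``c`` is a lower-chlorinated (≤3 Cl) congener."""
    return c.is_lc


def default_congeners() -> list[Congener]:
    """Illustrative three-congener set (values are NOT literature data).

    PCB 4 (2,2'-dichlorobiphenyl) — well degraded by LB400; PCB 19
    (2,2',6-trichlorobiphenyl) — recalcitrant LC congener; PCB 52 — a
    tetrachlorinated, non-LC reference.
    """
    return [
        Congener("PCB4", 2, log_kow=4.65, k_h=0.012, k_d=1000.0, mw=223.1),
        Congener("PCB19", 3, log_kow=5.02, k_h=0.012, k_d=2000.0, mw=257.5),
        Congener("PCB52", 4, log_kow=5.84, k_h=0.013, k_d=6000.0, mw=292.0),
    ]


def registry_by_peak(congeners: Iterable[Congener]) -> dict[str, Congener]:
    """Index congeners by peak_id, rejecting duplicates."""
    out: dict[str, Congener] = {}
    for c in congeners:
        if c.peak_id in out:
            raise CongenerError(f"duplicate peak_id {c.peak_id!r}")
        out[c.peak_id] = c
    return out


def _parse_members(raw: str) -> tuple[int, ...]:
    raw = raw.strip()
    if not raw:
        return ()
    try:
        return tuple(int(tok) for tok in raw.split(";"))
    except ValueError as exc:
        raise CongenerError(f"cannot parse member_n_cl {raw!r}") from exc


def load_congeners(path: str | Path) -> list[Congener]:
    """Load a congener table from CSV.

    Required columns: ``peak_id,n_cl,log_kow,k_h,k_d,mw``; optional
    ``member_n_cl`` lists coeluting members' chlorine counts separated by
    ``;``. Duplicate peak ids, missing columns, non-numeric fields and
    invariant violations raise :class:`CongenerError` naming the row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CongenerError(f"{path}: empty file")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CongenerError(f"{path}: missing columns {missing}")
        congeners: list[Congener] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            try:
                c = Congener(
                    peak_id=row["peak_id"].strip(),
                    n_cl=int(row["n_cl"]),
                    log_kow=float(row["log_kow"]),
                    k_h=float(row["k_h"]),
                    k_d=float(row["k_d"]),
                    mw=float(row["mw"]),
                    member_n_cl=_parse_members(row.get("member_n_cl") or ""),
                )
            except CongenerError as exc:
                raise CongenerError(f"{path} row {i}: {exc}") from exc
            except (KeyError, TypeError, ValueError) as exc:
                raise CongenerError(
                    f"{path} row {i}: invalid field ({exc})"
                ) from exc
            if c.peak_id in seen:
                raise CongenerError(
                    f"{path} row {i}: duplicate peak_id {c.peak_id!r}"
                )
            seen.add(c.peak_id)
            congeners.append(c)
    return congeners


def write_congeners(congeners: Sequence[Congener], path: str | Path) -> None:
    """Write a congener table; round-trips with :func:`load_congeners`.

    Floats are written with :func:`repr` so a load reproduces them
    bit-exactly.
    """
    registry_by_peak(congeners)  # enforce uniqueness before writing
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(CSV_COLUMNS) + ["member_n_cl"])
        for c in congeners:
            writer.writerow(
                [
                    c.peak_id,
                    c.n_cl,
                    repr(c.log_kow),
                    repr(c.k_h),
                    repr(c.k_d),
                    repr(c.mw),
                    ";".join(str(m) for m in c.member_n_cl),
                ]
            )
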