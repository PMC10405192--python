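"""Domain types for AnSBR monitoring data.

An anaerobic sequencing batch reactor (AnSBR) line consists of a buffer tank
that pre-acidifies raw wastewater, the reactor proper, and a settling tank.
Routine monitoring produces (i) analyte concentrations per tank and day,
(ii) batch settling tests of the sludge, (iii) particle-size distributions,
and (iv) 16S amplicon data reduced upstream to an ASV count table, a taxonomy
and a rooted phylogeny. The types below are thin, validated containers for
those observations; all heavy lifting lives in the analysis modules.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, OutOfRangeError, ValidationError


class Tank(str, enum.Enum):
    influent = "influent"
    buffer_tank = "buffer_tank"
    reactor = "reactor"
    effluent = "effluent"


class Analyte(str, enum.Enum):
    TCOD = "TCOD"
    SCOD = "SCOD"
    TSS = "TSS"
    VSS = "VSS"
    TKN = "TKN"
    soluble_KN = "soluble_KN"
    NH4_N = "NH4_N"
    VFA_COD = "VFA_COD"
    protein = "protein"
    carbohydrate = "carbohydrate"
    FOG = "FOG"
    biogas_volume = "biogas_volume"
    ch4_fraction = "ch4_fraction"


class SizeFraction(str, enum.Enum):
    total = "total"
    gt_1um = "gt_1um"
    um_0p45_to_1 = "um_0p45_to_1"
    lt_0p45um = "lt_0p45um"


#: Units per analyte. Concentrations are mg L^-1; biogas volume is L d^-1 and
#: the CH4 fraction of biogas is dimensionless in [0, 1].
ANALYTE_UNITS: Mapping[Analyte, str] = {
    **{a: "mg/L" for a in Analyte},
    Analyte.biogas_volume: "L/d",
    Analyte.ch4_fraction: "fraction",
}


@dataclass(frozen=True)
class MeasurementRecord:
    """One analyte observation at a time point in a tank."""

    day: float
    tank: Tank
    analyte: Analyte
    value: float
    size_fraction: SizeFraction = SizeFraction.total
    hour_in_cycle: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError(f"day must be >= 0, got {self.day}")
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"value must be finite and >= 0, got {self.value} "
                f"({self.analyte.value}, day {self.day})"
            )
        if self.analyte is Analyte.ch4_fraction and not 0.0 <= self.value <= 1.0:
            raise ValidationError(
                f"ch4_fraction must lie in [0, 1], got {self.value}"
            )
        if self.hour_in_cycle is not None and not 0 <= self.hour_in_cycle <= 6:
            raise ValidationError(
                f"hour_in_cycle must lie in 0..6, got {self.hour_in_cycle}"
            )


@dataclass(frozen=True)
class PhaseDefinition:
    """A named operational phase covering a closed interval of days."""

    name: str
    day_start: float
    day_end: float

    def __post_init__(self) -> None:
        if self.day_end < self.day_start:
            raise ValidationError(
                f"phase {self.name}: day_end {self.day_end} < day_start {self.day_start}"
            )

    def contains(self, day: float) -> bool:
        return self.day_start <= day <= self.day_end


#: The study's three operational phases: start-up, stable operation, and the
#: high-loading phase in which the organic loading rate was pushed to its
#: design threshold.
DEFAULT_PHASES: tuple[PhaseDefinition, ...] = (
    PhaseDefinition("I", 0, 55),
    PhaseDefinition("II", 56, 196),
    PhaseDefinition("III", 197, 260),
)


def validate_phases(phases: Sequence[PhaseDefinition]) -> None:
    """Check that phases are ordered and non-overlapping."""
    for prev, cur in zip(phases, phases[1:]):
        if cur.day_start <= prev.day_end:
            raise ValidationError(
                f"phases {prev.name} and {cur.name} overlap or are out of order"
            )


def assign_phase(day: float, phases: Sequence[PhaseDefinition] = DEFAULT_PHASES) -> str:
    """Return the name of the phase whose closed interval contains *day*.

    If a day falls on a boundary shared by two phases it belongs to the
    earlier one (phases are scanned in order). Phase windows are given in
    whole days, so a fractional day between two consecutive windows (e.g.
    55.5 between [0, 55] and [56, 196]) belongs to the phase of its whole
    day: phase I runs until day 56 begins.
    """
    for phase in phases:
        if phase.contains(day):
            return phase.name
    for prev, nxt in zip(phases, phases[1:]):
        if prev.day_end < day < nxt.day_start:
            return prev.name
    raise OutOfRangeError(f"day {day} falls outside all defined phases")


@dataclass(frozen=True)
class ReactorConfig:
    """Physical configuration of the AnSBR line.

    Defaults describe a 10-L buffer tank, 30-L reactor and 12-L settling tank
    run on four 6-h cycles per day at 36 degC, with gas volumes referred to
    standard conditions (273.15 K, 1 atm).
    """

    buffer_tank_volume: float = 10.0
    reactor_volume: float = 30.0
    settling_tank_volume: float = 12.0
    cycles_per_day: int = 4
    cycle_hours: float = 6.0
    reactor_temperature: float = 36.0
    gas_reference_temperature: float = 273.15
    gas_reference_pressure: float = 1.0

    def __post_init__(self) -> None:
        for name in ("buffer_tank_volume", "reactor_volume", "settling_tank_volume"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.gas_reference_temperature <= 0 or self.gas_reference_pressure <= 0:
            raise ValidationError("gas reference temperature/pressure must be > 0")


@dataclass(frozen=True)
class SettlingObservation:
    """A batch settling test.

    ``trajectory`` records the distance from the liquid surface to the
    sludge-liquid interface (same length unit throughout, increasing as the
    blanket settles) at strictly increasing times in minutes.
    """

    day: float
    sludge_concentration_X: float  # g TSS / L
    trajectory: tuple[tuple[float, float], ...]
    measured_zsv: Optional[float] = None  # m / h

    def __post_init__(self) -> None:
        if self.sludge_concentration_X <= 0:
            raise ValidationError("sludge concentration X must be > 0")
        times = [t for t, _ in self.trajectory]
        depths = [d for _, d in self.trajectory]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("trajectory times must be strictly increasing")
        if any(b < a for a, b in zip(depths, depths[1:])):
            raise ValidationError("interface depth must be non-decreasing in time")
        if any(d < 0 for d in depths):
            raise ValidationError("interface depths must be >= 0")

    @property
    def times_min(self) -> np.ndarray:
        return np.array([t for t, _ in self.trajectory], dtype=float)

    @property
    def depths(self) -> np.ndarray:
        return np.array([d for _, d in self.trajectory], dtype=float)


@dataclass(frozen=True)
class PSDRecord:
    """A particle-size distribution: volume fraction per diameter channel."""

    day: float
    distribution: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        diams = [d for d, _ in self.distribution]
        fracs = [f for _, f in self.distribution]
        if not diams:
            raise ValidationError("PSD distribution is empty")
        if any(b <= a for a, b in zip(diams, diams[1:])):
            raise ValidationError("PSD diameters must be strictly increasing")
        if min(diams) < 0.01 or max(diams) > 2000:
            raise ValidationError("PSD diameters must lie within 0.01-2000 um")
        if any(f < 0 for f in fracs):
            raise ValidationError("PSD volume fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > 1e-6:
            raise ValidationError(
                f"PSD volume fractions must sum to 1 (got {sum(fracs):.8f})"
            )

    @property
    def diameters_um(self) -> np.ndarray:
        return np.array([d for d, _ in self.distribution], dtype=float)

    @property
    def volume_fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.distribution], dtype=float)


class ASVTable:
    """A samples x ASVs count matrix with per-sample metadata.

    Counts are non-negative integers (one row per sample). ``sample_metadata``
    maps sample id to a dict of covariates (tank, day, operational values...).
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        asv_ids: Sequence[str],
        counts: np.ndarray,
        sample_metadata: Optional[Mapping[str, Mapping[str, object]]] = None,
    ) -> None:
        sample_ids = list(sample_ids)
        asv_ids = list(asv_ids)
        counts = np.asarray(counts)
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(asv_ids)) != len(asv_ids):
            dupes = sorted({a for a in asv_ids if asv_ids.count(a) > 1})
            raise ValidationError(f"duplicate ASV ids: {dupes[:5]}")
        if counts.shape != (len(sample_ids), len(asv_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"({len(sample_ids)} samples, {len(asv_ids)} ASVs)"
            )
        if counts.size and (not np.issubdtype(counts.dtype, np.integer)):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.sample_ids = sample_ids
        self.asv_ids = asv_ids
        self.counts = counts.astype(np.int64)
        self.sample_metadata = {s: dict((sample_metadata or {}).get(s, {})) for s in sample_ids}

    def __repr__(self) -> str:  # pragma: no cover
        return f"ASVTable({len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def presence(self) -> np.ndarray:
        """Boolean samples x ASVs presence matrix."""
        return self.counts > 0

    def select_samples(self, sample_ids: Sequence[str]) -> "ASVTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ASVTable(
            list(sample_ids),
            self.asv_ids,
            self.counts[idx],
            {s: self.sample_metadata[s] for s in sample_ids},
        )


TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus")


class Taxonomy:
    """Per-ASV rank assignments; missing ranks are stored as ``None``."""

    def __init__(self, assignments: Mapping[str, Mapping[str, Optional[str]]]) -> None:
        self.assignments = {
            asv: {r: (ranks.get(r) or None) for r in TAXONOMY_RANKS}
            for asv, ranks in assignments.items()
        }

    def rank_label(self, asv_id: str, rank: str) -> str:
        if rank not in TAXONOMY_RANKS:
            raise DomainError(f"unsupported rank {rank!r}; choose from {TAXONOMY_RANKS}")
        label = self.assignments.get(asv_id, {}).get(rank)
        return label if label else "Unassigned"

    def __contains__(self, asv_id: str) -> bool:
        return asv_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class DailyOperation:
    """Operational bookkeeping for one day, inputs to loading/retention metrics."""

    day: float
    influent_tcod: float  # mg/L
    fed_volume: float  # L/d
    reactor_vss_mass: float  # g VSS in the reactor
    wasted_sludge: float  # g/d
    total_sludge: float  # g

    def __post_init__(self) -> None:
        if self.fed_volume < 0:
            raise ValidationError("fed_volume must be >= 0")


@dataclass(frozen=True)
class PhaseSummary:
    """Mean +/- sample SD per metric within one operational phase."""

    phase: str
    metrics: Mapping[str, tuple[float, float, int]]  # name -> (mean, sd, n)


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric, hollow, non-negative pairwise distance matrix."""

    ids: tuple[str, ...]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if data.shape != (n, n):
            raise ValidationError(f"distance matrix shape {data.shape} != ({n}, {n})")
        if not np.allclose(data, data.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(data)) > 1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if data.size and data.min() < -1e-12:
            raise ValidationError("distances must be non-negative")
        object.__setattr__(self, "data", data)

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))
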