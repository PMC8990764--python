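"""Core data model for split-plot wheat-pea intercropping trials.

The experimental unit is one plot x species observation: a field plot belongs
to a season, a replicate block and a main plot (the cropping system:
wheat monoculture, pea monoculture, or the wheat-pea mixture), and within the
main plot to a subplot carrying one wheat entry.  Mixture plots yield two
records, one per species.  All validation lives here so that readers,
the simulator and the analysis stages share one contract.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

WHEAT = "wheat"
PEA = "pea"
SPECIES = (WHEAT, PEA)

MONO_WHEAT = "monoculture_wheat"
MONO_PEA = "monoculture_pea"
MIXTURE = "mixture"
SYSTEMS = (MONO_WHEAT, MONO_PEA, MIXTURE)

ENTRY_TYPES = ("line", "HP")
ORIGIN_GROUPS = ("C-lines", "H-lines", "K-HPs", "D-HPs", "H-HPs")

FOOT_PATHOGENS = ("fusarium", "oculimacula", "ceratobasidium", "joint")
FOOT_CLASSES = (0, 1, 2, 3)

REFERENCE_MOISTURE = 0.14


class MixtrialError(Exception):
    """Base class for package errors."""


class SchemaError(MixtrialError):
    """A table is structurally wrong (e.g. a mandatory column is missing)."""


class ValidationError(MixtrialError):
    """A value violates a data-model invariant."""


class DomainError(MixtrialError, ValueError):
    """A scalar argument is outside the mathematical domain of an index."""


class InsufficientDataError(MixtrialError):
    """Too few observations to compute the requested quantity."""


class DesignError(MixtrialError):
    """The trial design is unusable for the requested operation."""


@dataclass(frozen=True)
class EntryInfo:
    """One wheat entry: a line cultivar or a heterogeneous population (HP)."""

    name: str
    entry_type: str  # "line" or "HP"
    origin_group: str  # one of ORIGIN_GROUPS

    def __post_init__(self) -> None:
        if self.entry_type not in ENTRY_TYPES:
            raise ValidationError(
                f"entry_type {self.entry_type!r} not in {ENTRY_TYPES}"
            )
        if self.origin_group not in ORIGIN_GROUPS:
            raise ValidationError(
                f"origin_group {self.origin_group!r} not in {ORIGIN_GROUPS}"
            )


@dataclass
class TrialDesign:
    """Factor structure and sowing densities of the split-plot trial.

    ``sowing_density_mono`` holds pure-stand densities in seeds/m2 (wheat 350,
    pea 90 by default) and ``relative_density`` the unitless mixture fractions
    D_wheat = 0.7 and D_pea = 0.5: mixtures are sown partially additively at
    70% of the wheat and 50% of the pea pure stand.
    """

    seasons: tuple[str, ...] = ("2018/19", "2019/20")
    entries: tuple[EntryInfo, ...] = ()
    n_blocks: int = 4
    sowing_density_mono: dict = field(
        default_factory=lambda: {WHEAT: 350.0, PEA: 90.0}
    )
    relative_density: dict = field(
        default_factory=lambda: {WHEAT: 0.7, PEA: 0.5}
    )
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise DesignError("n_blocks must be a positive integer")
        for sp in SPECIES:
            d = self.relative_density[sp]
            if not 0.0 < d <= 1.0:
                raise DesignError(
                    f"relative density for {sp} must be in (0, 1], got {d}"
                )
            if self.sowing_density_mono[sp] <= 0:
                raise DesignError(f"monoculture density for {sp} must be > 0")
        if not 0.0 < self.ci_level < 1.0:
            raise DesignError("ci_level must be a fraction in (0, 1)")
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise DesignError("entry names must be unique")

    @property
    def entry_names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def require_inference(self) -> None:
        if self.n_blocks < 2:
            raise DesignError("at least 2 blocks are required for inference")


#: the 15 wheat entries of the reference trial, grouped by type and origin
DEFAULT_ENTRIES: tuple[EntryInfo, ...] = (
    EntryInfo("Achat", "line", "C-lines"),
    EntryInfo("Butaro", "line", "C-lines"),
    EntryInfo("Capo", "line", "C-lines"),
    EntryInfo("Wiwa", "line", "C-lines"),
    EntryInfo("Karizma", "line", "H-lines"),
    EntryInfo("Kolompos", "line", "H-lines"),
    EntryInfo("Nemere", "line", "H-lines"),
    EntryInfo("Toborzo", "line", "H-lines"),
    EntryInfo("OYQII", "HP", "K-HPs"),
    EntryInfo("OQII", "HP", "K-HPs"),
    EntryInfo("BSFI", "HP", "K-HPs"),
    EntryInfo("BSFII", "HP", "K-HPs"),
    EntryInfo("Brandex", "HP", "D-HPs"),
    EntryInfo("Liocharls", "HP", "D-HPs"),
    EntryInfo("Elit CCP", "HP", "H-HPs"),
)


def default_design(
    seasons: Sequence[str] = ("2018/19", "2019/20"), n_blocks: int = 4
) -> TrialDesign:
    """The reference design: 2 seasons x 3 systems x 15 entries x 4 blocks."""
    return TrialDesign(seasons=tuple(seasons), entries=DEFAULT_ENTRIES,
                       n_blocks=n_blocks)


@dataclass
class AssessmentSeries:
    """Repeated visual assessments of non-green leaf area (NGLA, %)."""

    dates: tuple[dt.date, ...]
    values: tuple[float, ...]
    causes: Optional[tuple[str, ...]] = None  # top causes per date, free text

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.values):
            raise ValidationError("dates and values must have equal length")
        for a, b in zip(self.dates, self.dates[1:]):
            if not b > a:
                raise ValidationError(
                    f"assessment dates must be strictly increasing: {a} !< {b}"
                )
        for v in self.values:
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"NGLA value {v} outside [0, 100]"
                )
        if self.causes is not None and len(self.causes) != len(self.dates):
            raise ValidationError("causes must align with dates")

    def __len__(self) -> int:
        return len(self.dates)


_PCT_FIELDS = ("protein", "gluten", "water_content", "weed_cover", "lodging")


@dataclass
class PlotRecord:
    """One plot x species observation set."""

    season: str
    block: int
    main_plot_id: str
    system: str
    entry: Optional[str]  # wheat entry; None on pea-monoculture rows
    species: str
    grain_yield: Optional[float] = None  # t/ha at 14% moisture
    raw_moisture: Optional[float] = None  # fraction, before normalisation
    total_biomass: Optional[float] = None  # t/ha
    ears_per_m2: Optional[float] = None
    kernels_per_ear: Optional[float] = None
    tgw: Optional[float] = None  # thousand-grain weight, g
    protein: Optional[float] = None  # %
    gluten: Optional[float] = None  # %
    water_content: Optional[float] = None  # %
    sedimentation: Optional[float] = None  # ml
    hectoliter_weight: Optional[float] = None  # kg/hl
    weed_cover: Optional[float] = None  # % of plot area
    lodging: Optional[float] = None  # % of plot area
    emergence_count: Optional[float] = None  # seedlings/m2
    survival_count: Optional[float] = None  # seedlings/m2 after winter
    sowing_date: Optional[dt.date] = None
    heading_date: Optional[dt.date] = None
    ngla_series: Optional[AssessmentSeries] = None
    foot_disease_counts: Optional[dict] = None  # {pathogen: (n0, n1, n2, n3)}

    def validate(self, design: Optional[TrialDesign] = None) -> None:
        if self.system not in SYSTEMS:
            raise ValidationError(f"unknown system {self.system!r}")
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.system == MONO_WHEAT and self.species != WHEAT:
            raise ValidationError("wheat monoculture rows must be wheat")
        if self.system == MONO_PEA and self.species != PEA:
            raise ValidationError("pea monoculture rows must be pea")
        if self.system != MONO_PEA and not self.entry:
            raise ValidationError(
                f"{self.system} row requires a wheat entry label"
            )
        if design is not None:
            if self.season not in design.seasons:
                raise ValidationError(
                    f"season {self.season!r} not in design {design.seasons}"
                )
            if not 1 <= self.block <= design.n_blocks:
                raise ValidationError(
                    f"block {self.block} outside 1..{design.n_blocks}"
                )
            if self.entry is not None and self.entry not in design.entry_names:
                raise ValidationError(
                    f"entry {self.entry!r} not in the trial design"
                )
        for name in _PCT_FIELDS:
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"{name} = {v} outside [0, 100]"
                )
        for name in ("grain_yield", "total_biomass", "ears_per_m2",
                     "kernels_per_ear", "tgw", "sedimentation",
                     "hectoliter_weight", "emergence_count", "survival_count"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} = {v} must be >= 0")
        if (self.grain_yield is not None and self.total_biomass is not None
                and self.grain_yield > self.total_biomass + 1e-9):
            raise ValidationError(
                f"grain_yield {self.grain_yield} exceeds total_biomass "
                f"{self.total_biomass}"
            )
        if (self.sowing_date is not None and self.heading_date is not None
                and self.heading_date < self.sowing_date):
            raise ValidationError("heading_date precedes sowing_date")
        if self.raw_moisture is not None and not 0.0 <= self.raw_moisture < 0.5:
            raise ValidationError(
                f"raw_moisture {self.raw_moisture} outside [0, 0.5)"
            )
        if self.foot_disease_counts is not None:
            for path, counts in self.foot_disease_counts.items():
                if path not in FOOT_PATHOGENS:
                    raise ValidationError(f"unknown foot pathogen {path!r}")
                if len(counts) != 4 or any(c < 0 for c in counts):
                    raise ValidationError(
                        f"foot disease counts for {path} must be 4 "
                        "non-negative class counts"
                    )


def normalize_moisture(raw_yield: float, raw_moisture: float) -> float:
    """Convert a fresh-weight yield to t/ha at the 14% reference moisture.

    Dry matter is conserved: yield_14 = raw * (1 - m) / (1 - 0.14).
    """
    if raw_moisture < 0 or raw_moisture >= 0.5:
        raise DomainError(
            f"raw moisture fraction must be in [0, 0.5), got {raw_moisture}"
        )
    if raw_yield < 0:
        raise DomainError("yield must be non-negative")
    return raw_yield * (1.0 - raw_moisture) / (1.0 - REFERENCE_MOISTURE)
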