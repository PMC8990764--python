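"""Mixture-performance, crop-protection and quality indices.

Implements the per-plot quantities of the analysis: expected mixture yield
Ymix_e = Y1mon*D1 + Y2mon*D2, yield gain YG = Ymix_t - Ymix_e (absolute and
relative), land equivalent ratio LER = sum of partial LERs, relative mixture
effects RME = 100*(Rmix/Rmon - 1) from per-plot response ratios, the area
under the non-green-leaf-area curve (AUNGLA, an AUDPC-type trapezoidal
integral), the 0-100 foot-disease severity index, harvest index, days to
heading, and the protein-based baking-quality classes.

All pairing is per block: each mixture plot is matched with the same-entry
wheat-monoculture plot and the pea-monoculture plot of its block, matching
the per-plot response-ratio models downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import (
    MIXTURE,
    MONO_PEA,
    MONO_WHEAT,
    PEA,
    WHEAT,
    AssessmentSeries,
    DomainError,
    InsufficientDataError,
    PlotRecord,
    TrialDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)

QUALITY_CLASSES = ("fodder", "second_class_baking", "first_class_baking")


@dataclass(frozen=True)
class MixtureYieldSet:
    """Species yields needed for YG and LER of one block x entry cell."""

    y1_mon: float  # wheat monoculture yield, t/ha
    y2_mon: float  # pea monoculture yield, t/ha
    y1_mix: float  # wheat yield in mixture, t/ha
    y2_mix: float  # pea yield in mixture, t/ha
    d1: float = 0.7  # relative wheat sowing density in mixture
    d2: float = 0.5  # relative pea sowing density in mixture

    def __post_init__(self) -> None:
        for name in ("y1_mon", "y2_mon", "y1_mix", "y2_mix"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        # densities of 0 are tolerated here so that pure-stand edge cases
        # remain expressible; the trial design itself requires (0, 1]
        for name in ("d1", "d2"):
            d = getattr(self, name)
            if not 0.0 <= d <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {d}")


def expected_mixture_yield(yset: MixtureYieldSet) -> float:
    """Density-weighted expected mixture yield from the two pure stands."""
    return yset.y1_mon * yset.d1 + yset.y2_mon * yset.d2


def yield_gain(y_mix_total: float, y_mix_expected: float,
               relative: bool = True):
    """Absolute (t/ha) and relative (%) yield gain of the mixture."""
    if y_mix_total < 0 or y_mix_expected < 0:
        raise DomainError("yields must be non-negative")
    absolute = y_mix_total - y_mix_expected
    if not relative:
        return absolute, None
    if y_mix_expected == 0:
        raise DomainError("relative yield gain undefined for expected yield 0")
    return absolute, 100.0 * absolute / y_mix_expected


def ler(yset: MixtureYieldSet) -> tuple[float, float, float]:
    """(LER, pLER_wheat, pLER_pea); LER is exactly the sum of the pLERs."""
    if yset.y1_mon <= 0 or yset.y2_mon <= 0:
        raise DomainError(
            "LER undefined: a monoculture yield is zero (zero denominator)"
        )
    pler_wheat = yset.y1_mix / yset.y1_mon
    pler_pea = yset.y2_mix / yset.y2_mon
    return pler_wheat + pler_pea, pler_wheat, pler_pea


def rme(r_mix: float, r_mon: float) -> float:
    """Relative mixture effect, %: 100*(Rmix/Rmon - 1)."""
    if r_mon == 0:
        raise DomainError("RME undefined: monoculture response is zero")
    return 100.0 * (r_mix / r_mon - 1.0)


def aungla(series: AssessmentSeries) -> float:
    """Trapezoidal area under the NGLA curve, %*days."""
    if series is None or len(series) < 2:
        raise InsufficientDataError(
            "AUNGLA needs at least two assessment dates"
        )
    t = np.array([(d - series.dates[0]).days for d in series.dates],
                 dtype=float)
    v = np.asarray(series.values, dtype=float)
    return float(np.trapezoid(v, t))


def foot_disease_index(counts: Iterable[float]) -> float:
    """Weighted severity index on 0-100 from per-class tiller counts n0..n3.

    DIA = 100 * (n1 + 2*n2 + 3*n3) / (3 * N).
    """
    n = np.asarray(list(counts), dtype=float)
    if n.shape != (4,):
        raise DomainError("expected four class counts n0..n3")
    if (n < 0).any():
        raise DomainError("class counts must be non-negative")
    total = n.sum()
    if total == 0:
        raise InsufficientDataError("no tillers scored")
    return float(100.0 * (n[1] + 2.0 * n[2] + 3.0 * n[3]) / (3.0 * total))


def harvest_index(grain: float, biomass: float) -> float:
    """Grain yield over total above-ground biomass, in [0, 1]."""
    if biomass <= 0:
        raise DomainError("biomass must be > 0")
    if grain < 0:
        raise DomainError("grain yield must be >= 0")
    if grain > biomass:
        raise ValidationError(
            f"grain {grain} exceeds biomass {biomass}"
        )
    return grain / biomass


def days_to_heading(sowing, heading) -> int:
    """Whole days from sowing to heading (growth stage BBCH 50)."""
    if heading < sowing:
        raise ValidationError("heading date precedes sowing date")
    return (heading - sowing).days


def quality_class(protein: float) -> str:
    """Protein-based wheat quality class.

    < 10% fodder; 10-11% (closed interval) second-class baking; > 11%
    first-class baking.
    """
    if not 0.0 <= protein <= 100.0:
        raise DomainError(f"protein {protein} outside [0, 100]")
    if protein < 10.0:
        return "fodder"
    if protein <= 11.0:
        return "second_class_baking"
    return "first_class_baking"


def density_summary(mono_wheat: float, mono_pea: float,
                    d_wheat: float, d_pea: float):
    """(mixture seeds/m2, % of wheat pure stand, % of pea pure stand).

    Percentages are rounded to whole percent, as conventionally reported.
    """
    if mono_wheat <= 0 or mono_pea <= 0:
        raise DomainError("pure-stand densities must be > 0")
    total = mono_wheat * d_wheat + mono_pea * d_pea
    pct_wheat = round(100.0 * total / mono_wheat)
    pct_pea = round(100.0 * total / mono_pea)
    return total, pct_wheat, pct_pea


def mixture_density_summary(design: TrialDesign):
    """Density summary of a trial design's mixture relative to pure stands."""
    dm = design.sowing_density_mono
    rd = design.relative_density
    return density_summary(dm[WHEAT], dm[PEA], rd[WHEAT], rd[PEA])


# ---------------------------------------------------------------------------
# plot-level response extraction and per-block index assembly

def _first(values):
    for v in values:
        if v is not None:
            return v
    return None


def _plot_map(records: Iterable[PlotRecord]):
    """{(season, block, system, entry): {species: record}}"""
    plots: dict = {}
    for r in records:
        key = (r.season, r.block, r.system, r.entry)
        plots.setdefault(key, {})[r.species] = r
    return plots


def _aungla_or_none(rec: Optional[PlotRecord]):
    if rec is None or rec.ngla_series is None or len(rec.ngla_series) < 2:
        return None
    return aungla(rec.ngla_series)


def _dia_or_none(rec: Optional[PlotRecord], pathogen: str = "joint"):
    if rec is None or not rec.foot_disease_counts:
        return None
    counts = rec.foot_disease_counts.get(pathogen)
    if counts is None:
        return None
    return foot_disease_index(counts)


def _hi_or_none(rec: Optional[PlotRecord]):
    if rec is None or rec.grain_yield is None or not rec.total_biomass:
        return None
    return harvest_index(rec.grain_yield, rec.total_biomass)


def _dth_or_none(rec: Optional[PlotRecord]):
    if rec is None or rec.sowing_date is None or rec.heading_date is None:
        return None
    return days_to_heading(rec.sowing_date, rec.heading_date)


# value extractors on the wheat record of a plot (or the plot's lead record)
_WHEAT_SCALARS = ("protein", "gluten", "water_content", "sedimentation",
                  "hectoliter_weight", "tgw", "ears_per_m2",
                  "kernels_per_ear", "emergence_count", "survival_count")


def build_index_table(records: Iterable[PlotRecord],
                      design: TrialDesign) -> pd.DataFrame:
    """Per (season, block, entry) mixture indices.

    Pairs each mixture plot with the same-entry wheat-monoculture plot and the
    pea-monoculture plot of the same block.  Rows with undefined quantities
    (missing plots, zero monoculture yields) carry NaN in the affected columns
    and are counted in the log.
    """
    plots = _plot_map(records)
    d1 = design.relative_density[WHEAT]
    d2 = design.relative_density[PEA]
    rows = []
    skipped = 0
    for season in design.seasons:
        for block in range(1, design.n_blocks + 1):
            pea_mono = plots.get((season, block, MONO_PEA, None), {}).get(PEA)
            for entry in design.entry_names:
                w_mono = plots.get((season, block, MONO_WHEAT, entry),
                                   {}).get(WHEAT)
                mix = plots.get((season, block, MIXTURE, entry), {})
                w_mix, p_mix = mix.get(WHEAT), mix.get(PEA)
                if w_mono is None and w_mix is None:
                    continue
                row = {"season": season, "block": block, "entry": entry}
                y1_mon = w_mono.grain_yield if w_mono else None
                y2_mon = pea_mono.grain_yield if pea_mono else None
                y1_mix = w_mix.grain_yield if w_mix else None
                y2_mix = p_mix.grain_yield if p_mix else None
                row.update(y1_mon=y1_mon, y2_mon=y2_mon,
                           y1_mix=y1_mix, y2_mix=y2_mix)
                if None not in (y1_mon, y2_mon, y1_mix, y2_mix):
                    yset = MixtureYieldSet(y1_mon, y2_mon, y1_mix, y2_mix,
                                           d1, d2)
                    y_exp = expected_mixture_yield(yset)
                    y_tot = y1_mix + y2_mix
                    row["y_mix_total"] = y_tot
                    row["y_mix_expected"] = y_exp
                    if y_exp > 0:
                        yg_abs, yg_rel = yield_gain(y_tot, y_exp)
                        row["yg_abs"] = yg_abs
                        row["yg_rel"] = yg_rel
                        row["rme_yield_gain"] = rme(y_tot, y_exp)
                    if y1_mon > 0 and y2_mon > 0:
                        l, pw, pp = ler(yset)
                        row.update(ler=l, pler_wheat=pw, pler_pea=pp)
                    else:
                        skipped += 1
                else:
                    skipped += 1
                row["aungla_mono"] = _aungla_or_none(w_mono)
                row["aungla_mix"] = _aungla_or_none(w_mix)
                row["dia_mono"] = _dia_or_none(w_mono)
                row["dia_mix"] = _dia_or_none(w_mix)
                row["hi_mono"] = _hi_or_none(w_mono)
                row["hi_mix"] = _hi_or_none(w_mix)
                row["dth_mono"] = _dth_or_none(w_mono)
                row["dth_mix"] = _dth_or_none(w_mix)
                for name in ("protein", "gluten", "sedimentation"):
                    row[f"{name}_mono"] = getattr(w_mono, name) if w_mono else None
                    row[f"{name}_mix"] = getattr(w_mix, name) if w_mix else None
                for rec, tag in ((w_mono, "mono"), (w_mix, "mix")):
                    p = rec.protein if rec else None
                    row[f"quality_class_{tag}"] = (
                        quality_class(p) if p is not None else None
                    )
                rows.append(row)
    if skipped:
        logger.info("build_index_table: %d block x entry cells lacked a "
                    "complete yield set", skipped)
    return pd.DataFrame(rows)


#: (response, baseline) pairs entering the response-ratio (RME) models;
#: baseline "expected" divides total mixture yield by the density-weighted
#: expectation (the RME route to relative yield gain)
DEFAULT_RME_RESPONSES = (
    ("wheat_yield", "wheat_mono"),
    ("pea_yield", "pea_mono"),
    ("total_yield", "wheat_mono"),
    ("total_yield", "pea_mono"),
    ("yield_gain", "expected"),
    ("protein", "wheat_mono"),
    ("gluten", "wheat_mono"),
    ("water_content", "wheat_mono"),
    ("sedimentation", "wheat_mono"),
    ("hectoliter_weight", "wheat_mono"),
    ("weed_cover", "wheat_mono"),
    ("weed_cover", "pea_mono"),
    ("aungla", "wheat_mono"),
    ("dia", "wheat_mono"),
)


def _mix_value(response, w_mix, p_mix):
    if response == "wheat_yield":
        return w_mix.grain_yield if w_mix else None
    if response == "pea_yield":
        return p_mix.grain_yield if p_mix else None
    if response in ("total_yield", "yield_gain"):
        if w_mix is None or p_mix is None:
            return None
        if w_mix.grain_yield is None or p_mix.grain_yield is None:
            return None
        return w_mix.grain_yield + p_mix.grain_yield
    if response == "weed_cover":
        return _first([w_mix.weed_cover if w_mix else None,
                       p_mix.weed_cover if p_mix else None])
    if response == "aungla":
        return _aungla_or_none(w_mix)
    if response == "dia":
        return _dia_or_none(w_mix)
    return getattr(w_mix, response, None) if w_mix else None


def _baseline_value(response, baseline, w_mono, pea_mono, y_expected):
    if baseline == "expected":
        return y_expected
    rec = w_mono if baseline == "wheat_mono" else pea_mono
    if rec is None:
        return None
    if response in ("wheat_yield", "pea_yield", "total_yield"):
        return rec.grain_yield
    if response == "weed_cover":
        return rec.weed_cover
    if response == "aungla":
        return _aungla_or_none(rec)
    if response == "dia":
        return _dia_or_none(rec)
    return getattr(rec, response, None)


def rme_long_table(records: Iterable[PlotRecord], design: TrialDesign,
                   responses=DEFAULT_RME_RESPONSES) -> pd.DataFrame:
    """Per-plot RMEs in long form: season, block, entry, response, baseline,
    rme.  Zero-baseline plots are skipped with a logged count (the reason RMEs
    are never computed for lodging)."""
    plots = _plot_map(records)
    d1 = design.relative_density[WHEAT]
    d2 = design.relative_density[PEA]
    rows = []
    zero_denominators = 0
    for season in design.seasons:
        for block in range(1, design.n_blocks + 1):
            pea_mono = plots.get((season, block, MONO_PEA, None), {}).get(PEA)
            for entry in design.entry_names:
                w_mono = plots.get((season, block, MONO_WHEAT, entry),
                                   {}).get(WHEAT)
                mix = plots.get((season, block, MIXTURE, entry), {})
                w_mix, p_mix = mix.get(WHEAT), mix.get(PEA)
                y_exp = None
                if (w_mono is not None and pea_mono is not None
                        and w_mono.grain_yield is not None
                        and pea_mono.grain_yield is not None):
                    y_exp = (w_mono.grain_yield * d1
                             + pea_mono.grain_yield * d2)
                for response, baseline in responses:
                    v_mix = _mix_value(response, w_mix, p_mix)
                    v_mon = _baseline_value(response, baseline, w_mono,
                                            pea_mono, y_exp)
                    if v_mix is None or v_mon is None:
                        continue
                    if v_mon == 0:
                        zero_denominators += 1
                        continue
                    rows.append({
                        "season": season, "block": block, "entry": entry,
                        "response": response, "baseline": baseline,
                        "rme": rme(v_mix, v_mon),
                    })
    if zero_denominators:
        logger.info("rme_long_table: skipped %d plot pairs with a zero "
                    "denominator", zero_denominators)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plot frames for the mixed models

#: response -> (species rows used, systems compared)
MODEL_RESPONSES = {
    "wheat_yield": (MONO_WHEAT, MIXTURE),
    "total_yield": (MONO_WHEAT, MIXTURE),
    "protein": (MONO_WHEAT, MIXTURE),
    "gluten": (MONO_WHEAT, MIXTURE),
    "sedimentation": (MONO_WHEAT, MIXTURE),
    "hectoliter_weight": (MONO_WHEAT, MIXTURE),
    "water_content": (MONO_WHEAT, MIXTURE),
    "weed_cover": (MONO_WHEAT, MIXTURE),
    "aungla": (MONO_WHEAT, MIXTURE),
    "dia": (MONO_WHEAT, MIXTURE),
    "hi": (MONO_WHEAT, MIXTURE),
    "dth": (MONO_WHEAT, MIXTURE),
    "tgw": (MONO_WHEAT, MIXTURE),
    "ears_per_m2": (MONO_WHEAT, MIXTURE),
    "kernels_per_ear": (MONO_WHEAT, MIXTURE),
}


def plot_frame(records: Iterable[PlotRecord], response: str,
               season: Optional[str] = None) -> pd.DataFrame:
    """One row per plot with columns season, block, system, entry, mainplot,
    value — the input of the split-plot model for wheat-measured responses."""
    if response not in MODEL_RESPONSES:
        raise KeyError(f"no model extractor for response {response!r}")
    systems = MODEL_RESPONSES[response]
    plots = _plot_map(records)
    rows = []
    for (ssn, block, system, entry), by_species in plots.items():
        if system not in systems or entry is None:
            continue
        if season is not None and ssn != season:
            continue
        w = by_species.get(WHEAT)
        p = by_species.get(PEA)
        if response == "total_yield":
            if system == MIXTURE:
                if (w is None or p is None or w.grain_yield is None
                        or p.grain_yield is None):
                    continue
                value = w.grain_yield + p.grain_yield
            else:
                value = w.grain_yield if w else None
        elif response == "wheat_yield":
            value = w.grain_yield if w else None
        elif response == "weed_cover":
            value = _first([w.weed_cover if w else None,
                            p.weed_cover if p else None])
        elif response == "aungla":
            value = _aungla_or_none(w)
        elif response == "dia":
            value = _dia_or_none(w)
        elif response == "hi":
            value = _hi_or_none(w)
        elif response == "dth":
            value = _dth_or_none(w)
        else:
            value = getattr(w, response, None) if w else None
        if value is None:
            continue
        rows.append({"season": ssn, "block": block, "system": system,
                     "entry": entry,
                     "mainplot": f"{ssn}-b{block}-{system}",
                     "value": float(value)})
    return pd.DataFrame(rows)


def lodging_frame(records: Iterable[PlotRecord],
                  season: Optional[str] = None) -> pd.DataFrame:
    """Plot-level lodging (% of area) across all three systems."""
    plots = _plot_map(records)
    rows = []
    for (ssn, block, system, entry), by_species in plots.items():
        if season is not None and ssn != season:
            continue
        value = _first([r.lodging for r in by_species.values()])
        if value is None:
            continue
        rows.append({"season": ssn, "block": block, "system": system,
                     "entry": entry, "value": float(value)})
    return pd.DataFrame(rows)
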