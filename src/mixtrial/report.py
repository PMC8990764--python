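"""Multifunctional evaluation: service classes, 4C quadrants, quality
promotion.

Relative mixture effects are grouped into four service classes — yield,
resource-use efficiency, crop protection, and wheat grain quality — each
response carrying its CI and effect-present flag.  The 4C view classifies
each wheat entry by whether its partial LER and the accompanying pea partial
LER exceed their relative sowing densities (strict inequality), separating
competition, complementarity, compensation and cooperation regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import Optional

import pandas as pd

from .model import PEA, WHEAT, MixtrialError, TrialDesign
from .indices import QUALITY_CLASSES, quality_class

logger = logging.getLogger(__name__)


class ConfigurationError(MixtrialError):
    pass


#: service class -> responses appearing in the grouped report
DEFAULT_SERVICE_MAP = {
    "yield": ("wheat_yield", "pea_yield", "total_yield"),
    "resource_use_efficiency": ("yield_gain",),
    "crop_protection": ("weed_cover", "aungla", "dia", "lodging"),
    "quality": ("water_content", "protein", "gluten", "hectoliter_weight",
                "sedimentation"),
}

#: reference lines for the yield panel: expected mixture fraction of each
#: pure stand implied by the sowing densities, in %
def expected_yield_fractions(design: TrialDesign) -> dict:
    return {
        "wheat_yield": 100.0 * design.relative_density[WHEAT],
        "pea_yield": 100.0 * design.relative_density[PEA],
    }


def service_report(rme_means: pd.DataFrame,
                   design: TrialDesign,
                   service_map: Optional[dict] = None,
                   lodging_means: Optional[pd.DataFrame] = None
                   ) -> pd.DataFrame:
    """Group fitted RME means into service classes.

    ``rme_means`` is the output of :func:`mixtrial.inference.fit_rme_model`.
    Lodging cannot enter as an RME (zero monoculture denominators); when
    ``lodging_means`` (columns system, estimate) is given it is appended as
    absolute per-system means under crop protection.
    """
    service_map = service_map or DEFAULT_SERVICE_MAP
    lookup = {}
    for klass, responses in service_map.items():
        for resp in responses:
            if resp in lookup:
                raise ConfigurationError(
                    f"response {resp!r} mapped to more than one class"
                )
            lookup[resp] = klass
    fractions = expected_yield_fractions(design)
    rows = []
    for _, rec in rme_means.iterrows():
        resp = rec["response"]
        if resp not in lookup:
            raise ConfigurationError(
                f"response {resp!r} has no service-class mapping"
            )
        rows.append({
            "service_class": lookup[resp],
            "response": resp,
            "baseline": rec.get("baseline"),
            "kind": "rme",
            "estimate": rec["estimate"],
            "lower": rec["lower"],
            "upper": rec["upper"],
            "effect_present": bool(rec["effect_present"]),
            "expected_fraction_pct": fractions.get(resp),
        })
    if lodging_means is not None:
        for _, rec in lodging_means.iterrows():
            rows.append({
                "service_class": "crop_protection",
                "response": "lodging",
                "baseline": rec["system"],
                "kind": "absolute_mean",
                "estimate": rec["estimate"],
                "lower": rec.get("lower"),
                "upper": rec.get("upper"),
                "effect_present": None,
                "expected_fraction_pct": None,
            })
    return pd.DataFrame(rows)


QUADRANTS = ("both_over", "wheat_only", "pea_only", "neither")


@dataclass(frozen=True)
class FourCVerdict:
    entry: str
    pler_wheat: float
    pler_pea: float
    wheat_over: bool
    pea_over: bool
    quadrant: str


def _quadrant(wheat_over: bool, pea_over: bool) -> str:
    if wheat_over and pea_over:
        return "both_over"
    if wheat_over:
        return "wheat_only"
    if pea_over:
        return "pea_only"
    return "neither"


def classify_4c_pair(pler_wheat: float, pler_pea: float,
                     design: TrialDesign, entry: str = "") -> FourCVerdict:
    """4C verdict for one pLER pair; over-yielding is strictly above the
    species' relative sowing density."""
    d_wheat = design.relative_density[WHEAT]
    d_pea = design.relative_density[PEA]
    wheat_over = pler_wheat > d_wheat
    pea_over = pler_pea > d_pea
    return FourCVerdict(entry, pler_wheat, pler_pea, wheat_over, pea_over,
                        _quadrant(wheat_over, pea_over))


def classify_4c(index_table: pd.DataFrame, design: TrialDesign,
                season: Optional[str] = None) -> list[FourCVerdict]:
    """Per-entry 4C verdicts from block-mean pLERs (per season when given)."""
    sub = index_table
    if season is not None:
        sub = sub[sub["season"] == season]
    verdicts = []
    for entry, grp in sub.groupby("entry"):
        pw = grp["pler_wheat"].mean()
        pp = grp["pler_pea"].mean()
        if pd.isna(pw) or pd.isna(pp):
            logger.warning("classify_4c: missing pLER for entry %s — skipped",
                           entry)
            continue
        verdicts.append(classify_4c_pair(float(pw), float(pp), design, entry))
    return verdicts


def quality_promotion(protein_mono: float, protein_mix: float
                      ) -> tuple[str, str, bool]:
    """Quality classes of both systems and whether mixing promoted the entry."""
    class_mono = quality_class(protein_mono)
    class_mix = quality_class(protein_mix)
    promoted = (QUALITY_CLASSES.index(class_mix)
                > QUALITY_CLASSES.index(class_mono))
    return class_mono, class_mix, promoted


def quality_promotion_table(index_table: pd.DataFrame,
                            season: Optional[str] = None) -> pd.DataFrame:
    sub = index_table
    if season is not None:
        sub = sub[sub["season"] == season]
    rows = []
    for entry, grp in sub.groupby("entry"):
        p_mono = grp["protein_mono"].mean()
        p_mix = grp["protein_mix"].mean()
        if pd.isna(p_mono) or pd.isna(p_mix):
            continue
        cm, cx, promoted = quality_promotion(float(p_mono), float(p_mix))
        rows.append({"entry": entry, "protein_mono": p_mono,
                     "protein_mix": p_mix, "class_mono": cm, "class_mix": cx,
                     "promoted": promoted})
    return pd.DataFrame(rows)
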