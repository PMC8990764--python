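"""GGE and genotype-by-trait biplot analysis.

A two-way genotype x environment table of response means is centered by
environment (column) means — removing the environment main effect and
retaining genotype plus genotype-x-environment variation — optionally
column-standardized, and decomposed by SVD.  Singular values are partitioned
between genotype and environment scores (symmetric partitioning by default:
each side carries sqrt(lambda)).  The mean-vs-stability view projects
genotype scores onto the average environment axis (AEA); the orthogonal
distance is the instability measure.

For genotype-by-trait (GT) analysis, trait columns are standardized to unit
variance first, and the cosine of the angle between two trait vectors in the
full-rank score space equals their correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import MIXTURE, MONO_WHEAT, DesignError, InsufficientDataError
from . import indices

logger = logging.getLogger(__name__)


def build_two_way(records, response: str,
                  environments: Sequence[str] = ("season", "system"),
                  design=None) -> pd.DataFrame:
    """Genotype x environment table of block means.

    Environments are labelled ``"season:system"`` (or whatever the requested
    factor combination is).  A missing cell raises unless the caller imputes.
    """
    frame = records if isinstance(records, pd.DataFrame) else \
        indices.plot_frame(records, response)
    frame = frame.copy()
    frame["environment"] = frame[list(environments)].astype(str).agg(
        ":".join, axis=1)
    table = frame.pivot_table(index="entry", columns="environment",
                              values="value", aggfunc="mean")
    if table.isna().any().any():
        missing = [(g, e) for (g, e) in
                   zip(*np.where(table.isna().to_numpy()))]
        raise DesignError(
            f"two-way table has {len(missing)} empty cell(s); supply complete "
            "data or impute explicitly"
        )
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise InsufficientDataError(
            "need at least 2 genotypes and 2 environments"
        )
    return table


@dataclass
class BiplotResult:
    genotype_scores: pd.DataFrame  # rows: genotypes; columns: PC1..PCk
    environment_scores: pd.DataFrame  # rows: environments (or traits)
    singular_values: np.ndarray
    explained: np.ndarray  # % per component, sums to 100
    svp: str
    centering: str
    scaling: str
    centered: pd.DataFrame = field(repr=False, default=None)
    u: np.ndarray = field(repr=False, default=None)
    vt: np.ndarray = field(repr=False, default=None)
    dropped_columns: tuple = ()

    def reconstruct(self) -> pd.DataFrame:
        """Centered/scaled table from all retained components (SVD identity)."""
        m = (self.u * self.singular_values) @ self.vt
        return pd.DataFrame(m, index=self.genotype_scores.index,
                            columns=self.environment_scores.index)


def _sign_fix(u: np.ndarray, vt: np.ndarray):
    """Deterministic orientation: per component, the largest-magnitude
    environment loading is made positive."""
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    return u, vt


def gge_decompose(table: pd.DataFrame, scaling: str = "none",
                  svp: str = "symmetric",
                  drop_constant: bool = False) -> BiplotResult:
    """Environment-centered SVD of a genotype x environment table.

    scaling: "none" (GGE default) or "unit" (column unit variance, GT
    default).  svp: "symmetric" | "genotype" | "environment".
    """
    if table.isna().any().any():
        raise DesignError("missing cells are not supported without imputation")
    work = table.astype(float).copy()
    dropped = ()
    if scaling == "unit":
        sd = work.std(ddof=1)
        constant = sd[sd <= 1e-12].index.tolist()
        if constant:
            if not drop_constant:
                raise DesignError(
                    f"zero-variance column(s): {constant}"
                )
            logger.warning("dropping zero-variance column(s): %s", constant)
            work = work.drop(columns=constant)
            sd = sd.drop(index=constant)
            dropped = tuple(constant)
        work = (work - work.mean()) / sd
    elif scaling == "none":
        work = work - work.mean()
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    if np.allclose(work.to_numpy(), 0.0):
        raise DesignError("table is constant after centering: nothing to "
                          "decompose")

    u, s, vt = np.linalg.svd(work.to_numpy(), full_matrices=False)
    s = np.where(s < 1e-12 * s[0], 0.0, s)  # suppress numerically null axes
    u, vt = _sign_fix(u, vt)
    total = float((s ** 2).sum())
    explained = 100.0 * (s ** 2) / total

    if svp == "symmetric":
        g = u * np.sqrt(s)
        e = vt.T * np.sqrt(s)
    elif svp == "genotype":
        g = u * s
        e = vt.T
    elif svp == "environment":
        g = u
        e = vt.T * s
    else:
        raise ValueError(f"unknown svp mode {svp!r}")

    comps = [f"PC{i + 1}" for i in range(len(s))]
    return BiplotResult(
        genotype_scores=pd.DataFrame(g, index=work.index, columns=comps),
        environment_scores=pd.DataFrame(e, index=work.columns, columns=comps),
        singular_values=s, explained=explained, svp=svp,
        centering="environment", scaling=scaling, centered=work,
        u=u, vt=vt, dropped_columns=dropped,
    )


def mean_vs_stability(result: BiplotResult, n_components: int = 2
                      ) -> pd.DataFrame:
    """Per-genotype mean projection on the AEA and stability distance.

    The AEA is the unit vector toward the average environment score in the
    first ``n_components`` dimensions; the stability distance is the norm of
    the genotype score orthogonal to it (distance along the AEC).
    """
    if result.singular_values.size < 2:
        raise InsufficientDataError("need at least two components")
    g = result.genotype_scores.iloc[:, :n_components].to_numpy()
    e = result.environment_scores.iloc[:, :n_components].to_numpy()
    avg_env = e.mean(axis=0)
    norm = np.linalg.norm(avg_env)
    if norm <= 1e-12:
        raise DesignError("average environment vector has zero length: "
                          "AEA undefined")
    aea = avg_env / norm
    proj = g @ aea
    ortho = g - np.outer(proj, aea)
    stability = np.linalg.norm(ortho, axis=1)
    out = pd.DataFrame({
        "mean_projection": proj,
        "stability_distance": stability,
    }, index=result.genotype_scores.index)
    out["mean_rank"] = out["mean_projection"].rank(ascending=False,
                                                   method="min").astype(int)
    out["stability_rank"] = out["stability_distance"].rank(
        ascending=True, method="min").astype(int)
    return out


def gt_decompose(trait_table: pd.DataFrame,
                 svp: str = "symmetric") -> BiplotResult:
    """Genotype-by-trait decomposition: unit-variance scaling then SVD."""
    return gge_decompose(trait_table, scaling="unit", svp=svp,
                         drop_constant=True)


def trait_cosines(result: BiplotResult,
                  n_components: Optional[int] = None) -> pd.DataFrame:
    """Cosines of trait-vector angles.

    In the full-rank space (default) the cosine between two standardized,
    centered trait columns equals their Pearson correlation; with two retained
    components it is the biplot's visual approximation of it.
    """
    if n_components is None:
        n_components = result.singular_values.size
    # trait geometry lives in V * Sigma regardless of the plotting SVP
    vectors = (result.vt.T * result.singular_values)[:, :n_components]
    norms = np.linalg.norm(vectors, axis=1)
    norms[norms <= 1e-15] = 1.0
    unit = vectors / norms[:, None]
    cos = unit @ unit.T
    labels = result.environment_scores.index
    return pd.DataFrame(np.clip(cos, -1.0, 1.0), index=labels, columns=labels)


def default_environment_table(records, response: str = "wheat_yield"
                              ) -> pd.DataFrame:
    """Entries x (season:system) table over the wheat systems."""
    frame = indices.plot_frame(records, response)
    frame = frame[frame["system"].isin((MONO_WHEAT, MIXTURE))]
    return build_two_way(frame, response)


def genotype_trait_table(index_table: pd.DataFrame, season: str,
                         performance=("ler", "yg_abs", "pler_wheat",
                                      "pler_pea"),
                         traits=("hi_mix", "dth_mix", "protein_mix")
                         ) -> pd.DataFrame:
    """Entry x (performance + trait) means for one season."""
    sub = index_table[index_table["season"] == season]
    cols = [c for c in (*performance, *traits) if c in sub.columns]
    table = sub.groupby("entry")[cols].mean()
    return table.dropna(axis=1, how="all")
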