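"""Split-plot inference: stratum-based mixed models, marginal means,
Holm-corrected contrasts, response-ratio models and robustness verdicts.

The split-plot model is R ~ system*entry + replicate + (1 | replicate:mainplot)
fitted per season.  For balanced complete data the two error strata are
estimated exactly: the main-plot stratum (system x replicate mean square,
df = (a-1)(r-1)) carries system comparisons, the subplot stratum
(df = a(r-1)(b-1)) carries entry and interaction comparisons, and contrasts
spanning both strata get Satterthwaite degrees of freedom.  Under balance this
reproduces the REML solution whenever the main-plot variance component is
interior, and is the classical exact analysis otherwise; statsmodels MixedLM
(REML) is used for unbalanced data.

Entry-level models for yield gain and LER are R ~ entry + (1 | replicate);
their per-entry confidence intervals drive the robustness rule: a mixture
effect is judged robust when the CI excludes 0 (YG, RME) or 1 (LER).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import DesignError, DomainError, MIXTURE, MONO_WHEAT
from . import indices

logger = logging.getLogger(__name__)

_EPS = 1e-12


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm adjustment, input order preserved.

    adj_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) over the ascending order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class MarginalMeans:
    """Model-based cell means with CIs and Holm-adjusted pairwise contrasts."""

    cells: pd.DataFrame  # label columns + estimate, se, df, lower, upper
    contrasts: pd.DataFrame  # contrast, estimate, se, df, t, p_raw, p_holm
    ci_level: float = 0.95
    boundary: bool = False  # a variance component was estimated at zero
    notes: list = field(default_factory=list)


@dataclass(frozen=True)
class RobustnessVerdict:
    """CI-based decision: the metric's CI excludes its null value."""

    metric: str
    entry: Optional[str]
    estimate: float
    lower: float
    upper: float
    null_value: float
    robust: bool

    @classmethod
    def from_ci(cls, metric, entry, estimate, lower, upper, null_value):
        robust = bool(lower > null_value or upper < null_value)
        return cls(metric, entry, float(estimate), float(lower),
                   float(upper), float(null_value), robust)


def _t_ci(estimate, se, df, level):
    if se <= _EPS or df <= 0:
        return estimate, estimate
    q = stats.t.ppf(0.5 + level / 2.0, df)
    return estimate - q * se, estimate + q * se


def _f_pvalue(f, df1, df2):
    if not np.isfinite(f):
        return 0.0
    if df2 <= 0:
        return np.nan
    return float(stats.f.sf(f, df1, df2))


def _safe_f(ms_num, ms_den):
    if ms_den <= _EPS:
        return 0.0 if ms_num <= _EPS else np.inf
    return ms_num / ms_den


class _SplitPlotStrata:
    """Balanced split-plot error strata and contrast variances.

    Cell means are indexed by (system, entry).  A contrast with cell weights
    w has variance (S_m * sigma2_m + S_e * sigma2_e) / r with
    S_m = sum_s (sum_e w_se)^2 and S_e = sum w^2, re-expressed on the two
    mean squares for Satterthwaite df.
    """

    def __init__(self, df: pd.DataFrame):
        self.systems = sorted(df["system"].unique())
        self.entries = sorted(df["entry"].unique())
        self.blocks = sorted(df["block"].unique())
        a, b, r = len(self.systems), len(self.entries), len(self.blocks)
        counts = df.groupby(["system", "entry", "block"])["value"].count()
        if len(counts) != a * b * r or (counts != 1).any():
            raise DesignError("split-plot strata require one observation per "
                              "system x entry x block cell")
        self.a, self.b, self.r = a, b, r
        y = df["value"].to_numpy()
        grand = y.mean()
        sys_m = df.groupby("system")["value"].mean()
        blk_m = df.groupby("block")["value"].mean()
        ent_m = df.groupby("entry")["value"].mean()
        wp_m = df.groupby(["system", "block"])["value"].mean()
        cell_m = df.groupby(["system", "entry"])["value"].mean()

        self.grand = grand
        self.cell_means = cell_m

        ss_total = float(((y - grand) ** 2).sum())
        ss_sys = r * b * float(((sys_m - grand) ** 2).sum())
        ss_blk = a * b * float(((blk_m - grand) ** 2).sum())
        ss_ent = a * r * float(((ent_m - grand) ** 2).sum())
        dev_wp = (wp_m
                  - sys_m.reindex(wp_m.index.get_level_values(0)).to_numpy()
                  - blk_m.reindex(wp_m.index.get_level_values(1)).to_numpy()
                  + grand)
        ss_wp = b * float((dev_wp ** 2).sum())
        dev_int = (cell_m
                   - sys_m.reindex(cell_m.index.get_level_values(0)).to_numpy()
                   - ent_m.reindex(cell_m.index.get_level_values(1)).to_numpy()
                   + grand)
        ss_int = r * float((dev_int ** 2).sum())
        ss_res = ss_total - ss_sys - ss_blk - ss_ent - ss_wp - ss_int
        ss_res = max(ss_res, 0.0)

        self.df_sys, self.df_blk = a - 1, r - 1
        self.df_wp = (a - 1) * (r - 1)
        self.df_ent = b - 1
        self.df_int = (a - 1) * (b - 1)
        self.df_res = a * (r - 1) * (b - 1)
        self.ss = dict(system=ss_sys, replicate=ss_blk, whole_plot_error=ss_wp,
                       entry=ss_ent, interaction=ss_int, residual=ss_res)
        self.ms_wp = ss_wp / self.df_wp if self.df_wp else 0.0
        self.ms_res = ss_res / self.df_res if self.df_res else 0.0
        # variance components (EMS; truncated at zero like REML)
        self.sigma2_e = self.ms_res
        self.sigma2_m = max(0.0, (self.ms_wp - self.ms_res) / b)
        self.boundary = self.ms_wp <= self.ms_res + _EPS

    def effect_table(self) -> pd.DataFrame:
        ms = {k: (v / d if d else np.nan) for (k, v), d in zip(
            self.ss.items(),
            [self.df_sys, self.df_blk, self.df_wp, self.df_ent, self.df_int,
             self.df_res])}
        rows = []
        for term, df_num, df_den, den in (
                ("system", self.df_sys, self.df_wp, self.ms_wp),
                ("replicate", self.df_blk, self.df_wp, self.ms_wp),
                ("entry", self.df_ent, self.df_res, self.ms_res),
                ("system:entry", self.df_int, self.df_res, self.ms_res)):
            f = _safe_f(ms[term] if term != "system:entry" else ms["interaction"],
                        den)
            rows.append({"term": term, "df_num": df_num, "df_den": df_den,
                         "F": f, "p": _f_pvalue(f, df_num, df_den)})
        return pd.DataFrame(rows)

    def contrast_variance(self, weights: dict):
        """(variance, df) of a cell-mean contrast given {(system, entry): w}."""
        s_m = 0.0
        for system in self.systems:
            s_m += sum(w for (s, _), w in weights.items() if s == system) ** 2
        s_e = sum(w * w for w in weights.values())
        c_w = s_m / (self.r * self.b)
        c_s = (s_e - s_m / self.b) / self.r
        c_s = max(c_s, 0.0)
        var = c_w * self.ms_wp + c_s * self.ms_res
        parts = []
        if c_w > _EPS:
            parts.append((c_w * self.ms_wp, self.df_wp))
        if c_s > _EPS:
            parts.append((c_s * self.ms_res, self.df_res))
        if not parts:
            return 0.0, self.df_res
        if len(parts) == 1:
            return var, parts[0][1]
        denom = sum((v ** 2) / d for v, d in parts if d > 0)
        df = (var ** 2) / denom if denom > _EPS else self.df_res
        return var, df

    def cell_variance(self):
        # mean of one (system, entry) cell over blocks
        return self.contrast_variance(
            {(self.systems[0], self.entries[0]): 1.0})


def _season_frame(frame: pd.DataFrame, season: Optional[str]) -> pd.DataFrame:
    seasons = frame["season"].unique()
    if season is None:
        if len(seasons) > 1:
            raise DesignError(
                "records span several seasons; seasons are analysed "
                "separately — pass season explicitly"
            )
        return frame
    out = frame[frame["season"] == season]
    if out.empty:
        raise DesignError(f"no data for season {season!r}")
    return out


def fit_splitplot(records, response: str, season: Optional[str] = None,
                  ci_level: float = 0.95,
                  contrast_family: str = "system_within_entry"):
    """Fit the per-season split-plot model for a wheat-measured response.

    Returns (effect_table, MarginalMeans, components) where components holds
    the estimated variance components and a boundary flag.
    """
    frame = records if isinstance(records, pd.DataFrame) else \
        indices.plot_frame(records, response)
    frame = _season_frame(frame, season)
    if frame["system"].nunique() < 2:
        raise DesignError("both cropping systems must be present")
    if frame["block"].nunique() < 2:
        raise DesignError("at least 2 blocks are required")

    notes = []
    try:
        strata = _SplitPlotStrata(frame)
    except DesignError:
        return _fit_splitplot_mixedlm(frame, ci_level, contrast_family)

    effects = strata.effect_table()
    cell_var, cell_df = strata.cell_variance()
    cell_se = float(np.sqrt(cell_var))
    rows = []
    for (system, entry), est in strata.cell_means.items():
        lo, hi = _t_ci(est, cell_se, cell_df, ci_level)
        rows.append({"system": system, "entry": entry, "estimate": est,
                     "se": cell_se, "df": cell_df, "lower": lo, "upper": hi})
    cells = pd.DataFrame(rows)

    contrasts = _cell_contrasts(strata, contrast_family)
    mm = MarginalMeans(cells=cells, contrasts=contrasts, ci_level=ci_level,
                       boundary=strata.boundary, notes=notes)
    components = {"sigma2_mainplot": strata.sigma2_m,
                  "sigma2_residual": strata.sigma2_e,
                  "ms_wholeplot": strata.ms_wp, "ms_residual": strata.ms_res,
                  "boundary": strata.boundary}
    return effects, mm, components


def _pairs(labels):
    labels = list(labels)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            yield labels[i], labels[j]


def _cell_contrasts(strata: _SplitPlotStrata, family: str) -> pd.DataFrame:
    cells = strata.cell_means
    pairs = []
    if family == "system_within_entry":
        for entry in strata.entries:
            for s1, s2 in _pairs(strata.systems):
                pairs.append(((s1, entry), (s2, entry)))
    elif family == "entry_within_system":
        for system in strata.systems:
            for e1, e2 in _pairs(strata.entries):
                pairs.append(((system, e1), (system, e2)))
    elif family == "all":
        pairs = list(_pairs(list(cells.index)))
    else:
        raise ValueError(f"unknown contrast family {family!r}")
    rows = []
    for c1, c2 in pairs:
        est = float(cells[c1] - cells[c2])
        var, df = strata.contrast_variance({c1: 1.0, c2: -1.0})
        se = float(np.sqrt(var))
        if se <= _EPS:
            t = np.inf if abs(est) > _EPS else 0.0
            p = 0.0 if abs(est) > _EPS else 1.0
        else:
            t = est / se
            p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append({"contrast": f"{c1[0]}:{c1[1]} - {c2[0]}:{c2[1]}",
                     "estimate": est, "se": se, "df": df, "t": t, "p_raw": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def _fit_splitplot_mixedlm(frame, ci_level, contrast_family):
    """Unbalanced fallback: REML via statsmodels MixedLM, Wald inference."""
    import statsmodels.formula.api as smf

    cells_present = frame.groupby(["system", "entry"])["value"].count()
    full = pd.MultiIndex.from_product(
        [sorted(frame["system"].unique()), sorted(frame["entry"].unique())])
    missing = [c for c in full if c not in cells_present.index]
    notes = []
    if missing:
        notes.append(f"unestimable cells (no data): {missing}")
        logger.warning("fit_splitplot: unestimable cells flagged: %s", missing)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(system) * C(entry) + C(block)",
                            data=frame, groups=frame["mainplot"])
        fit = model.fit(reml=True, method="lbfgs")
    sigma2_m = float(np.asarray(fit.cov_re)[0, 0])
    sigma2_e = float(fit.scale)
    df_resid = max(int(len(frame) - fit.k_fe), 1)

    rows = []
    params = fit.params[:fit.k_fe]
    exog_names = model.exog_names
    blocks = sorted(frame["block"].unique())
    for (system, entry), _ in cells_present.items():
        L = _cell_vector(exog_names, system, entry, blocks)
        est = float(L @ params)
        se = float(np.sqrt(L @ fit.cov_params().iloc[:fit.k_fe, :fit.k_fe]
                           @ L))
        lo, hi = _t_ci(est, se, df_resid, ci_level)
        rows.append({"system": system, "entry": entry, "estimate": est,
                     "se": se, "df": df_resid, "lower": lo, "upper": hi})
    cells = pd.DataFrame(rows)

    crows = []
    for (i1, r1) in cells.iterrows():
        for (i2, r2) in cells.iterrows():
            if i2 <= i1:
                continue
            if contrast_family == "system_within_entry" and \
                    r1["entry"] != r2["entry"]:
                continue
            if contrast_family == "entry_within_system" and \
                    r1["system"] != r2["system"]:
                continue
            est = r1["estimate"] - r2["estimate"]
            se = float(np.sqrt(r1["se"] ** 2 + r2["se"] ** 2))  # conservative
            t = est / se if se > _EPS else 0.0
            p = float(2.0 * stats.t.sf(abs(t), df_resid))
            crows.append({
                "contrast": f"{r1['system']}:{r1['entry']} - "
                            f"{r2['system']}:{r2['entry']}",
                "estimate": est, "se": se, "df": df_resid, "t": t,
                "p_raw": p})
    contrasts = pd.DataFrame(crows)
    if not contrasts.empty:
        contrasts["p_holm"] = holm_adjust(contrasts["p_raw"].to_numpy())

    wald = fit.wald_test_terms(scalar=True)
    effects = wald.table.reset_index().rename(
        columns={"index": "term", "statistic": "F", "pvalue": "p",
                 "df_constraint": "df_num"})
    boundary = sigma2_m <= 1e-8 * max(sigma2_e, 1.0)
    mm = MarginalMeans(cells=cells, contrasts=contrasts, ci_level=ci_level,
                       boundary=boundary, notes=notes)
    components = {"sigma2_mainplot": sigma2_m, "sigma2_residual": sigma2_e,
                  "boundary": boundary}
    return effects, mm, components


def _cell_vector(exog_names, system, entry, blocks):
    """Design vector of a (system, entry) cell mean averaged over blocks
    (treatment coding)."""
    L = np.zeros(len(exog_names))
    for i, name in enumerate(exog_names):
        if name == "Intercept":
            L[i] = 1.0
        elif name.startswith("C(system)") and ":" not in name:
            L[i] = 1.0 if f"[T.{system}]" in name else 0.0
        elif name.startswith("C(entry)") and ":" not in name:
            L[i] = 1.0 if f"[T.{entry}]" in name else 0.0
        elif ":" in name and "C(system)" in name:
            L[i] = 1.0 if (f"[T.{system}]" in name
                           and f"[T.{entry}]" in name) else 0.0
        elif name.startswith("C(block)"):
            L[i] = 1.0 / len(blocks)
    return L


# ---------------------------------------------------------------------------
# one-way models with a random replicate effect

class _BlockStrata:
    """Balanced two-way (block x group) layout, block as the random effect."""

    def __init__(self, frame: pd.DataFrame, group: str = "entry"):
        counts = frame.groupby([group, "block"])["value"].count()
        self.k = frame[group].nunique()
        self.r = frame["block"].nunique()
        if len(counts) != self.k * self.r or (counts != 1).any():
            raise DesignError("entry model requires one value per "
                              f"{group} x block cell")
        y = frame["value"].to_numpy()
        grand = y.mean()
        gm = frame.groupby(group)["value"].mean()
        bm = frame.groupby("block")["value"].mean()
        ss_total = float(((y - grand) ** 2).sum())
        ss_g = self.r * float(((gm - grand) ** 2).sum())
        ss_b = self.k * float(((bm - grand) ** 2).sum())
        ss_res = max(ss_total - ss_g - ss_b, 0.0)
        self.df_g, self.df_b = self.k - 1, self.r - 1
        self.df_res = (self.k - 1) * (self.r - 1)
        self.ms_g = ss_g / self.df_g if self.df_g else 0.0
        self.ms_b = ss_b / self.df_b if self.df_b else 0.0
        self.ms_res = ss_res / self.df_res if self.df_res else 0.0
        self.group_means = gm
        self.sigma2_e = self.ms_res
        self.sigma2_b = max(0.0, (self.ms_b - self.ms_res) / self.k)

    def group_mean_variance(self):
        """Variance and Satterthwaite df of one group mean over blocks
        (includes the block component)."""
        c_b = 1.0 / (self.r * self.k)
        c_e = (1.0 - 1.0 / self.k) / self.r
        var = c_b * self.ms_b + c_e * self.ms_res
        parts = [(c_b * self.ms_b, self.df_b), (c_e * self.ms_res,
                                                self.df_res)]
        denom = sum((v ** 2) / d for v, d in parts if d > 0 and v > _EPS)
        df = (var ** 2) / denom if denom > _EPS else self.df_res
        return var, df

    def diff_variance(self):
        return 2.0 * self.ms_res / self.r, self.df_res


def fit_entry_model(index_table: pd.DataFrame, metric: str,
                    season: Optional[str] = None,
                    null_value: Optional[float] = None,
                    ci_level: float = 0.95):
    """Entry model R ~ entry + (1 | replicate) for a per-block metric.

    ``metric`` is a column of the index table ("yg_abs", "ler", ...).  Returns
    (effect_table, MarginalMeans, verdicts).  Blocks where the metric is
    undefined are excluded with a logged count.
    """
    if null_value is None:
        null_value = {"yg_abs": 0.0, "yg_rel": 0.0, "ler": 1.0,
                      "rme_yield_gain": 0.0}.get(metric, 0.0)
    frame = index_table.rename(columns={metric: "value"})[
        ["season", "block", "entry", "value"]].copy()
    frame = _season_frame(frame, season)
    n_missing = int(frame["value"].isna().sum())
    if n_missing:
        logger.info("fit_entry_model(%s): excluded %d undefined block values",
                    metric, n_missing)
        frame = frame.dropna(subset=["value"])
    strata = _BlockStrata(frame, group="entry")

    f = _safe_f(strata.ms_g, strata.ms_res)
    effects = pd.DataFrame([{
        "term": "entry", "df_num": strata.df_g, "df_den": strata.df_res,
        "F": f, "p": _f_pvalue(f, strata.df_g, strata.df_res)}])

    var, df = strata.group_mean_variance()
    se = float(np.sqrt(var))
    rows, verdicts = [], []
    for entry, est in strata.group_means.items():
        lo, hi = _t_ci(est, se, df, ci_level)
        rows.append({"entry": entry, "estimate": est, "se": se, "df": df,
                     "lower": lo, "upper": hi})
        verdicts.append(RobustnessVerdict.from_ci(
            metric.upper(), entry, est, lo, hi, null_value))
    cells = pd.DataFrame(rows)

    dvar, ddf = strata.diff_variance()
    dse = float(np.sqrt(dvar))
    crows = []
    for e1, e2 in _pairs(list(strata.group_means.index)):
        est = float(strata.group_means[e1] - strata.group_means[e2])
        if dse <= _EPS:
            t, p = (np.inf, 0.0) if abs(est) > _EPS else (0.0, 1.0)
        else:
            t = est / dse
            p = float(2.0 * stats.t.sf(abs(t), ddf))
        crows.append({"contrast": f"{e1} - {e2}", "estimate": est, "se": dse,
                      "df": ddf, "t": t, "p_raw": p})
    contrasts = pd.DataFrame(crows)
    if not contrasts.empty:
        contrasts["p_holm"] = holm_adjust(contrasts["p_raw"].to_numpy())
    mm = MarginalMeans(cells=cells, contrasts=contrasts, ci_level=ci_level,
                       boundary=strata.sigma2_b == 0.0)
    return effects, mm, verdicts


def fit_rme_model(rme_long: pd.DataFrame, season: Optional[str] = None,
                  ci_level: float = 0.95) -> pd.DataFrame:
    """Mean RME and CI per response x baseline, RME ~ 1 + (1 | replicate).

    Each response is fitted on its own variance (the weighted-variance
    response-ratio model): the grand-mean variance is MS_between_blocks / n
    with df = r - 1, which collapses to the unweighted one-sample analysis
    when responses are homoscedastic.  The effect-present flag is the CI
    excluding zero.
    """
    frame = _season_frame(rme_long, season)
    rows = []
    for (response, baseline), grp in frame.groupby(["response", "baseline"]):
        values = grp["rme"].to_numpy(dtype=float)
        if values.size == 0:
            logger.warning("fit_rme_model: no values for %s|%s — skipped",
                           response, baseline)
            continue
        n = values.size
        mean = float(values.mean())
        block_means = grp.groupby("block")["rme"].mean()
        r = len(block_means)
        k = n / r
        if r > 1:
            ms_b = float(k * block_means.var(ddof=1))
            var = ms_b / n
            df = r - 1
        else:
            var = float(values.var(ddof=1)) / n if n > 1 else 0.0
            df = max(n - 1, 1)
        se = float(np.sqrt(var))
        lo, hi = _t_ci(mean, se, df, ci_level)
        rows.append({"season": grp["season"].iloc[0], "response": response,
                     "baseline": baseline, "estimate": mean, "se": se,
                     "df": df, "lower": lo, "upper": hi, "n": n,
                     "effect_present": bool(lo > 0 or hi < 0)})
    return pd.DataFrame(rows)


def fit_lodging_glm(records, season: Optional[str] = None,
                    include_entry: bool = False,
                    reference_system: str = MIXTURE) -> pd.DataFrame:
    """Poisson GLM (log link) on plot lodging percentages rounded to integers.

    Returns a rate-ratio table relative to the reference system.  An all-zero
    response yields a degenerate-fit warning and an intercept-only row.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if isinstance(records, pd.DataFrame):
        frame = _season_frame(records, season)
    else:
        frame = indices.lodging_frame(records, season)
    if (frame["value"] < 0).any():
        raise DomainError("lodging percentages must be >= 0")
    frame = frame.copy()
    frame["y"] = frame["value"].round().astype(int)
    if (frame["y"] == 0).all():
        warnings.warn("all lodging counts are zero: degenerate Poisson fit, "
                      "returning intercept-only summary", RuntimeWarning)
        return pd.DataFrame([{"term": "Intercept", "rate": 0.0,
                              "rate_ratio": np.nan, "lower": np.nan,
                              "upper": np.nan, "p": np.nan,
                              "degenerate": True}])
    terms = f"C(system, Treatment('{reference_system}'))"
    if include_entry:
        terms += " + C(entry)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.glm(f"y ~ {terms}", data=frame,
                      family=sm.families.Poisson()).fit()
    ci = fit.conf_int()
    rows = []
    for name in fit.params.index:
        est = fit.params[name]
        lo, hi = ci.loc[name]
        label = name
        if "C(system" in name:
            label = "system:" + name.split("[T.")[-1].rstrip("]")
        elif "C(entry)" in name:
            label = "entry:" + name.split("[T.")[-1].rstrip("]")
        rows.append({"term": label,
                     "rate": float(np.exp(est)) if name == "Intercept" else np.nan,
                     "rate_ratio": float(np.exp(est)) if name != "Intercept" else np.nan,
                     "log_estimate": float(est), "se": float(fit.bse[name]),
                     "lower": float(np.exp(lo)), "upper": float(np.exp(hi)),
                     "p": float(fit.pvalues[name]), "degenerate": False})
    return pd.DataFrame(rows)


def splitplot_system_contrast(records, response: str,
                              season: Optional[str] = None,
                              ci_level: float = 0.95):
    """Marginal mono-vs-mixture difference with its whole-plot CI.

    Convenience accessor used for effect-recovery and coverage checks.
    """
    frame = records if isinstance(records, pd.DataFrame) else \
        indices.plot_frame(records, response)
    frame = _season_frame(frame, season)
    strata = _SplitPlotStrata(frame)
    weights = {}
    for entry in strata.entries:
        weights[(MONO_WHEAT, entry)] = 1.0 / strata.b
        weights[(MIXTURE, entry)] = -1.0 / strata.b
    sys_means = strata.cell_means.groupby(level=0).mean()
    est = float(sys_means[MONO_WHEAT] - sys_means[MIXTURE])
    var, df = strata.contrast_variance(weights)
    se = float(np.sqrt(var))
    lo, hi = _t_ci(est, se, df, ci_level)
    return {"estimate": est, "se": se, "df": df, "lower": lo, "upper": hi}
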