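"""Model skill metrics and the stratified random-sampling ensemble analysis.

Skill between modelled (M) and observed (O) temperatures is summarised by five
standard regression metrics — Mean Bias MB = mean(M-O), Mean Error
ME = mean|M-O|, RMSE, Pearson's R and Willmott's Index of Agreement
d = 1 - sum((M-O)^2) / sum((|M-Obar| + |O-Obar|)^2) — plus normalised
variants (divided by the mean observed temperature).

Because raw metrics confound skill with sample size and average temperature,
ensemble-average scores are computed by a five-stage stratified random
sampling algorithm: (A) keep node-month cells with enough observations,
(B) draw a fixed-size subsample per cell and score it, (C) repeat many times,
(D) summarise each cell by the median score across draws, and (E) average
cell scores across nodes (per month) or across months (per node).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SkillScores",
    "EnsembleScores",
    "ImprovementReport",
    "skill_metrics",
    "stratified_skill",
    "percentage_improvement",
    "correlate_group_summaries",
    "regress_scores_on_depth",
]

ERROR_METRICS = ("mb", "me", "rmse")
BOUNDED_METRICS = ("r", "d")
_METRICS = ("mb", "me", "rmse", "r", "d", "nmb", "nme", "nrmse")


@dataclass(frozen=True)
class SkillScores:
    """Skill metrics for one set of (modelled, observed) pairs.

    Undefined quantities (R under zero variance, normalised metrics when the
    mean observation is zero) are NaN.
    """

    n: int
    m_mean: float
    o_mean: float
    sigma_m: float
    sigma_o: float
    mb: float
    me: float
    rmse: float
    r: float
    d: float
    nmb: float
    nme: float
    nrmse: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n", "m_mean", "o_mean", "sigma_m", "sigma_o") + _METRICS}


def _metrics_matrix(M: np.ndarray, O: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised metrics over the last axis of (..., k) arrays."""
    diff = M - O
    mb = diff.mean(axis=-1)
    me = np.abs(diff).mean(axis=-1)
    rmse = np.sqrt((diff**2).mean(axis=-1))

    Mc = M - M.mean(axis=-1, keepdims=True)
    Oc = O - O.mean(axis=-1, keepdims=True)
    cov = (Mc * Oc).sum(axis=-1)
    var_m = (Mc**2).sum(axis=-1)
    var_o = (Oc**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((var_m > 0) & (var_o > 0), cov / np.sqrt(var_m * var_o), np.nan)
        obar = O.mean(axis=-1)
        denom_d = ((np.abs(M - obar[..., None]) + np.abs(O - obar[..., None])) ** 2).sum(axis=-1)
        d = np.where(denom_d > 0, 1.0 - (diff**2).sum(axis=-1) / denom_d, np.nan)
        # perfect agreement: d = 1 by convention even though the denominator is 0
        d = np.where((denom_d == 0) & ((diff**2).sum(axis=-1) == 0), 1.0, d)
        # d is bounded in [0, 1] by the triangle inequality; clip float residue
        d = np.clip(d, 0.0, 1.0)
        nmb = np.where(obar != 0, mb / obar, np.nan)
        nme = np.where(obar != 0, me / obar, np.nan)
        nrmse = np.where(obar != 0, rmse / obar, np.nan)
    return {"mb": mb, "me": me, "rmse": rmse, "r": r, "d": d,
            "nmb": nmb, "nme": nme, "nrmse": nrmse}


def skill_metrics(modelled, observed) -> SkillScores:
    """Skill metrics for paired modelled/observed values (n >= 1)."""
    M = np.asarray(modelled, dtype=float)
    O = np.asarray(observed, dtype=float)
    if M.shape != O.shape or M.ndim != 1 or M.size < 1:
        raise ValueError("modelled and observed must be 1-d arrays of equal length >= 1")
    m = _metrics_matrix(M, O)
    return SkillScores(
        n=M.size,
        m_mean=float(M.mean()),
        o_mean=float(O.mean()),
        sigma_m=float(M.std(ddof=1)) if M.size > 1 else np.nan,
        sigma_o=float(O.std(ddof=1)) if O.size > 1 else np.nan,
        **{k: float(m[k]) for k in _METRICS},
    )


@dataclass
class EnsembleScores:
    """Output of the stratified sampling algorithm.

    ``per_cell`` has one row per qualifying (node, year, month) cell with the
    median score per metric; ``per_stratum`` averages cells within each
    stratum value (month or node); ``ensemble`` is the grand mean across
    strata.  Undefined metric values (NaN) are excluded from medians and
    means, with the exclusion count recorded.
    """

    stratum: str
    per_cell: pd.DataFrame
    per_stratum: pd.DataFrame
    ensemble: dict[str, float]
    n_min: float
    n_sample: int
    n_sim: int
    seed: int
    n_undefined: int = 0


def stratified_skill(
    validation: pd.DataFrame,
    stratum: str = "month",
    floor: int = 5,
    n_sample: int = 5,
    n_sim: int = 1000,
    seed: int = 0,
) -> EnsembleScores:
    """Five-stage stratified random-sampling ensemble skill scores.

    Cells are (node, year, month) groups; a cell qualifies if its size is at
    least ``max(floor, 25th percentile of cell sizes)``.  Within each cell,
    ``n_sample`` rows are drawn without replacement ``n_sim`` times, metrics
    are computed per draw, and the cell is summarised by the per-metric median
    across draws.  ``stratum='month'`` then averages cells across nodes within
    each year-month; ``stratum='node'`` averages across months within each
    node.  Fully reproducible under ``seed``.
    """
    if stratum not in ("month", "node"):
        raise ValueError("stratum must be 'month' or 'node'")
    sizes = validation.groupby(["node_id", "year", "month"]).size()
    n_min = max(float(floor), float(np.percentile(sizes.values, 25)))
    qualifying = sizes[sizes >= n_min]
    if qualifying.empty:
        raise ValueError(
            f"no (node, month) cells meet the threshold n >= {n_min:g}; "
            f"largest cell has {int(sizes.max())} rows"
        )

    rng = np.random.default_rng(seed)
    rows = []
    n_undefined = 0
    grouped = validation.groupby(["node_id", "year", "month"], sort=True)
    for key, cell in grouped:
        n = len(cell)
        if n < n_min:
            continue
        M = cell["mod_temp"].to_numpy()
        O = cell["obs_temp"].to_numpy()
        if n == n_sample:
            draws = np.tile(np.arange(n), (n_sim, 1))
        else:
            draws = np.argsort(rng.random((n_sim, n)), axis=1)[:, :n_sample]
        m = _metrics_matrix(M[draws], O[draws])
        row = {"node_id": key[0], "year": key[1], "month": key[2], "n": n}
        for name in _METRICS:
            vals = m[name]
            bad = int(np.isnan(vals).sum())
            n_undefined += bad
            row[name] = float(np.nanmedian(vals)) if bad < len(vals) else np.nan
        rows.append(row)
    per_cell = pd.DataFrame(rows)

    group_cols = ["year", "month"] if stratum == "month" else ["node_id"]
    per_stratum = per_cell.groupby(group_cols)[list(_METRICS)].mean().reset_index()
    per_stratum["n_cells"] = per_cell.groupby(group_cols).size().values
    ensemble = {name: float(per_stratum[name].mean()) for name in _METRICS}
    return EnsembleScores(
        stratum=stratum,
        per_cell=per_cell,
        per_stratum=per_stratum,
        ensemble=ensemble,
        n_min=n_min,
        n_sample=n_sample,
        n_sim=n_sim,
        seed=seed,
        n_undefined=n_undefined,
    )


@dataclass
class ImprovementReport:
    """Percentage improvement in ensemble-average skill between two periods."""

    per_month: pd.DataFrame  # one row per month-of-year, one column per metric
    mean_p: dict[str, float]
    error_formula: str
    bounded_formula: str
    excluded: list = field(default_factory=list)


def percentage_improvement(
    ens_baseline: EnsembleScores,
    ens_update: EnsembleScores,
    months: tuple[int, ...] = (3, 4, 5),
    metrics: tuple[str, ...] = ERROR_METRICS + BOUNDED_METRICS,
) -> ImprovementReport:
    """Per-month and mean percentage improvement P between two monthly ensembles.

    Error-type metrics (MB, ME, RMSE) use the signed reduction relative to the
    baseline magnitude, P = 100 * (|b| - u * sign(b)) / |b|, so an update that
    overshoots past zero scores above 100%.  Bounded agreement metrics (R, d)
    use the fraction of the remaining headroom closed,
    P = 100 * (u - b) / (1 - b).  Months with an undefined formula (baseline
    score 0, or baseline agreement 1) are excluded from the mean and listed.
    """
    if ens_baseline.stratum != "month" or ens_update.stratum != "month":
        raise ValueError("improvement requires month-stratified ensembles")

    def month_scores(ens: EnsembleScores, m: int) -> pd.Series:
        rows = ens.per_stratum[ens.per_stratum["month"] == m]
        if len(rows) != 1:
            raise ValueError(f"month {m} not uniquely present in ensemble "
                             f"({len(rows)} rows); pass a single-year ensemble")
        return rows.iloc[0]

    excluded = []
    records = []
    for m in months:
        b_row, u_row = month_scores(ens_baseline, m), month_scores(ens_update, m)
        rec = {"month": m}
        for name in metrics:
            b, u = float(b_row[name]), float(u_row[name])
            if name in ERROR_METRICS:
                if b == 0 or not np.isfinite(b):
                    excluded.append((m, name, "zero or undefined baseline"))
                    rec[name] = np.nan
                else:
                    rec[name] = 100.0 * (abs(b) - u * np.sign(b)) / abs(b)
            else:
                if b == 1 or not np.isfinite(b) or not np.isfinite(u):
                    excluded.append((m, name, "no headroom or undefined baseline"))
                    rec[name] = np.nan
                else:
                    rec[name] = 100.0 * (u - b) / (1.0 - b)
        records.append(rec)
    per_month = pd.DataFrame(records)
    mean_p = {name: float(per_month[name].mean()) for name in metrics}
    return ImprovementReport(
        per_month=per_month,
        mean_p=mean_p,
        error_formula="100*(|base| - update*sign(base))/|base|",
        bounded_formula="100*(update - base)/(1 - base)",
        excluded=excluded,
    )


def correlate_group_summaries(validation: pd.DataFrame, stratum: str = "node") -> pd.DataFrame:
    """Correlations of group size and mean temperature with raw group skill.

    Groups are nodes or year-months; per group, MB/ME/RMSE are computed
    directly (no subsampling) and correlated across groups with the group's
    number of observations and mean observed temperature.
    """
    keys = ["node_id"] if stratum == "node" else ["year", "month"]
    groups = validation.groupby(keys)
    if groups.ngroups < 3:
        raise ValueError("need at least 3 groups for a correlation analysis")
    summary = groups.apply(
        lambda g: pd.Series(
            {
                "n": len(g),
                "mean_obs": g["obs_temp"].mean(),
                "mb": (g["mod_temp"] - g["obs_temp"]).mean(),
                "me": (g["mod_temp"] - g["obs_temp"]).abs().mean(),
                "rmse": np.sqrt(((g["mod_temp"] - g["obs_temp"]) ** 2).mean()),
            }
        ),
        include_groups=False,
    )
    rows = []
    for predictor in ("n", "mean_obs"):
        for metric in ERROR_METRICS:
            x, y = summary[predictor].values, summary[metric].values
            if np.std(x) == 0 or np.std(y) == 0:
                r = np.nan  # degenerate: constant across groups
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"predictor": predictor, "metric": metric,
                         "r": r, "n_groups": len(summary)})
    return pd.DataFrame(rows)


def regress_scores_on_depth(per_node: pd.DataFrame, depths: pd.Series | dict) -> pd.DataFrame:
    """OLS of per-node ensemble-average scores on node depth, per metric.

    ``per_node`` is an ``EnsembleScores.per_stratum`` frame with a ``node_id``
    column; ``depths`` maps node id to depth (m).
    """
    if len(per_node) < 3:
        raise ValueError("need at least 3 nodes with scores")
    depth = per_node["node_id"].map(dict(depths) if not isinstance(depths, dict) else depths)
    depth = depth.astype(float)
    if depth.nunique() < 2:
        raise ValueError("depth is constant across nodes; regression undefined")
    rows = []
    for name in _METRICS:
        if name not in per_node:
            continue
        y = per_node[name].astype(float)
        ok = np.isfinite(y)
        fit = stats.linregress(depth[ok], y[ok])
        rows.append({"metric": name, "slope": fit.slope, "intercept": fit.intercept,
                     "r": fit.rvalue, "p": fit.pvalue, "stderr": fit.stderr})
    return pd.DataFrame(rows)
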