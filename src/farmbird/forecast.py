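"""Forecast decomposition and guild-level summaries.

Predicted abundance changes are expressed as the symmetric change

    (RA_future - RA_current) / ((RA_current + RA_future) / 2),

bounded in [-2, 2] (-2 = extinction, +2 = appearance), decomposed by driver
combination (climate, farmland area, farmland cover, and their unions) by
toggling only the drivers of interest to their future values, and
aggregated across regions with weights area / n_points so that densely and
sparsely surveyed regions contribute comparably. Species are classified into
grassland / cropland / mixed guilds by the grassland specialization index
SSIg (abundance-weighted mean of sub-habitat coefficients 4, 3, 2, 1), and
guild responses are compared with weighted one-sample t-tests and Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import ModelFit, predict_abundance
from .synthetic import CROPS

__all__ = [
    "DRIVER_GROUPS",
    "DEFAULT_COMBOS",
    "DriverCombination",
    "symmetric_change",
    "region_weight",
    "weighted_mean_sd",
    "cochran_sem",
    "compute_ssig",
    "classify_main_habitat",
    "one_sample_t",
    "tukey_hsd",
    "driver_decomposition",
]

#: Covariate columns toggled by each driver.
DRIVER_GROUPS: dict[str, tuple[str, ...]] = {
    "climate": ("suitability",),
    "land_use": ("farmland_prop",),
    "farmland_cover": CROPS,
}


@dataclass(frozen=True)
class DriverCombination:
    """A named subset of drivers set to their future values."""

    name: str
    drivers: frozenset[str]

    def __post_init__(self):
        unknown = self.drivers - set(DRIVER_GROUPS)
        if unknown:
            raise ValueError(f"unknown drivers in combination {self.name!r}: {sorted(unknown)}")

    def toggled_columns(self) -> list[str]:
        return [c for d in sorted(self.drivers) for c in DRIVER_GROUPS[d]]


DEFAULT_COMBOS: tuple[DriverCombination, ...] = (
    DriverCombination("climate_only", frozenset({"climate"})),
    DriverCombination("land_use_only", frozenset({"land_use"})),
    DriverCombination("farmland_cover_only", frozenset({"farmland_cover"})),
    DriverCombination("land_use_plus_cover", frozenset({"land_use", "farmland_cover"})),
    DriverCombination("all_drivers", frozenset({"climate", "land_use", "farmland_cover"})),
)


def symmetric_change(ra_current, ra_future):
    """Symmetric relative change of regional abundance.

    ``(fut - cur) / ((cur + fut) / 2)``: bounded in [-2, 2], antisymmetric
    under swapping the arguments. The (0, 0) pair — species absent before
    and after — is defined as 0.
    """
    cur = np.asarray(ra_current, dtype=float)
    fut = np.asarray(ra_future, dtype=float)
    if (cur < 0).any() or (fut < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = 0.5 * (cur + fut)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (fut - cur) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def region_weight(area, n_points):
    """Aggregation weight of a region: area / number of count points."""
    area = np.asarray(area, dtype=float)
    n_points = np.asarray(n_points, dtype=float)
    if (area <= 0).any():
        raise ValueError("area must be > 0")
    if (n_points < 1).any():
        raise ValueError("n_points must be >= 1")
    out = area / n_points
    return float(out) if out.ndim == 0 else out


def _check_weights(values, weights):
    x = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
    if len(x) == 0:
        raise ValueError("empty input")
    if x.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if (w <= 0).any():
        raise ValueError("weights must be > 0")
    return x, w


def cochran_sem(values, weights) -> float:
    """Standard error of the weighted mean, ratio-estimator form (Cochran).

    With n values x_i, weights w_i, mean weight wbar and weighted mean xw,

        SEM^2 = n / ((n-1) (n wbar)^2) * [ sum (w_i x_i - wbar xw)^2
                - 2 xw sum (w_i - wbar)(w_i x_i - wbar xw)
                + xw^2 sum (w_i - wbar)^2 ],

    the variance of a ratio estimator with random weights; it reduces to the
    usual s / sqrt(n) when all weights are equal.
    """
    x, w = _check_weights(values, weights)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    wbar = w.mean()
    xw = float((w * x).sum() / w.sum())
    a = w * x - wbar * xw
    b = w - wbar
    var = (n / ((n - 1) * (n * wbar) ** 2)) * float((a**2).sum() - 2 * xw * (b * a).sum() + xw**2 * (b**2).sum())
    return float(np.sqrt(max(var, 0.0)))


def weighted_mean_sd(values, weights=None) -> tuple[float, float]:
    """Weighted mean and its Cochran SD.

    The mean is ``sum(w x) / sum(w)``; the SD is the per-observation spread
    implied by the Cochran ratio-estimator SEM, ``SEM * sqrt(n_eff)`` with
    Kish's effective sample size ``n_eff = (sum w)^2 / sum w^2`` (equal to
    ``s`` for equal weights).
    """
    x, w = _check_weights(values, weights)
    mean = float((w * x).sum() / w.sum())
    if len(x) < 2:
        return mean, 0.0
    n_eff = float(w.sum() ** 2 / (w**2).sum())
    return mean, cochran_sem(x, w) * np.sqrt(n_eff)


def compute_ssig(abundance_by_subhabitat) -> float:
    """Grassland specialization index.

    Abundance-weighted mean of the sub-habitat coefficients 4 (unimproved
    grassland), 3 (improved grassland), 2 (mixed grass/crop) and 1
    (cropland); ranges from 1 (pure cropland species) to 4 (pure unimproved
    grassland species).
    """
    a = np.asarray(abundance_by_subhabitat, dtype=float)
    if a.shape != (4,):
        raise ValueError("expected four sub-habitat abundances")
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    if a.sum() == 0:
        raise ValueError("SSIg undefined for an all-zero abundance profile")
    coef = np.array([4.0, 3.0, 2.0, 1.0])
    return float((a * coef).sum() / a.sum())


def classify_main_habitat(ssig: float) -> str:
    """Guild from SSIg: > 2.2 grassland, < 1.8 cropland, else mixed."""
    if not (1.0 <= ssig <= 4.0):
        raise ValueError(f"SSIg must lie in [1, 4], got {ssig}")
    if ssig > 2.2:
        return "grassland"
    if ssig < 1.8:
        return "cropland"
    return "mixed"


def one_sample_t(values, weights=None, mu: float = 0.0) -> tuple[float, float]:
    """Weighted one-sample t-test of the mean against ``mu``.

    Uses the Cochran SD and Kish's effective sample size
    ``n_eff = (sum w)^2 / sum w^2``; with equal weights this is the textbook
    one-sample t-test. Zero spread returns an infinite t (sign of the mean
    shift) with p = 0.
    """
    x, w = _check_weights(values, weights)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    mean, sd = weighted_mean_sd(x, w)
    n_eff = float(w.sum() ** 2 / (w**2).sum())
    if sd == 0:
        if mean == mu:
            return 0.0, 1.0
        return float(np.sign(mean - mu) * np.inf), 0.0
    t = (mean - mu) / (sd / np.sqrt(n_eff))
    p = 2.0 * stats.t.sf(abs(t), df=n_eff - 1)
    return float(t), float(p)


def tukey_hsd(
    group_values: Mapping[str, Sequence[float]] | Sequence[float],
    group_labels: Sequence | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise group comparisons by Tukey's HSD (Tukey-Kramer).

    Accepts either a mapping group -> values or a flat value array plus
    ``group_labels``. Returns one row per pair with columns group1, group2,
    diff, lower, upper, p_adj: mean differences with studentized-range
    confidence intervals and single-step adjusted p-values, using the pooled
    within-group variance.
    """
    if group_labels is not None:
        s = pd.Series(np.asarray(group_values, dtype=float), index=list(group_labels))
        group_values = {g: s.loc[[g]].to_numpy() for g in sorted(set(group_labels))}
    groups = {k: np.asarray(v, dtype=float) for k, v in group_values.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")
    k = len(groups)
    ns = {g: len(v) for g, v in groups.items()}
    df = sum(ns.values()) - k
    s2 = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df
    q_crit = stats.studentized_range.ppf(1 - alpha, k, df)
    rows = []
    names = list(groups)
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = names[i], names[j]
            diff = float(groups[g2].mean() - groups[g1].mean())
            se = np.sqrt(s2 * 0.5 * (1.0 / ns[g1] + 1.0 / ns[g2]))
            half = q_crit * se
            q_obs = abs(diff) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q_obs, k, df))
            rows.append((g1, g2, diff, diff - half, diff + half, min(max(p, 0.0), 1.0)))
    return pd.DataFrame(rows, columns=["group1", "group2", "diff", "lower", "upper", "p_adj"])


def driver_decomposition(
    fit: ModelFit,
    current_covariates: pd.DataFrame,
    future_covariates: pd.DataFrame,
    combos: Sequence[DriverCombination] = DEFAULT_COMBOS,
    weights=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region symmetric changes under each driver combination.

    ``current_covariates`` and ``future_covariates`` are row-aligned frames
    holding current and projected covariate values (suitability, farmland
    proportion, crop shares; effort always stays current). For each
    combination only the toggled columns take future values, current and
    future abundances are predicted (region intercepts at conditional modes,
    year at population level), and symmetric changes are computed.

    Returns (changes, summary): per region x combo changes with weights, and
    per-combo weighted mean, Cochran SD, t and p against 0.
    """
    if len(current_covariates) != len(future_covariates):
        raise ValueError("current and future covariate tables must align row-wise")
    cur = current_covariates.reset_index(drop=True)
    fut = future_covariates.reset_index(drop=True)
    if weights is None:
        w = np.ones(len(cur))
    else:
        w = np.asarray(weights, dtype=float)
    ra_cur = predict_abundance(fit, cur)

    change_rows = []
    summary_rows = []
    for combo in combos:
        toggled = combo.toggled_columns()
        missing = [c for c in toggled if c not in fut.columns]
        if missing:
            raise ValueError(f"combination {combo.name!r} toggles missing columns: {missing}")
        scenario_cov = cur.copy()
        for c in toggled:
            if c in fit.covariates:
                scenario_cov[c] = fut[c].to_numpy()
        ra_fut = predict_abundance(fit, scenario_cov)
        change = symmetric_change(ra_cur, ra_fut)
        for i in range(len(cur)):
            region = cur["region_id"].iloc[i] if "region_id" in cur.columns else i
            change_rows.append((combo.name, region, float(change[i]), float(w[i])))
        mean, sd = weighted_mean_sd(change, w)
        if len(change) >= 2 and np.ptp(change) > 0:
            t, p = one_sample_t(change, w)
        else:
            t, p = np.nan, np.nan
        summary_rows.append((combo.name, mean, sd, t, p))
    changes = pd.DataFrame(change_rows, columns=["combo", "region_id", "change", "weight"])
    summary = pd.DataFrame(summary_rows, columns=["combo", "mean", "sd", "t", "p"])
    return changes, summary
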