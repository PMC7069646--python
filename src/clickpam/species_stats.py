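"""Descriptive statistics and nonparametric species comparisons.

Click parameters are heavy-tailed and heteroscedastic, so each parameter
is summarized per species by its median with 5th and 95th percentiles,
and species are compared with two-sided Mann-Whitney U tests.  Normality
(Kolmogorov-Smirnov against a fitted normal), variance homogeneity
(Levene) and log-normality checks document why the nonparametric route
is taken.  Note the KS test here uses fitted parameters, which makes it
anti-conservative (the Lilliefors issue); it is retained as a
descriptive screen, not a calibrated test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_extraction import PARAMS

__all__ = [
    "ParameterSummary",
    "MannWhitneyResult",
    "DistributionChecks",
    "summarize",
    "compare_species",
    "compare_all",
    "distribution_checks",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ParameterSummary:
    parameter: str
    species: str
    median: float
    p5: float
    p95: float
    n: int


@dataclass(frozen=True)
class MannWhitneyResult:
    parameter: str
    u_statistic: float
    p_value: float
    method: str

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class DistributionChecks:
    parameter: str
    ks_p: dict[str, float]       # species -> KS p against fitted normal
    log_ks_p: dict[str, float]   # species -> KS p on log-transformed data
    levene_p: float
    lognormal_ok: bool           # every species passes KS on the log scale


def summarize(
    features: pd.DataFrame, parameters: list[str] | None = None
) -> pd.DataFrame:
    """Median and 5th/95th percentiles per species and parameter.

    Percentiles use linear interpolation between order statistics.
    Returns a tidy frame with columns parameter, species, median, p5,
    p95, n.
    """
    if features.empty:
        raise ValueError("empty feature table")
    if "species" not in features:
        raise ValueError("feature table lacks a species column")
    parameters = parameters or [p for p in PARAMS if p in features.columns]
    rows = []
    for species, grp in features.groupby("species", sort=True):
        for param in parameters:
            vals = grp[param].to_numpy(dtype=float)
            rows.append(
                ParameterSummary(
                    parameter=param,
                    species=str(species),
                    median=float(np.median(vals)),
                    p5=float(np.quantile(vals, 0.05)),
                    p95=float(np.quantile(vals, 0.95)),
                    n=vals.size,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def _two_groups(features: pd.DataFrame, parameter: str) -> tuple[np.ndarray, np.ndarray]:
    species = sorted(features["species"].unique())
    if len(species) != 2:
        raise ValueError(f"expected exactly 2 species, found {species}")
    a = features.loc[features["species"] == species[0], parameter].to_numpy(dtype=float)
    b = features.loc[features["species"] == species[1], parameter].to_numpy(dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("need at least 3 observations per species")
    return a, b


def compare_species(features: pd.DataFrame, parameter: str) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test between the two species.

    Exact enumeration of the U null distribution when both samples hold
    at most 20 untied observations; otherwise the normal approximation
    with tie correction.
    """
    a, b = _two_groups(features, parameter)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(parameter, float(res.statistic), float(res.pvalue), method)


def compare_all(features: pd.DataFrame, parameters: list[str] | None = None) -> pd.DataFrame:
    """Mann-Whitney comparison of every parameter; tidy result frame."""
    parameters = parameters or [p for p in PARAMS if p in features.columns]
    rows = [compare_species(features, p) for p in parameters]
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "u_statistic": [r.u_statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
            "method": [r.method for r in rows],
        }
    )


def distribution_checks(features: pd.DataFrame, parameter: str) -> DistributionChecks:
    """Normality, equal-variance and log-normality screens for one parameter."""
    groups = {
        str(s): g[parameter].to_numpy(dtype=float)
        for s, g in features.groupby("species", sort=True)
    }
    for s, v in groups.items():
        if v.size < 8:
            raise ValueError(f"species {s}: need n >= 8 for distribution checks")
    ks_p = {}
    log_ks_p = {}
    for s, v in groups.items():
        ks_p[s] = float(stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1))).pvalue)
        if np.all(v > 0):
            lv = np.log(v)
            log_ks_p[s] = float(stats.kstest(lv, "norm", args=(lv.mean(), lv.std(ddof=1))).pvalue)
        else:  # non-positive values: a log transform is undefined
            log_ks_p[s] = float("nan")
    levene_p = float(stats.levene(*groups.values()).pvalue)
    lognormal_ok = all(p > ALPHA for p in log_ks_p.values())
    return DistributionChecks(parameter, ks_p, log_ks_p, levene_p, lognormal_ok)
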