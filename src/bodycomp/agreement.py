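"""Method-comparison statistics for paired body-composition estimates.

The battery applied to each method against the 4-C reference: Pearson
correlation with Fisher-z confidence interval, Lin's concordance
correlation coefficient with the Lin (1989) Z-transform interval, ordinary
least-squares calibration regression (method on reference), paired t-test,
and Bland-Altman agreement (bias, SD of differences, limits of agreement)
with a proportional-bias regression of differences on pair averages.

Difference direction is fixed as method minus reference throughout. The
default LOA multiplier is 2.0 (the +/-2 SD convention); 1.96 is available
via argument. CCC uses population (1/n) moments per Lin's original
definition. Regression confidence intervals use t quantiles with n-2
degrees of freedom. No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AgeGroup, Method, PairedSeries, age_group_of


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class CccResult:
    ccc: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_ci: tuple
    intercept_ci: tuple
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    averages: tuple
    differences: tuple
    multiplier: float


@dataclass(frozen=True)
class PropBiasResult:
    slope: float
    intercept: float
    p_value: float


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    flag: str = ""


def _check_n(pairs: PairedSeries, minimum: int) -> tuple:
    if pairs.n < minimum:
        raise ValueError(f"need at least {minimum} pairs, got {pairs.n}")
    return np.asarray(pairs.method_values), np.asarray(pairs.reference_values)


def pearson_r_ci(pairs: PairedSeries, alpha: float = 0.05) -> PearsonResult:
    """Sample Pearson r with a Fisher-z interval (SE = 1/sqrt(n-3))."""
    x, y = _check_n(pairs, 3)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate series: zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    n = pairs.n
    if n > 3 and abs(r) < 1:
        z = math.atanh(r)
        half = stats.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
    else:
        lo = hi = r
    return PearsonResult(r=r, ci_low=lo, ci_high=hi, n=n)


def lins_ccc_ci(pairs: PairedSeries, alpha: float = 0.05) -> CccResult:
    """Lin's concordance correlation coefficient with Z-transform CI.

    ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), population (1/n)
    moments. The CI uses Lin's (1989) large-sample variance of atanh(ccc).
    """
    x, y = _check_n(pairs, 3)
    n = pairs.n
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("degenerate: both series constant and equal")
    ccc = 2 * sxy / denom
    if sx2 == 0 or sy2 == 0 or abs(ccc) >= 1:
        return CccResult(ccc=ccc, ci_low=ccc, ci_high=ccc, n=n)
    r = sxy / math.sqrt(sx2 * sy2)
    if r == 0:
        return CccResult(ccc=ccc, ci_low=ccc, ci_high=ccc, n=n)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    z = math.atanh(ccc)
    var_z = (
        (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - ccc**2) ** 2)
        - ccc**4 * u**4 / (2 * r**2 * (1 - ccc**2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    half = stats.norm.ppf(1 - alpha / 2) * math.sqrt(var_z)
    return CccResult(ccc=ccc, ci_low=math.tanh(z - half), ci_high=math.tanh(z + half), n=n)


def simple_linear_regression(pairs: PairedSeries, alpha: float = 0.05) -> RegressionResult:
    """OLS of the method (response) on the reference (predictor), t-based CIs."""
    y, x = _check_n(pairs, 3)  # method is the response
    if np.std(x) == 0:
        raise ValueError("degenerate predictor: reference has zero variance")
    fit = stats.linregress(x, y)
    n = pairs.n
    tq = stats.t.ppf(1 - alpha / 2, n - 2) if n > 2 else float("nan")
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_ci=(fit.slope - tq * fit.stderr, fit.slope + tq * fit.stderr),
        intercept_ci=(
            fit.intercept - tq * fit.intercept_stderr,
            fit.intercept + tq * fit.intercept_stderr,
        ),
        n=n,
    )


def bland_altman(pairs: PairedSeries, loa_multiplier: float = 2.0) -> BlandAltmanResult:
    """Bland-Altman agreement: bias, SD of differences, limits of agreement.

    differences = method - reference; bias = mean difference; SD uses n-1;
    LOA = bias +/- multiplier*SD. The per-pair (average, difference) points
    are returned for plotting.
    """
    x, y = _check_n(pairs, 3)
    diffs = x - y
    avgs = (x + y) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        averages=tuple(avgs),
        differences=tuple(diffs),
        multiplier=loa_multiplier,
    )


def proportional_bias(pairs: PairedSeries) -> PropBiasResult:
    """OLS of (method - reference) on the pair average, with slope p-value.

    With differences defined method - reference, a negative slope means the
    method increasingly over-reads at low values / under-reads at high
    values of the measured quantity.
    """
    x, y = _check_n(pairs, 3)
    diffs = x - y
    avgs = (x + y) / 2.0
    if np.std(avgs) == 0:
        raise ValueError("degenerate: pair averages have zero variance")
    fit = stats.linregress(avgs, diffs)
    return PropBiasResult(slope=float(fit.slope), intercept=float(fit.intercept),
                          p_value=float(fit.pvalue))


def paired_t_test(pairs: PairedSeries) -> PairedTResult:
    """Classical paired t-test, df = n-1, two-sided p.

    Zero-variance differences are special-cased: identical series give
    t = 0, p = 1; a constant nonzero difference cannot produce a finite t
    and is reported with p = 0.0 and flag ``constant-difference``.
    """
    x, y = _check_n(pairs, 2)
    diffs = x - y
    n = pairs.n
    if float(diffs.std(ddof=1)) == 0.0:
        if float(diffs.mean()) == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0)
        return PairedTResult(t=math.inf if diffs.mean() > 0 else -math.inf,
                             df=n - 1, p=0.0, flag="constant-difference")
    res = stats.ttest_rel(x, y)
    return PairedTResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


def sample_size_for_correlation(rho: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Participants needed to detect correlation rho against a zero null.

    n = ceil( ((z_{1-alpha/2} + z_{power}) / atanh(rho))^2 + 3 )
    """
    if not (0 < rho < 1):
        raise ValueError("rho must be in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    return math.ceil(((za + zb) / math.atanh(rho)) ** 2 + 3)


# ---------------------------------------------------------------------------
# Table assembly

COMPARISON_COLUMNS = [
    "method", "group", "n_pairs",
    "pearson_r", "pearson_ci_low", "pearson_ci_high",
    "slope", "slope_ci_low", "slope_ci_high",
    "intercept", "intercept_ci_low", "intercept_ci_high",
    "ccc", "ccc_ci_low", "ccc_ci_high",
    "bias", "sd", "loa_low", "loa_high",
    "prop_bias_slope", "prop_bias_intercept", "prop_bias_p",
    "paired_t", "paired_t_df", "paired_t_p",
    "flags",
]


def comparison_row(pairs: PairedSeries, loa_multiplier: float = 2.0,
                   alpha: float = 0.05) -> dict:
    """One full battery of agreement statistics for one method/group cell."""
    pr = pearson_r_ci(pairs, alpha)
    cc = lins_ccc_ci(pairs, alpha)
    reg = simple_linear_regression(pairs, alpha)
    ba = bland_altman(pairs, loa_multiplier)
    pb = proportional_bias(pairs)
    tt = paired_t_test(pairs)
    return {
        "n_pairs": pairs.n,
        "pearson_r": pr.r, "pearson_ci_low": pr.ci_low, "pearson_ci_high": pr.ci_high,
        "slope": reg.slope, "slope_ci_low": reg.slope_ci[0], "slope_ci_high": reg.slope_ci[1],
        "intercept": reg.intercept,
        "intercept_ci_low": reg.intercept_ci[0], "intercept_ci_high": reg.intercept_ci[1],
        "ccc": cc.ccc, "ccc_ci_low": cc.ci_low, "ccc_ci_high": cc.ci_high,
        "bias": ba.bias, "sd": ba.sd, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
        "prop_bias_slope": pb.slope, "prop_bias_intercept": pb.intercept,
        "prop_bias_p": pb.p_value,
        "paired_t": tt.t, "paired_t_df": tt.df, "paired_t_p": tt.p,
        "flags": tt.flag,
    }


def _group_labels(participants: pd.DataFrame) -> pd.Series:
    sexes = participants["sex"].astype(str)
    groups = participants["age_years"].map(lambda a: age_group_of(a).value)
    return sexes + " " + groups


def comparison_table(
    estimates: pd.DataFrame,
    participants: Optional[pd.DataFrame] = None,
    value: str = "fm_kg",
    reference_method: str = "FOURC",
    grouping: str = "total",
    loa_multiplier: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Agreement battery of every method against the reference, per group.

    ``estimates`` is the tidy table (participant_id, method, fm_kg, ffm_kg,
    pct_fat, ...). ``grouping`` is ``"total"`` or ``"sex_age"``; the latter
    needs a ``participants`` frame with id, sex, age_years and yields the
    four sex-by-age cells plus the total (5 rows per method). Cells with
    fewer than 3 complete pairs are emitted with an ``insufficient-n`` flag
    rather than dropped.
    """
    if grouping not in ("total", "sex_age"):
        raise ValueError("grouping must be 'total' or 'sex_age'")
    wide = estimates.pivot_table(index="participant_id", columns="method",
                                 values=value, aggfunc="first")
    if reference_method not in wide.columns:
        raise ValueError(f"no estimates for reference method {reference_method!r}")

    memberships = [("total", wide.index)]
    if grouping == "sex_age":
        if participants is None:
            raise ValueError("sex_age grouping needs a participants frame")
        p = participants.set_index("id") if "id" in participants.columns else participants.set_index("participant_id")
        labels = _group_labels(p)
        for name in sorted(labels.unique()):
            ids = labels.index[labels == name]
            memberships.append((name, wide.index.intersection(ids)))

    methods = [m for m in wide.columns if m != reference_method]
    rows = []
    for method in methods:
        for group_name, ids in memberships:
            sub = wide.loc[ids, [method, reference_method]].dropna()
            row = {"method": method, "group": group_name}
            if len(sub) < 3:
                row.update({c: float("nan") for c in COMPARISON_COLUMNS[2:-1]})
                row["n_pairs"] = len(sub)
                row["flags"] = "insufficient-n"
            else:
                pairs = PairedSeries(
                    method_values=tuple(sub[method]),
                    reference_values=tuple(sub[reference_method]),
                    label=str(method),
                )
                row.update(comparison_row(pairs, loa_multiplier, alpha))
            rows.append(row)
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


def bland_altman_points(
    estimates: pd.DataFrame,
    value: str = "fm_kg",
    reference_method: str = "FOURC",
) -> pd.DataFrame:
    """Per-pair (average, difference) points for Bland-Altman plotting."""
    wide = estimates.pivot_table(index="participant_id", columns="method",
                                 values=value, aggfunc="first")
    frames = []
    for method in (m for m in wide.columns if m != reference_method):
        sub = wide[[method, reference_method]].dropna()
        frames.append(pd.DataFrame({
            "participant_id": sub.index,
            "method": method,
            "average": (sub[method] + sub[reference_method]).to_numpy() / 2.0,
            "difference": (sub[method] - sub[reference_method]).to_numpy(),
        }))
    if not frames:
        return pd.DataFrame(columns=["participant_id", "method", "average", "difference"])
    return pd.concat(frames, ignore_index=True)
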