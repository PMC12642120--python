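"""Normality-gated two-group inference with domain-wise Bonferroni control.

Each of the 15 behavioral features is compared between the MDD and control
groups: Shapiro-Wilk gates the test choice (independent-samples t when both
groups look normal, Mann-Whitney U otherwise), and significance is judged
against the domain-wise Bonferroni threshold alpha_domain = 0.05 / m_domain
(gaze/ocular/speech: .0167; affect: .0125; head: .0250). Findings with
p < alpha_domain are "significant after correction", findings with
alpha_domain <= p < .05 are "nominal only". A normal-approximation power
calculator reports the minimum detectable standardized effect at given
alpha/power/group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import FEATURE_DOMAIN, FeatureMatrix, domain_specs

TIER_SIGNIFICANT = "significant_after_correction"
TIER_NOMINAL = "nominal_only"
TIER_NOT = "not_significant"


@dataclass
class GroupComparisonResult:
    feature: str
    domain: str
    test: str  # welch_t | student_t | mann_whitney | chi_square
    statistic: float
    df: float | None
    p: float
    alpha_domain: float
    tier: str
    effect_size: float
    effect_size_name: str
    z: float | None = None
    u_statistic: float | None = None
    ci_mean_diff: tuple[float, float] | None = None
    n1: int = 0
    n2: int = 0
    direction: str = ""


def domain_alpha(m_domain: int, family_alpha: float = 0.05) -> float:
    """Domain-wise Bonferroni threshold family_alpha / m_domain."""
    if m_domain < 1:
        raise ValueError("a domain must contain at least one feature")
    return family_alpha / m_domain


def assign_tier(p: float, alpha_domain: float, nominal_alpha: float = 0.05) -> str:
    """Significance tier from a p-value and the domain threshold."""
    if p < alpha_domain:
        return TIER_SIGNIFICANT
    if p < nominal_alpha:
        return TIER_NOMINAL
    return TIER_NOT


def normality_gate(
    group1: np.ndarray,
    group2: np.ndarray,
    alpha: float = 0.05,
) -> tuple[bool, dict]:
    """Parametric-test gate: Shapiro-Wilk non-rejection in both groups.

    Returns (parametric, details) where details carries the per-group
    Shapiro-Wilk and (informational) Kolmogorov-Smirnov p-values. A constant
    group is never treated as normal and triggers a warning.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("need at least 3 values per group")
    details: dict = {}
    parametric = True
    for name, g in (("group1", g1), ("group2", g2)):
        if np.ptp(g) == 0:
            warnings.warn(f"{name} is constant; treating as non-normal")
            details[f"shapiro_p_{name}"] = 0.0
            details[f"ks_p_{name}"] = 0.0
            parametric = False
            continue
        sw = sps.shapiro(g)
        ks = sps.kstest(g, "norm", args=(g.mean(), g.std(ddof=1)))
        details[f"shapiro_p_{name}"] = float(sw.pvalue)
        details[f"ks_p_{name}"] = float(ks.pvalue)
        if sw.pvalue < alpha:
            parametric = False
    return parametric, details


def cohens_d_from_summaries(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> float:
    """Cohen's d = (m1 - m2) / pooled SD from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise ValueError("zero pooled standard deviation")
    return (m1 - m2) / np.sqrt(pooled_var)


def cohens_d(group1: np.ndarray, group2: np.ndarray) -> float:
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    return cohens_d_from_summaries(
        g1.mean(), g1.std(ddof=1), len(g1), g2.mean(), g2.std(ddof=1), len(g2)
    )


def t_test_from_summaries(
    m1: float,
    sd1: float,
    n1: int,
    m2: float,
    sd2: float,
    n2: int,
    welch: bool = True,
    conf: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """Two-sample t statistic, df, and mean-difference CI from summaries.

    Welch mode uses the Welch-Satterthwaite degrees of freedom; pooled mode
    uses the classical df = n1 + n2 - 2.
    """
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    diff = m1 - m2
    if welch:
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    t = diff / se
    tcrit = sps.t.ppf(1 - (1 - conf) / 2, df)
    return float(t), float(df), (float(diff - tcrit * se), float(diff + tcrit * se))


def _mann_whitney_exact_p(group1: np.ndarray, group2: np.ndarray, u1: float) -> float:
    """Two-sided exact p by enumerating every label assignment (small n only)."""
    pooled = np.concatenate([group1, group2])
    n1 = len(group1)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    obs_dev = abs(u1 - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        r1 = ranks[list(idx)].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def mann_whitney(
    group1: np.ndarray,
    group2: np.ndarray,
    exact_max_n: int = 10,
    continuity: bool = True,
) -> dict:
    """Mann-Whitney U with exact small-sample p and a reported Z.

    For n1 + n2 <= ``exact_max_n`` the two-sided p is computed by exact
    enumeration of all label assignments (valid under ties); otherwise the
    normal approximation with tie correction and (optional) continuity
    correction is used. U is reported for group 1 (U1); Z's sign follows
    mean rank of group1 minus mean rank of group2.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = len(g1), len(g2)
    pooled = np.concatenate([g1, g2])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    mu = n1 * n2 / 2.0
    # tie-corrected variance of U
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sigma = np.sqrt(sigma2)
    if sigma > 0:
        dev = u1 - mu
        cc = 0.5 * np.sign(dev) if continuity else 0.0
        z = (dev - cc) / sigma
    else:
        z = 0.0
    if n <= exact_max_n:
        p = _mann_whitney_exact_p(g1, g2, u1)
    else:
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    # rank-biserial effect size: magnitude 1 - 2*min(U)/(n1*n2), signed by
    # the mean-rank difference
    r_rb = 1.0 - 2.0 * min(u1, u2) / (n1 * n2)
    mean_rank_diff = ranks[:n1].mean() - ranks[n1:].mean()
    r_rb *= np.sign(mean_rank_diff) if mean_rank_diff != 0 else 0.0
    return {
        "u1": float(u1),
        "u_min": float(min(u1, u2)),
        "z": float(z),
        "p": float(p),
        "rank_biserial": float(r_rb),
    }


def compare_feature(
    group1: np.ndarray,
    group2: np.ndarray,
    feature: str = "",
    parametric: bool | None = None,
    alpha_domain: float = 0.05,
    welch: bool = True,
    exact_max_n: int = 10,
) -> GroupComparisonResult:
    """Normality-gated two-group comparison of one feature.

    group1 is the MDD group by convention; a negative parametric statistic or
    a lower group-1 mean rank reads "MDD < HC".
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    g1 = g1[np.isfinite(g1)]
    g2 = g2[np.isfinite(g2)]
    n1, n2 = len(g1), len(g2)
    if n1 < 3 or n2 < 3:
        raise ValueError(f"{feature}: need at least 3 complete cases per group")
    if parametric is None:
        parametric, _ = normality_gate(g1, g2)
    domain = FEATURE_DOMAIN.get(feature, "")
    if parametric:
        test = "welch_t" if welch else "student_t"
        t, df, ci = t_test_from_summaries(
            g1.mean(), g1.std(ddof=1), n1, g2.mean(), g2.std(ddof=1), n2, welch=welch
        )
        p = float(2.0 * sps.t.sf(abs(t), df))
        result = GroupComparisonResult(
            feature=feature,
            domain=domain,
            test=test,
            statistic=t,
            df=df,
            p=p,
            alpha_domain=alpha_domain,
            tier=assign_tier(p, alpha_domain),
            effect_size=cohens_d(g1, g2),
            effect_size_name="cohens_d",
            ci_mean_diff=ci,
            n1=n1,
            n2=n2,
        )
        sign = np.sign(t)
    else:
        mw = mann_whitney(g1, g2, exact_max_n=exact_max_n)
        result = GroupComparisonResult(
            feature=feature,
            domain=domain,
            test="mann_whitney",
            statistic=mw["u_min"],
            df=None,
            p=mw["p"],
            alpha_domain=alpha_domain,
            tier=assign_tier(mw["p"], alpha_domain),
            effect_size=mw["rank_biserial"],
            effect_size_name="rank_biserial",
            z=mw["z"],
            u_statistic=mw["u1"],
            n1=n1,
            n2=n2,
        )
        sign = np.sign(mw["z"]) if mw["z"] != 0 else 0.0
    if result.tier == TIER_NOT or sign == 0:
        result.direction = "No difference"
    else:
        result.direction = "MDD < HC" if sign < 0 else "MDD > HC"
    return result


def minimum_detectable_d(
    n1: int,
    n2: int,
    alpha: float = 0.05,
    power: float = 0.80,
    method: str = "normal",
) -> float:
    """Minimum detectable standardized mean difference (two-sided test).

    The default normal approximation d = (z_{1-alpha/2} + z_power) *
    sqrt(1/n1 + 1/n2) matches the convention of standard power software at
    these sample sizes; ``method="noncentral_t"`` solves the exact two-sample
    noncentral-t power equation instead.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie strictly in (0, 1)")
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    if method == "normal":
        return float((sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)) * scale)
    if method != "noncentral_t":
        raise ValueError(f"unknown method {method!r}")
    df = n1 + n2 - 2
    tcrit = sps.t.ppf(1 - alpha / 2, df)

    def power_at(d: float) -> float:
        ncp = d / scale
        return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))

    from scipy.optimize import brentq

    return float(brentq(lambda d: power_at(d) - power, 1e-6, 10.0, xtol=1e-8))


def chi_square_counts(table: np.ndarray, correction: bool = False) -> dict:
    """Pearson chi-square on a contingency table (demographics)."""
    chi2, p, df, _ = sps.chi2_contingency(np.asarray(table), correction=correction)
    return {"chi2": float(chi2), "p": float(p), "df": int(df)}


def run_domain_analysis(
    matrix: FeatureMatrix,
    qc_report=None,
    family_alpha: float = 0.05,
    welch: bool = True,
    gate_alpha: float = 0.05,
) -> list[GroupComparisonResult]:
    """Compare all 15 features with domain-wise Bonferroni control.

    Complete cases per domain: when a QC report is given, participants whose
    domain was flagged excluded contribute no values to that domain's
    comparisons; NaN cells are always dropped per feature.
    """
    specs = domain_specs(family_alpha)
    results: list[GroupComparisonResult] = []
    is_mdd = matrix.labels == "MDD"
    for domain, spec in specs.items():
        if qc_report is not None:
            ok_ids = set(qc_report.included_ids(domain)) & set(matrix.data.index)
            sub = matrix.data.loc[sorted(ok_ids)]
            sub_mdd = is_mdd.loc[sorted(ok_ids)]
        else:
            sub = matrix.data
            sub_mdd = is_mdd
        for feature in spec.members:
            vals = sub[feature]
            g1 = vals[sub_mdd].to_numpy()
            g2 = vals[~sub_mdd].to_numpy()
            results.append(
                compare_feature(
                    g1, g2, feature=feature, alpha_domain=spec.alpha, welch=welch
                )
            )
    return results


_TIER_LABEL = {
    TIER_SIGNIFICANT: "Significant after correction",
    TIER_NOMINAL: "Nominally significant only",
    TIER_NOT: "Not significant",
}


def report_table(results: list[GroupComparisonResult]) -> pd.DataFrame:
    """Render comparison results as the standard group-comparison table."""
    rows = []
    for r in results:
        if r.test in ("welch_t", "student_t"):
            name = "Welch's t-test" if r.test == "welch_t" else "Independent t-test"
            stat = f"t({r.df:.2f}) = {r.statistic:.2f}"
        else:
            name = "Mann-Whitney U"
            stat = f"U = {r.statistic:.1f}, Z = {r.z:.2f}"
        rows.append(
            {
                "Domain": r.domain,
                "Measure": r.feature,
                "Test": name,
                "Statistic": stat,
                "P-value": f"{r.p:.3f}" if r.p >= 0.001 else "<.001",
                "Bonferroni (domain)": _TIER_LABEL[r.tier],
                "Group difference (MDD vs. HC)": r.direction,
            }
        )
    return pd.DataFrame(rows)
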