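"""Group-level statistics: normality gate, pairwise t-tests, ANCOVA, Spearman.

The plan mirrors a standard neuropathology cohort analysis.  Chromogenic
case-mean intensity scores, which pass Shapiro-Wilk and an equal-variance
check, are compared with pooled-variance two-sample t-tests for the six
ordered group pairs, with no multiplicity correction by default (a Holm
option exists).  An ANCOVA on the case-level scores tests whether age,
final MMSE and APOE genotype influence the result beyond the stage x region
design.  Fluorescence percentage-of-sum data are non-normal, so the
red/green association within each group is assessed with Spearman rank
correlation (midranks for ties; exact permutation p for n <= 9).
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .image_io import GROUP_ORDER

logger = logging.getLogger(__name__)

#: the six pairwise comparisons, in the order the design lists them:
#: the spared endogenous-control group (early-MFG) against each NFT-affected
#: group first, then the NFT-affected groups among themselves.
TTEST_PAIRS: tuple[tuple[str, str], ...] = (
    ("early-MFG", "early-aHPC"),
    ("early-MFG", "late-MFG"),
    ("early-MFG", "late-aHPC"),
    ("late-MFG", "early-aHPC"),
    ("late-MFG", "late-aHPC"),
    ("early-aHPC", "late-aHPC"),
)


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: int
    groups: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "groups": list(self.groups),
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# normality gate


def shapiro_gate(values, alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk normality test, gating the parametric (t-test) path.

    Returns the W statistic and p; callers route to the t-test path only when
    p >= alpha, otherwise to rank-based methods (Spearman), which is how the
    non-normal fluorescence proportions are handled.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    stat, p = scipy.stats.shapiro(x)
    passed = p >= alpha
    return TestResult(
        name="shapiro_wilk",
        statistic=float(stat),
        p_value=float(p),
        n=int(x.size),
        note="pass" if passed else "fail",
    )


# ---------------------------------------------------------------------------
# pairwise t-tests


def pairwise_ttests(
    case_means_by_group: dict[str, np.ndarray | list[float]],
    *,
    holm: bool = False,
) -> list[TestResult]:
    """Equal-variance two-sided t-tests for the six listed group pairs.

    No multiple-testing correction is applied by default (matching the
    original analysis plan); ``holm=True`` adjusts the six p-values with
    Holm's step-down method.
    """
    for g in GROUP_ORDER:
        if g not in case_means_by_group:
            raise ValueError(f"missing group {g!r}")
        if len(case_means_by_group[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cases")
    results = []
    for g1, g2 in TTEST_PAIRS:
        a = np.asarray(case_means_by_group[g1], dtype=float)
        b = np.asarray(case_means_by_group[g2], dtype=float)
        stat, p = scipy.stats.ttest_ind(a, b, equal_var=True)
        results.append(
            TestResult(
                name="t_test",
                statistic=float(stat),
                p_value=float(p),
                n=int(a.size + b.size),
                groups=(g1, g2),
            )
        )
    if holm:
        order = np.argsort([r.p_value for r in results])
        adj = {}
        running = 0.0
        for rank, idx in enumerate(order):
            padj = min(1.0, (len(results) - rank) * results[idx].p_value)
            running = max(running, padj)
            adj[idx] = running
        results = [
            TestResult(
                name=r.name,
                statistic=r.statistic,
                p_value=adj[i],
                n=r.n,
                groups=r.groups,
                note="holm-adjusted",
            )
            for i, r in enumerate(results)
        ]
    return results


# ---------------------------------------------------------------------------
# ANCOVA

_APOE_ALLELE = re.compile(r"[eEεΕ]\s*[-–/]?\s*([234])")


def parse_apoe_e4_count(genotype) -> float:
    """Number of APOE ε4 alleles in a genotype string such as 'ε3–ε4' or 'e3/e4'.

    Missing entries ('-', '', NaN, None) map to NaN.
    """
    if genotype is None or (isinstance(genotype, float) and math.isnan(genotype)):
        return math.nan
    s = str(genotype).strip()
    alleles = _APOE_ALLELE.findall(s)
    if len(alleles) != 2:
        if s in ("-", "", "NA", "na", "nan"):
            return math.nan
        raise ValueError(f"cannot parse APOE genotype {genotype!r}")
    return float(sum(a == "4" for a in alleles))


@dataclass(frozen=True)
class AncovaResult:
    covariates: dict[str, TestResult]
    factors: dict[str, TestResult]
    n_used: int
    dropped_cases: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "covariates": {k: v.to_dict() for k, v in self.covariates.items()},
            "factors": {k: v.to_dict() for k, v in self.factors.items()},
            "n_used": self.n_used,
            "dropped_cases": list(self.dropped_cases),
            "notes": list(self.notes),
        }


def ancova(
    records: pd.DataFrame,
    *,
    response: str = "mean_score",
    apoe_coding: str = "e4_count",
) -> AncovaResult:
    """Case-level ANCOVA: response ~ stage + region + age + final MMSE + APOE.

    ``records`` needs columns case_id, stage, region, age, final_mmse, apoe
    (genotype string or pre-coded numeric) and the response.  Cases with a
    missing covariate are dropped listwise and logged.  ``apoe_coding`` is
    ``"e4_count"`` (ε4 allele count 0/1/2 as a numeric covariate, default) or
    ``"onehot"`` (genotype as a categorical factor).  Per-term p-values are
    type-II F tests from the fitted linear model.
    """
    df = records.copy()
    required = {"case_id", "stage", "region", "age", "final_mmse", "apoe", response}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if apoe_coding not in ("e4_count", "onehot"):
        raise ValueError("apoe_coding must be 'e4_count' or 'onehot'")

    if apoe_coding == "e4_count":
        if pd.api.types.is_numeric_dtype(df["apoe"]):
            df["apoe_num"] = df["apoe"].astype(float)
        else:
            df["apoe_num"] = [parse_apoe_e4_count(g) for g in df["apoe"]]
        apoe_term = "apoe_num"
    else:
        df["apoe_cat"] = df["apoe"].where(df["apoe"].astype(str).str.strip() != "-")
        apoe_term = "C(apoe_cat)"

    cov_cols = ["age", "final_mmse", "apoe_num" if apoe_coding == "e4_count" else "apoe_cat"]
    usable = df.dropna(subset=cov_cols + [response])
    dropped = tuple(df.loc[~df.index.isin(usable.index), "case_id"].astype(str))
    if dropped:
        logger.info("ANCOVA: dropped cases with missing covariates: %s", list(dropped))
    if len(usable) < 7:
        raise ValueError(f"too few complete cases for ANCOVA (n={len(usable)})")

    notes = []
    # constant covariates are inestimable; flag and drop them from the model
    terms = {"age": "age", "final_mmse": "final_mmse", "apoe": apoe_term}
    inestimable = {}
    for key in ("age", "final_mmse"):
        if usable[key].nunique() <= 1:
            inestimable[key] = "constant across cases; effect inestimable"
    apoe_data_col = "apoe_num" if apoe_coding == "e4_count" else "apoe_cat"
    if usable[apoe_data_col].nunique() <= 1:
        inestimable["apoe"] = "constant across cases; effect inestimable"

    rhs = ["C(stage)", "C(region)"] + [
        t for k, t in terms.items() if k not in inestimable
    ]
    formula = f"{response} ~ " + " + ".join(rhs)
    model = smf.ols(formula, data=usable).fit()
    if model.df_resid <= 0:
        raise ValueError("ANCOVA model is saturated; no residual degrees of freedom")
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        notes.append("design matrix is rank deficient; some effects are aliased")
    table = sm.stats.anova_lm(model, typ=2)

    def _term_result(term_key: str, model_term: str) -> TestResult:
        row = table.loc[model_term]
        return TestResult(
            name=f"ancova_{term_key}",
            statistic=float(row["F"]),
            p_value=float(row["PR(>F)"]),
            n=int(len(usable)),
        )

    covs = {}
    for key, model_term in terms.items():
        if key in inestimable:
            covs[key] = TestResult(
                name=f"ancova_{key}",
                statistic=math.nan,
                p_value=math.nan,
                n=int(len(usable)),
                note=inestimable[key],
            )
        else:
            covs[key] = _term_result(key, model_term)
    factors = {
        "stage": _term_result("stage", "C(stage)"),
        "region": _term_result("region", "C(region)"),
    }
    return AncovaResult(
        covariates=covs,
        factors=factors,
        n_used=int(len(usable)),
        dropped_cases=dropped,
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation


def _midranks(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, method="average")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of midranks, in exact integer arithmetic.

    Midranks are half-integers, so doubling them gives exact integers; the
    product-moment formula is then evaluated in Python's arbitrary-precision
    ints, which makes perfectly (anti)monotone data yield exactly +/-1.0
    rather than a float one ulp away.
    """
    n = len(rx)
    ax = [int(round(2 * v)) for v in rx]
    ay = [int(round(2 * v)) for v in ry]
    sx, sy = sum(ax), sum(ay)
    sxx = sum(v * v for v in ax)
    syy = sum(v * v for v in ay)
    sxy = sum(u * v for u, v in zip(ax, ay))
    num = n * sxy - sx * sy
    d1 = n * sxx - sx * sx
    d2 = n * syy - sy * sy
    if d1 == 0 or d2 == 0:
        raise ValueError("Spearman undefined: a variable has no rank variation")
    if num * num == d1 * d2:
        return 1.0 if num > 0 else -1.0
    return num / math.sqrt(d1 * d2)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p over all n! orderings of one rank vector."""
    n = len(rx)
    rxc = rx - rx.mean()
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    permc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt(float(rxc @ rxc) * (permc * permc).sum(axis=1))
    rhos = permc @ rxc / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, *, exact_max_n: int = 9) -> TestResult:
    """Spearman rank correlation with midrank tie handling.

    rho is the Pearson correlation of midranks.  The two-sided p-value is an
    exact permutation enumeration for n <= ``exact_max_n`` and the usual
    t-approximation otherwise; no reporting floor is applied, so extreme
    associations at large n genuinely underflow to 0.0 rather than being
    clamped to a smallest printable value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"Spearman needs n >= 3, got n={n}")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rank_corr(rx, ry)
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
    elif abs(rho) >= 1.0:
        p = 0.0  # t statistic diverges; asymptotic tail mass underflows
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    return TestResult(name="spearman", statistic=rho, p_value=p, n=int(n))
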