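"""Clinical layer of the trial analysis.

Works on a long-format clinical table (one row per patient-visit with
patient_id, arm, visit_day, mrss, disease_duration, covariates).  Provides
last-observation-carried-forward filling over the visit schedule,
skin-score responder ("improver") classification, small-sample exact tests
(Fiser-style exact 2x2, exact Wilcoxon signed rank), two-sample t-tests
from summary statistics, cohort summary tables, and the random-intercept
mixed model for mRSS adjusted for disease duration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "VISIT_DAYS",
    "apply_locf",
    "classify_improver",
    "summary_two_sample_t",
    "fisher_exact_2x2",
    "wilcoxon_signed_rank",
    "pooled_mean",
    "pooled_proportion",
    "cohort_summary",
    "fit_mrss_mixed_model",
]

#: trial visit schedule in days: infusions on days 1, 15, 29 and every 28
#: days through day 141, with the final efficacy visit at day 169 (week 24)
VISIT_DAYS = [1, 15, 29, 57, 85, 113, 141, 169]

#: mRSS responder threshold: relative decrease from baseline of at least 30%
IMPROVER_THRESHOLD = 0.30


def apply_locf(clinical: pd.DataFrame, visit_days: list[int] | None = None) -> pd.DataFrame:
    """Fill missing visits by carrying the last observation forward.

    Every patient is expanded to the full visit schedule; an mRSS value
    missing at a scheduled visit is replaced by the most recent observed
    value, and the fill is flagged in a boolean ``locf`` column.  A patient
    without a baseline (first scheduled visit) observation is an error.
    Per-patient covariate columns are propagated to the filled rows.
    """
    days = visit_days if visit_days is not None else VISIT_DAYS
    out = []
    for pid, grp in clinical.groupby("patient_id", sort=True):
        grp = grp.sort_values("visit_day")
        observed = grp.dropna(subset=["mrss"]).set_index("visit_day")["mrss"]
        if days[0] not in observed.index:
            raise ValueError(f"patient {pid!r} missing baseline mRSS at day {days[0]}")
        filled = observed.reindex(days).ffill()
        rec = grp.iloc[0].drop(labels=["visit_day", "mrss"])
        block = pd.DataFrame({
            "visit_day": days,
            "mrss": filled.values,
            "locf": [d not in observed.index for d in days],
        })
        for col, val in rec.items():
            block[col] = val
        out.append(block)
    cols = ["patient_id", "arm", "visit_day", "mrss", "locf"]
    result = pd.concat(out, ignore_index=True)
    other = [c for c in result.columns if c not in cols]
    return result[cols + other]


def classify_improver(clinical: pd.DataFrame, visit_days: list[int] | None = None) -> pd.DataFrame:
    """Responder classification: mRSS decrease of >=30% at the final visit.

    Expects a LOCF-completed table (``apply_locf`` output). The relative
    change is (baseline - final)/baseline; the threshold is inclusive.
    Returns one row per patient with arm, baseline, final,
    relative_change and improver.
    """
    days = visit_days if visit_days is not None else VISIT_DAYS
    rows = []
    for pid, grp in clinical.groupby("patient_id", sort=True):
        series = grp.set_index("visit_day")["mrss"]
        if days[0] not in series.index or pd.isna(series[days[0]]):
            raise ValueError(f"patient {pid!r} missing baseline mRSS")
        baseline = float(series[days[0]])
        if baseline == 0:
            raise ValueError(f"patient {pid!r} has baseline mRSS 0")
        final_day = max(d for d in days if d in series.index and not pd.isna(series[d]))
        final = float(series[final_day])
        rel = (baseline - final) / baseline
        rows.append({
            "patient_id": pid,
            "arm": grp["arm"].iloc[0],
            "baseline_mrss": baseline,
            "final_mrss": final,
            "relative_change": rel,
            "improver": bool(rel >= IMPROVER_THRESHOLD),
        })
    return pd.DataFrame(rows).set_index("patient_id")


def summary_two_sample_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    pooled: bool = True,
) -> dict:
    """Two-sample t-test from summary statistics.

    Pooled (equal-variance) by default: sp^2 = ((n1-1)sd1^2 + (n2-1)sd2^2)
    / (n1+n2-2) on n1+n2-2 df. ``pooled=False`` gives Welch's t with
    Satterthwaite df. Two identical summaries with zero spread return
    t=0, p=1 with a degenerate flag.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    diff = mean1 - mean2
    if sd1 == 0 and sd2 == 0:
        if diff == 0:
            return {"t": 0.0, "df": n1 + n2 - 2, "p": 1.0, "degenerate": True}
        return {"t": math.copysign(math.inf, diff), "df": n1 + n2 - 2,
                "p": float(np.nextafter(0, 1)), "degenerate": True}
    if pooled:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df=df)
    return {"t": float(t), "df": float(df), "p": float(p), "degenerate": False}


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Two-sided Fisher exact test by the probability-mass rule.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table
    (within relative tolerance 1e-7).  A zero margin leaves a single
    possible table, so p = 1 by convention (flagged).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, c1, N = a + b, a + c, a + b + c + d
    if N == 0:
        raise ValueError("empty table")
    if r1 == 0 or c1 == 0 or r1 == N or c1 == N:
        return {"p": 1.0, "degenerate": True}
    lo = max(0, r1 + c1 - N)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(support, N, c1, r1)
    p_obs = probs[a - lo]
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return {"p": min(p, 1.0), "degenerate": False}


def _wilcoxon_exact_p(ranks2: np.ndarray, w2_obs: float) -> float:
    """Exact two-sided p for the signed-rank statistic via the distribution
    of W+ over all sign assignments (dynamic program on doubled ranks)."""
    total = int(ranks2.sum())
    # dist[s] = number of assignments with doubled positive-rank sum s
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    center = total / 2.0
    dev = abs(w2_obs - center)
    support = np.arange(total + 1)
    count = dist[np.abs(support - center) >= dev - 1e-9].sum()
    return float(count / dist.sum())


def wilcoxon_signed_rank(diffs) -> dict:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (the classical policy); tied absolute
    differences receive midranks. The two-sided p is exact for n <= 25
    (full distribution of the positive-rank sum W+ over the 2^n equally
    likely sign assignments, measured as deviation from the null center)
    and uses the normal approximation with continuity and tie correction
    above. Returns W+ and p.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no information: all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _wilcoxon_exact_p(ranks2, 2 * w_plus)
    else:
        mu = total / 2.0
        sigma = math.sqrt((ranks**2).sum() / 4.0)
        dev = abs(w_plus - mu)
        z = max(dev - 0.5, 0.0) / sigma
        p = 2 * stats.norm.sf(z)
    return {"W": w_plus, "n": n, "p": float(min(p, 1.0))}


def pooled_mean(means, ns) -> float:
    """Size-weighted mean of per-arm means (for summary-only inputs)."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    return float((means * ns).sum() / ns.sum())


def pooled_proportion(counts, ns) -> float:
    """Overall proportion from per-arm counts and sizes."""
    return float(np.asarray(counts, dtype=float).sum() / np.asarray(ns, dtype=float).sum())


def cohort_summary(
    baseline: pd.DataFrame,
    numeric: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Per-arm and pooled baseline characteristics table.

    ``baseline`` has one row per patient with an ``arm`` column. Numeric
    covariates get mean, SD, median and range; categorical covariates get
    counts and percentages. The pooled column aggregates across arms.
    """
    if baseline.empty:
        raise ValueError("no patients")
    numeric = numeric or []
    categorical = categorical or []
    arms = sorted(baseline["arm"].unique())
    groups = {arm: baseline[baseline["arm"] == arm] for arm in arms}
    groups["pooled"] = baseline
    rows = []
    for var in numeric:
        for name, grp in groups.items():
            vals = grp[var].dropna().astype(float)
            rows.append({
                "variable": var, "arm": name, "n": len(vals),
                "mean": vals.mean(), "sd": vals.std(ddof=1),
                "median": vals.median(),
                "min": vals.min(), "max": vals.max(),
            })
    for var in categorical:
        for name, grp in groups.items():
            vals = grp[var].dropna()
            count = int((vals.astype(bool)).sum()) if vals.dtype != object else int(vals.value_counts().iloc[0])
            rows.append({
                "variable": var, "arm": name, "n": len(vals),
                "count": count, "percent": 100.0 * count / len(vals) if len(vals) else np.nan,
            })
    return pd.DataFrame(rows)


def fit_mrss_mixed_model(
    clinical: pd.DataFrame,
    interaction: bool = False,
    drug_arm: str = "abatacept",
) -> dict:
    """Random-intercept mixed model for mRSS adjusted for disease duration.

    Fits mrss ~ disease_duration + drug + visit (+ visit x drug with
    ``interaction``) with a patient-level random intercept, variance
    components by REML.  Visit enters as the 0-based index into the sorted
    visit schedule.  Fixed-effect confidence intervals and p-values use a
    t reference with residual degrees of freedom
    N_obs - n_fixed - n_patients + 1 (method recorded in the output).

    Returns coefficient table (estimate, 95% CI, p), the random-intercept
    and residual variances, and fit metadata.
    """
    df = clinical.dropna(subset=["mrss"]).copy()
    counts = df.groupby("patient_id").size()
    arm_sizes = df.drop_duplicates("patient_id")["arm"].value_counts()
    if (arm_sizes < 2).any() or len(arm_sizes) < 2:
        raise ValueError("need at least 2 patients per arm")
    if (counts < 2).any():
        raise ValueError("need at least 2 visits per patient")
    visit_index = {d: i for i, d in enumerate(sorted(df["visit_day"].unique()))}
    df["visit"] = df["visit_day"].map(visit_index).astype(float)
    df["drug"] = (df["arm"] == drug_arm).astype(float)

    names = ["intercept", "disease_duration", "drug", "visit"]
    cols = [np.ones(len(df)), df["disease_duration"].to_numpy(dtype=float),
            df["drug"].to_numpy(), df["visit"].to_numpy()]
    if interaction:
        names.append("visit_x_drug")
        cols.append(df["visit"].to_numpy() * df["drug"].to_numpy())
    X = np.column_stack(cols)
    y = df["mrss"].to_numpy(dtype=float)

    model = sm.MixedLM(y, X, groups=df["patient_id"].to_numpy())
    fit = None
    errors = []
    for method in ("lbfgs", "powell", "cg"):
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            errors.append(f"{method}: {exc}")
            continue
        if candidate.converged:
            fit = candidate
            break
        errors.append(f"{method}: did not converge")
    if fit is None:
        raise RuntimeError(f"mixed model failed to converge ({'; '.join(errors)})")

    n_obs = len(df)
    n_groups = df["patient_id"].nunique()
    dof = n_obs - len(names) - n_groups + 1
    tcrit = stats.t.ppf(0.975, dof)
    coefs = {}
    for i, name in enumerate(names):
        est = float(fit.fe_params[i])
        se = float(fit.bse_fe[i])
        tval = est / se
        coefs[name] = {
            "estimate": est,
            "se": se,
            "ci_low": est - tcrit * se,
            "ci_high": est + tcrit * se,
            "p": float(2 * stats.t.sf(abs(tval), dof)),
        }
    sigma2_re = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    out = {
        "coefficients": coefs,
        "random_intercept_var": sigma2_re,
        "residual_var": float(fit.scale),
        "n_obs": n_obs,
        "n_patients": n_groups,
        "df_method": "residual: n_obs - n_fixed - n_patients + 1",
        "df": int(dof),
        "converged": bool(fit.converged),
        "boundary_variance": bool(sigma2_re <= 1e-8),
    }
    return out
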