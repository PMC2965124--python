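"""Clinical derivations and group/correlation statistics.

Integrates the structural (cortical thickness, tract FA), functional (number of
connections, gamma) and clinical (ALSFRS-R, disease duration) measures:
progression-rate derivation, covariate-adjusted group comparisons via a general
linear model, two-sample t-tests from printed summary statistics, partial
correlations, and a pre-registered report table tying structure, function and
clinic together.  All tests are two-sided; the default significance threshold
is alpha = 0.05 with no multiple-testing correction (single-region strategy),
with an optional Bonferroni adjustment on the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TestResult",
    "progression_rate",
    "add_progression_rate",
    "glm_group_compare",
    "summary_ttest",
    "partial_correlation",
    "structure_function_clinic_report",
    "REPORT_PAIRS",
]


@dataclass(frozen=True)
class TestResult:
    effect: float          # group coefficient / mean difference
    statistic: float       # t
    p: float               # two-sided
    df: float
    covariates: tuple[str, ...]
    n_per_group: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")


# ---------------------------------------------------------------------------
# Clinical derivation
# ---------------------------------------------------------------------------

def progression_rate(alsfrs_r, duration_months):
    """Disease progression rate in ALSFRS-R points lost per month:
    (48 - ALSFRS-R) / disease duration.  48 is the maximum (unimpaired) score."""
    score = np.asarray(alsfrs_r, dtype=float)
    dur = np.asarray(duration_months, dtype=float)
    if np.any(dur <= 0):
        raise ValueError("disease duration must be positive")
    if np.any((score < 0) | (score > 48)):
        raise ValueError("ALSFRS-R must lie in [0, 48]")
    rate = (48.0 - score) / dur
    return float(rate) if rate.ndim == 0 else rate


def add_progression_rate(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fill the derived progression-rate column (NaN for controls)."""
    out = cohort.copy()
    pat = out["group"] == "patient"
    rates = np.full(len(out), np.nan)
    rates[pat.to_numpy()] = progression_rate(
        out.loc[pat, "alsfrs_r"], out.loc[pat, "disease_duration_months"])
    out["progression_rate"] = rates
    return out


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.flatnonzero(diag < 1e-10 * max(diag.max(), 1))]
        raise ValueError(f"design matrix is rank deficient (rank {rank} < "
                         f"{mat.shape[1]}); collinear column(s): {bad}")


def glm_group_compare(outcome, group, covariates: pd.DataFrame | dict | None = None
                      ) -> TestResult:
    """Linear model ``outcome ~ group + covariates``; reports the group effect.

    ``group`` holds two labels (e.g. patient/control); the coefficient is the
    mean of the lexicographically larger label minus the smaller one, adjusted
    for the covariates.  With no covariates this is algebraically the pooled
    two-sample t-test.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise ValueError("group must contain exactly two labels")
    indicator = (g == labels[1]).astype(float)
    n1, n0 = int(indicator.sum()), int(len(g) - indicator.sum())
    if min(n0, n1) < 3:
        raise ValueError("need at least 3 subjects per group")

    X = pd.DataFrame({"intercept": np.ones(len(y)), "group": indicator})
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            X[c] = np.asarray(cov[c], dtype=float)
    _check_full_rank(X)
    fit = sm.OLS(y, X).fit()
    return TestResult(
        effect=float(fit.params["group"]),
        statistic=float(fit.tvalues["group"]),
        p=float(fit.pvalues["group"]),
        df=float(fit.df_resid),
        covariates=tuple(c for c in X.columns if c not in ("intercept", "group")),
        n_per_group=(n1, n0),
    )


def summary_ttest(mean1: float, sd1: float, n1: int, mean2: float, sd2: float,
                  n2: int, variant: str = "pooled") -> TestResult:
    """Two-sample t-test from summary statistics alone.

    ``pooled`` assumes equal variances (df = n1 + n2 - 2); ``welch`` uses the
    Welch–Satterthwaite approximation.  Lets published group means/SDs be
    re-tested without subject-level data.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    diff = mean1 - mean2
    if variant == "pooled":
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    elif variant == "welch":
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(effect=diff, statistic=float(t), p=float(p), df=float(df),
                      covariates=(), n_per_group=(n1, n2))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(x, y, covariates: pd.DataFrame | dict | None = None
                        ) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariates from both.

    Both variables are residualized on the covariates (with intercept); the
    p-value uses n - 2 - #covariates degrees of freedom.  With no covariates
    this is the ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is not None and len(pd.DataFrame(covariates).columns) > 0:
        cov = pd.DataFrame(covariates).to_numpy(dtype=float)
    else:
        cov = np.empty((len(x), 0))
    n, k = len(x), cov.shape[1]
    if n < k + 4:
        raise ValueError(f"need at least {k + 4} observations for {k} covariates")
    Z = np.column_stack([np.ones(n), cov])
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    tol_x = 1e-10 * max(np.abs(x).max(), 1.0)
    tol_y = 1e-10 * max(np.abs(y).max(), 1.0)
    if rx.std() <= tol_x or ry.std() <= tol_y:
        raise ValueError("residuals are constant; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip ** 2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# Integrated report
# ---------------------------------------------------------------------------

# (x, y, covariate columns, subject subset) — the pre-registered comparisons.
# Thickness is adjusted for age and global thickness, gamma for the number of
# connections and age; tract-FA correlations are deliberately unadjusted.
REPORT_PAIRS: tuple[tuple[str, str, tuple[str, ...], str], ...] = (
    ("thickness_precentral_affected", "alsfrs_r", ("age", "thickness_whole_brain"), "patients"),
    ("thickness_precentral_affected", "progression_rate", ("age", "thickness_whole_brain"), "patients"),
    ("fa_cst_rostral", "alsfrs_r", (), "patients"),
    ("fa_cst_rostral", "progression_rate", (), "patients"),
    ("fa_cc", "alsfrs_r", (), "patients"),
    ("fa_cc", "progression_rate", (), "patients"),
    ("gamma", "alsfrs_r", ("n_connections", "age"), "patients"),
    ("gamma", "progression_rate", ("n_connections", "age"), "patients"),
    ("fa_cc", "n_interhemispheric", (), "all"),
)


def _affected_precentral(cohort: pd.DataFrame) -> pd.Series:
    """Precentral thickness contralateral to the clinically most affected body
    side (the motor cortex controlling the affected limbs)."""
    for col in ("affected_side", "thickness_lh_precentral", "thickness_rh_precentral"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table is missing required column {col!r}")
    side = cohort["affected_side"].fillna("")
    return pd.Series(
        np.where(side == "L", cohort["thickness_rh_precentral"],
                 cohort["thickness_lh_precentral"]),
        index=cohort.index,
    )


def structure_function_clinic_report(cohort: pd.DataFrame,
                                     bonferroni: bool = False) -> pd.DataFrame:
    """Partial correlations for every pre-registered structure/function/clinic pair.

    Derives the progression rate if absent, resolves the affected-side precentral
    thickness per patient, and emits one tidy row per pair: x, y, covariates,
    subset, n, r, p (and p_adjusted under the optional Bonferroni flag).
    """
    if len(cohort) < 4:
        raise ValueError("cohort table is too small for correlation analysis")
    df = cohort.copy()
    if "progression_rate" not in df.columns:
        df = add_progression_rate(df)
    df["thickness_precentral_affected"] = _affected_precentral(df)

    needed = {x for x, _, _, _ in REPORT_PAIRS} | {y for _, y, _, _ in REPORT_PAIRS}
    needed |= {c for _, _, covs, _ in REPORT_PAIRS for c in covs}
    missing = sorted(needed - set(df.columns))
    if missing:
        raise ValueError(f"cohort table is missing required column(s): {missing}")

    rows = []
    for x, y, covs, subset in REPORT_PAIRS:
        sub = df[df["group"] == "patient"] if subset == "patients" else df
        cols = [x, y, *covs]
        sub = sub.dropna(subset=cols)
        r, p = partial_correlation(sub[x], sub[y],
                                   sub[list(covs)] if covs else None)
        rows.append({"x": x, "y": y, "covariates": "+".join(covs) if covs else "none",
                     "subset": subset, "n": len(sub), "r": r, "p": p})
    out = pd.DataFrame(rows)
    if bonferroni:
        out["p_adjusted"] = np.minimum(out["p"] * len(out), 1.0)
    return out
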