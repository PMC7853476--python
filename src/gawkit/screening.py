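"""Correlation screen, FDR control, relevance rules and norm tables.

Every pairing of a GAW-based with an acoustic-based parameter is screened
per gender (healthy and disordered groups merged within gender) with

* the Pearson product-moment coefficient (PCC) with the classical two-sided
  t-test p-value, and
* the distance correlation coefficient (DCC) of Székely-Rizzo-Bakirov, a
  dependence measure in [0, 1] that is zero iff the variables are
  independent, with a seeded permutation p-value (probability of a permuted
  DCC at least as large as the observed one).

Each (gender x coefficient-type) family of 35 x 14 = 490 tests is adjusted
with the Benjamini-Yekutieli step-up procedure, which controls the false
discovery rate under arbitrary dependence among the tests.  A pair is
*relevant* when its adjusted p-value is below 5% and the absolute
coefficient reaches 0.3, and coefficients are binned with Mukaka's
rule-of-thumb limits (negligible / low / moderate / high / very high).

Norm tables report per group and parameter: n, min, max, mean, median,
sample standard deviation, skewness (g1 = m3 / m2^{3/2}) and excess
kurtosis (m4 / m2^2 - 3), both from central moments with 1/n normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sci_stats

from .battery import acoustic_parameter_names, gaw_parameter_names
from .errors import DegenerateSignalError, GawkitError
from .io import FEMALE_GROUPS, MALE_GROUPS

__all__ = [
    "pearson",
    "distance_correlation",
    "dcc_permutation_p",
    "by_fdr",
    "mukaka_category",
    "relevance_screen",
    "run_screen",
    "norm_table",
]

MUKAKA_BINS = (
    (0.9, "very high"),
    (0.7, "high"),
    (0.5, "moderate"),
    (0.3, "low"),
    (0.0, "negligible"),
)

RELEVANCE_THRESHOLD = 0.3
FDR_Q = 0.05
DEFAULT_N_PERM = 1000


def _pairwise_complete(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = np.isfinite(x) & np.isfinite(y)
    return x[m], y[m]


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-approximation p-value.

    Observations are pairwise-complete; constant inputs raise.
    """
    x, y = _pairwise_complete(x, y)
    if len(x) < 3:
        raise GawkitError(f"need at least 3 complete pairs, have {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSignalError("constant input: correlation undefined")
    res = sci_stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _centered_distances(v: np.ndarray) -> np.ndarray:
    """Double-centered pairwise absolute-difference matrix."""
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x, y) -> float:
    """Sample distance correlation (biased V-statistic estimator) in [0, 1]."""
    x, y = _pairwise_complete(x, y)
    if len(x) < 4:
        raise GawkitError(f"need at least 4 complete pairs, have {len(x)}")
    a = _centered_distances(x)
    b = _centered_distances(y)
    dcov2 = float(np.mean(a * b))
    dvar_x = float(np.mean(a * a))
    dvar_y = float(np.mean(b * b))
    denom = np.sqrt(dvar_x * dvar_y)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def dcc_permutation_p(x, y, n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> float:
    """Permutation p-value for the distance correlation.

    ``p = (1 + #{permuted dcor >= observed}) / (1 + n_perm)`` with y permuted
    by a seeded generator.  The denominator of dcor is permutation-invariant,
    so permuted coefficients are compared through their dCov^2 values.
    """
    if n_perm < 200:
        raise ValueError("n_perm must be at least 200")
    x, y = _pairwise_complete(x, y)
    a = _centered_distances(x)
    b = _centered_distances(y)
    obs = np.mean(a * b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(y))
        if np.mean(a * b[np.ix_(idx, idx)]) >= obs - 1e-15:
            count += 1
    return (1 + count) / (1 + n_perm)


def by_fdr(pvals, q: float = FDR_Q):
    """Benjamini-Yekutieli step-up adjustment.

    Returns (adjusted p-values in input order, rejection flags at level q).
    With order statistics p_(1) <= ... <= p_(m) and c(m) = sum_{k<=m} 1/k,
    adjusted_(i) = min(min_{j>=i} m c(m) p_(j) / j, 1).
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < q


def mukaka_category(coef: float) -> str:
    """Rule-of-thumb strength bin for |coefficient|."""
    a = abs(coef)
    if not np.isfinite(a):
        return "undefined"
    for lo, label in MUKAKA_BINS:
        if a >= lo:
            return label
    return "negligible"


def relevance_screen(screen: pd.DataFrame, threshold: float = RELEVANCE_THRESHOLD,
                     q: float = FDR_Q) -> pd.DataFrame:
    """(Re)compute relevance flags and Mukaka categories on a screen table."""
    out = screen.copy()
    for coef_col, p_col, flag_col in (
        ("pcc", "pcc_p_adj", "relevant_pcc"),
        ("dcc", "dcc_p_adj", "relevant_dcc"),
    ):
        out[flag_col] = (out[p_col] < q) & (out[coef_col].abs() >= threshold)
    out["category"] = out["pcc"].map(mukaka_category)
    out["category_dcc"] = out["dcc"].map(mukaka_category)
    return out


def _fast_dcc_family(sub: pd.DataFrame, gaw_cols, ac_cols, n_perm, rng):
    """All-pairs dcor + permutation p for a complete-case column block.

    One seeded permutation set is shared across pairs; for each acoustic
    column the permuted double-centered matrices are stacked and contracted
    against all GAW columns in a single matrix product.
    """
    n = len(sub)
    a_mats = {c: _centered_distances(sub[c].to_numpy()) for c in gaw_cols}
    a_flat = np.stack([a_mats[c].ravel() for c in gaw_cols], axis=1)  # (n^2, 35)
    dvar_a = np.array([np.mean(a_mats[c] ** 2) for c in gaw_cols])
    perms = [rng.permutation(n) for _ in range(n_perm)]

    dcc = np.empty((len(gaw_cols), len(ac_cols)))
    pvals = np.empty_like(dcc)
    for j, c in enumerate(ac_cols):
        b = _centered_distances(sub[c].to_numpy())
        dvar_b = np.mean(b * b)
        obs = (b.ravel() @ a_flat) / (n * n)                       # (35,)
        b_stack = np.stack([b[np.ix_(p, p)].ravel() for p in perms])
        perm_cov = (b_stack @ a_flat) / (n * n)                    # (n_perm, 35)
        denom = np.sqrt(dvar_a * dvar_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            dcc[:, j] = np.sqrt(np.maximum(obs, 0.0) / denom)
        ge = (perm_cov >= obs[None, :] - 1e-15).sum(axis=0)
        pvals[:, j] = (1 + ge) / (1 + n_perm)
    return dcc, pvals


def run_screen(
    params: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    threshold: float = RELEVANCE_THRESHOLD,
    q: float = FDR_Q,
    compute_dcc: bool = True,
    genders: tuple[str, ...] = ("female", "male"),
) -> dict[str, pd.DataFrame]:
    """Run the full GAW x acoustic correlation screen per gender.

    ``params`` is a cohort parameter table (one row per subject with the 49
    battery columns plus ``group``).  Females are NF+FDF, males NM+FDM.
    PCC and DCC are adjusted in separate per-gender families of 490 tests.
    Returns ``{"female": tidy DataFrame, "male": tidy DataFrame}``.
    """
    gaw_cols = gaw_parameter_names()
    ac_cols = acoustic_parameter_names()
    out: dict[str, pd.DataFrame] = {}

    for g_idx, (gender, groups) in enumerate(
        (("female", FEMALE_GROUPS), ("male", MALE_GROUPS))
    ):
        if gender not in genders:
            continue
        sub = params[params["group"].isin(groups)]
        complete = sub.dropna(subset=gaw_cols + ac_cols)
        if len(complete) < 4:
            raise GawkitError(
                f"too few complete subjects for gender '{gender}' ({len(complete)})"
            )

        rows = []
        for gc in gaw_cols:
            for ac in ac_cols:
                x, y = _pairwise_complete(sub[gc], sub[ac])
                try:
                    r, p = pearson(x, y)
                except GawkitError:
                    r, p = np.nan, np.nan
                rows.append({"gender": gender, "gaw_param": gc, "acoustic_param": ac,
                             "n": len(x), "pcc": r, "pcc_p_raw": p})
        screen = pd.DataFrame(rows)

        if compute_dcc:
            rng = np.random.default_rng([seed, g_idx])
            if len(complete) == len(sub):
                dcc, dcc_p = _fast_dcc_family(sub, gaw_cols, ac_cols, n_perm, rng)
                screen["dcc"] = dcc.reshape(-1)
                screen["dcc_p_raw"] = dcc_p.reshape(-1)
            else:  # pairwise-complete fallback, one pair at a time
                dvals, dps = [], []
                for k, (gc, ac) in enumerate(
                    (gc, ac) for gc in gaw_cols for ac in ac_cols
                ):
                    x, y = _pairwise_complete(sub[gc], sub[ac])
                    if len(x) < 4:
                        dvals.append(np.nan), dps.append(np.nan)
                        continue
                    dvals.append(distance_correlation(x, y))
                    dps.append(dcc_permutation_p(x, y, n_perm=n_perm,
                                                 seed=abs(hash((seed, g_idx, k))) % 2**31))
                screen["dcc"] = dvals
                screen["dcc_p_raw"] = dps
        else:
            screen["dcc"] = np.nan
            screen["dcc_p_raw"] = np.nan

        for raw, adj in (("pcc_p_raw", "pcc_p_adj"), ("dcc_p_raw", "dcc_p_adj")):
            pv = screen[raw].to_numpy()
            adjusted = np.full(len(pv), np.nan)
            ok = np.isfinite(pv)
            if ok.any():
                adjusted[ok], _ = by_fdr(pv[ok], q=q)
            screen[adj] = adjusted

        out[gender] = relevance_screen(screen, threshold=threshold, q=q)
    return out


_MOMENT_MIN_N = {"std": 2, "skewness": 3, "kurtosis": 4}


def norm_table(params: pd.DataFrame, groups=("NF", "FDF", "NM", "FDM")) -> pd.DataFrame:
    """Per-group descriptive statistics for every battery parameter.

    Skewness and excess kurtosis use central moments with 1/n normalization
    (``g1`` and ``m4/m2^2 - 3``); cells with too few non-missing values for
    a statistic are NaN.
    """
    param_cols = gaw_parameter_names() + acoustic_parameter_names()
    rows = []
    for group in groups:
        sub = params[params["group"] == group]
        for col in param_cols:
            v = sub[col].dropna().to_numpy() if len(sub) else np.array([])
            n = len(v)
            row = {"group": group, "parameter": col, "n": n,
                   "min": np.nan, "max": np.nan, "mean": np.nan, "median": np.nan,
                   "std": np.nan, "skewness": np.nan, "kurtosis": np.nan}
            if n >= 1:
                row.update(min=v.min(), max=v.max(), mean=v.mean(), median=np.median(v))
            if n >= _MOMENT_MIN_N["std"]:
                row["std"] = v.std(ddof=1)
            if n >= _MOMENT_MIN_N["skewness"] and np.ptp(v) > 0:
                row["skewness"] = sci_stats.skew(v, bias=True)
            if n >= _MOMENT_MIN_N["kurtosis"] and np.ptp(v) > 0:
                row["kurtosis"] = sci_stats.kurtosis(v, fisher=True, bias=True)
            rows.append(row)
    return pd.DataFrame(rows)
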