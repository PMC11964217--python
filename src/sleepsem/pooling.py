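"""Pooling across imputations and the mediation decomposition.

Point estimates are pooled by Rubin's rules (T = Ubar + (1 + 1/m) B with
Barnard-Rubin style small-sample df), chi-square test statistics by the D2
procedure (an F-reference combination of the m statistics).  The mediation
decomposition reports, per mediator, the A-path, B-path, direct effect c',
indirect effect a*b, total effect a*b + c', and the percentage mediated
PM = 100 * indirect / total.  PM intervals follow the endpoint-ratio of
the indirect and total intervals (approximate, non-inferential); a
delta-method alternative is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PooledEstimate",
    "rubin_pool",
    "d2_pool_chisq",
    "mediation_decompose",
    "pooled_mediation_report",
]


@dataclass
class PooledEstimate:
    qbar: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    ci95: tuple
    df_rubin: float
    m: int
    warning: str | None = None


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Pool m point estimates and their sampling variances.

    With m = 1 the single estimate is returned, the between-imputation
    variance is undefined (NaN) and a warning is attached.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    if (u < 0).any():
        raise ValueError("variances must be non-negative")
    m = len(q)
    qbar = float(q.mean())
    ubar = float(u.mean())
    if m == 1:
        se = math.sqrt(ubar)
        ci = (qbar - 1.959964 * se, qbar + 1.959964 * se)
        return PooledEstimate(
            qbar, ubar, float("nan"), ubar, se, ci, float("inf"), 1,
            warning="m=1: between-imputation variance not estimable",
        )
    B = float(q.var(ddof=1))
    T = ubar + (1.0 + 1.0 / m) * B
    se = math.sqrt(T)
    if B > 0:
        ratio = ubar / ((1.0 + 1.0 / m) * B)
        df = (m - 1) * (1.0 + ratio) ** 2 if ratio < 1e100 else float("inf")
        tcrit = stats.t.ppf(0.975, df) if np.isfinite(df) else 1.959964
    else:
        df = float("inf")
        tcrit = 1.959964
    ci = (qbar - tcrit * se, qbar + tcrit * se)
    return PooledEstimate(qbar, ubar, B, T, se, ci, float(df), m)


def d2_pool_chisq(chi2s, df: int):
    """Combine m chi-square statistics (common df = k) into an F statistic.

    Returns ``(F, df1, df2, p)``.  When the statistics agree exactly the
    replication variance r is zero and the limit F = dbar/k with an
    infinite denominator df (chi-square/k reference) applies.
    """
    d = np.asarray(chi2s, dtype=float)
    if (d < 0).any():
        raise ValueError("chi-square statistics must be non-negative")
    k = int(df)
    if k < 1:
        raise ValueError("df must be >= 1")
    m = len(d)
    if m < 2:
        raise ValueError("D2 pooling needs m >= 2 statistics")
    dbar = float(d.mean())
    r = (1.0 + 1.0 / m) * float(np.sqrt(d).var(ddof=1))
    if r <= 0:
        F = dbar / k
        return float(F), k, float("inf"), float(stats.chi2.sf(dbar, k))
    F = (dbar / k - (m + 1.0) / (m - 1.0) * r) / (1.0 + r)
    df2 = k ** (-3.0 / m) * (m - 1.0) * (1.0 + 1.0 / r) ** 2
    p = float(stats.f.sf(F, k, df2)) if F > 0 else 1.0
    return float(F), k, float(df2), p


def mediation_decompose(
    a: float,
    b: float,
    c_prime: float,
    indirect_ci=None,
    total_ci=None,
    pm_ci_method: str = "ratio",
    indirect_var: float | None = None,
    total_var: float | None = None,
) -> dict:
    """Product-of-coefficients decomposition for one mediator.

    ``pm`` is the percentage mediated, 100 * (a*b) / (a*b + c').  It is
    reported only when the indirect and total effects share sign;
    otherwise the row is flagged ``inconsistent_mediation`` and ``pm`` is
    NaN.  PM interval: ``"ratio"`` maps the endpoint pairs of the indirect
    and total intervals (approximate), ``"delta"`` uses a first-order
    variance expansion.
    """
    for v in (a, b, c_prime):
        if not np.isfinite(v):
            raise ValueError("mediation inputs must be finite")
    indirect = a * b
    total = indirect + c_prime
    row = {
        "a": a,
        "b": b,
        "c_prime": c_prime,
        "indirect": indirect,
        "total": total,
        "pm": float("nan"),
        "pm_ci": (float("nan"), float("nan")),
        "flag": None,
    }
    if total == 0:
        row["flag"] = "total_effect_zero"
        return row
    if indirect != 0 and np.sign(indirect) != np.sign(total):
        row["flag"] = "inconsistent_mediation"
        return row
    row["pm"] = 100.0 * indirect / total
    if pm_ci_method == "ratio" and indirect_ci is not None and total_ci is not None:
        ends = [
            100.0 * i / t for i, t in zip(indirect_ci, total_ci) if t != 0
        ]
        if len(ends) == 2:
            row["pm_ci"] = (min(ends), max(ends))
            row["flag"] = row["flag"] or "pm_ci_approximate"
    elif pm_ci_method == "delta" and indirect_var is not None and total_var is not None:
        # cov(I, T) = cov(I, I + C) ~ var(I) to first order
        var_pm = (
            (1.0 / total) ** 2 * indirect_var
            + (indirect / total**2) ** 2 * total_var
            - 2.0 * indirect / total**3 * indirect_var
        ) * 100.0**2
        half = 1.959964 * math.sqrt(max(var_pm, 0.0))
        row["pm_ci"] = (row["pm"] - half, row["pm"] + half)
        row["flag"] = row["flag"] or "pm_ci_delta"
    return row


#: Pre-specified anticipation order of the mediators.
MEDIATOR_ORDER = ["sqi", "wasd", "msf", "sjl"]


def pooled_mediation_report(
    fits,
    mediators=("sqi", "wasd", "msf"),
    groups=None,
    predictor: str = "screen",
    outcome: str = "g",
    max_nonconverged: float = 0.10,
    pm_ci_method: str = "ratio",
) -> pd.DataFrame:
    """Mediation table pooled over m imputed-model fits.

    For each group x mediator: the raw A-path, B-path and c' are pooled by
    Rubin's rules; the indirect effect is computed within each imputation
    (delta-method variance) and pooled; PM comes from the pooled raw
    coefficients.  Fully standardized (std.all) twins of the coefficients
    are pooled alongside as point estimates.  Non-converged fits are
    excluded (hard error beyond ``max_nonconverged``).
    """
    from .sem import standardize

    fits = list(fits)
    ok = [f for f in fits if f.converged]
    n_bad = len(fits) - len(ok)
    if n_bad > max_nonconverged * len(fits):
        raise RuntimeError(
            f"{n_bad}/{len(fits)} fits non-converged (> {max_nonconverged:.0%})"
        )
    if not ok:
        raise RuntimeError("no converged fits to pool")
    groups = list(groups or ok[0].spec.groups)
    med_sorted = sorted(
        mediators,
        key=lambda x: MEDIATOR_ORDER.index(x) if x in MEDIATOR_ORDER else 99,
    )
    std_tabs = [standardize(f) for f in ok]

    rows = []
    for g in groups:
        for med in med_sorted:
            a = np.array([f.param("beta", med, predictor, g) for f in ok])
            a_se = np.array([f.param("beta", med, predictor, g, "se") for f in ok])
            b = np.array([f.param("beta", outcome, med, g) for f in ok])
            b_se = np.array([f.param("beta", outcome, med, g, "se") for f in ok])
            c = np.array([f.param("beta", outcome, predictor, g) for f in ok])
            c_se = np.array([f.param("beta", outcome, predictor, g, "se") for f in ok])

            pa = rubin_pool(a, a_se**2)
            pb = rubin_pool(b, b_se**2)
            pc = rubin_pool(c, c_se**2)
            ind = a * b
            ind_var = b**2 * a_se**2 + a**2 * b_se**2
            p_ind = rubin_pool(ind, ind_var)
            tot = ind + c
            tot_var = ind_var + c_se**2
            p_tot = rubin_pool(tot, tot_var)

            dec = mediation_decompose(
                pa.qbar,
                pb.qbar,
                pc.qbar,
                indirect_ci=p_ind.ci95,
                total_ci=p_tot.ci95,
                pm_ci_method=pm_ci_method,
                indirect_var=p_ind.total_var,
                total_var=p_tot.total_var,
            )

            def _std(tab, mat, r, cc):
                sel = tab[
                    (tab.matrix == mat)
                    & (tab.row == r)
                    & (tab.col == cc)
                    & (tab.group == g)
                ]
                return float(sel["std"].iloc[0])

            sa = np.mean([_std(t, "beta", med, predictor) for t in std_tabs])
            sb = np.mean([_std(t, "beta", outcome, med) for t in std_tabs])
            sc = np.mean([_std(t, "beta", outcome, predictor) for t in std_tabs])
            s_ind = sa * sb
            s_tot = s_ind + sc
            s_pm = 100.0 * s_ind / s_tot if s_tot != 0 and (
                s_ind == 0 or np.sign(s_ind) == np.sign(s_tot)
            ) else float("nan")

            rows.append(
                {
                    "group": g,
                    "mediator": med,
                    "a": pa.qbar,
                    "a_se": pa.se,
                    "b": pb.qbar,
                    "b_se": pb.se,
                    "c_prime": pc.qbar,
                    "c_se": pc.se,
                    "indirect": p_ind.qbar,
                    "indirect_ci_lo": p_ind.ci95[0],
                    "indirect_ci_hi": p_ind.ci95[1],
                    "total": p_tot.qbar,
                    "total_ci_lo": p_tot.ci95[0],
                    "total_ci_hi": p_tot.ci95[1],
                    "pm": dec["pm"],
                    "pm_ci_lo": dec["pm_ci"][0],
                    "pm_ci_hi": dec["pm_ci"][1],
                    "flag": dec["flag"],
                    "std_a": sa,
                    "std_b": sb,
                    "std_c_prime": sc,
                    "std_indirect": s_ind,
                    "std_total": s_tot,
                    "std_pm": s_pm,
                    "n_fits_pooled": len(ok),
                    "n_fits_excluded": n_bad,
                }
            )
    return pd.DataFrame(rows)
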