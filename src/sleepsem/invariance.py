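"""Measurement-invariance testing across groups, pooled over imputations.

The ladder runs configural (same structure, all parameters group-specific)
-> metric/weak (equal loadings; factor variances freed in the non-reference
groups) -> scalar/strong (equal loadings and intercepts; latent means freed
in the non-reference groups).  Each successive nested comparison is pooled
over the m imputations with the D2 chi-square combination.  When a rung is
rejected, a greedy partial-invariance search releases the single
constrained parameter whose release most improves fit (scored by an exact
single-release refit, a modification-index analogue) and re-tests, bounded
at 5 freed parameters overall.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pooling import d2_pool_chisq
from .sem import SemSpec, fit

__all__ = ["constrain_level", "invariance_ladder"]

LEVELS = ("configural", "metric", "scalar")


def _loading_slots(spec: SemSpec):
    out = []
    for f, inds in spec.factors.items():
        if f in spec.manifests:
            continue
        for ind in inds:
            slot = spec.slot("lam", ind, f, spec.groups[0])
            if slot is not None and slot.free:
                out.append(("lam", ind, f))
    return out


def _intercept_slots(spec: SemSpec):
    out = []
    for v in spec.observed:
        slot = spec.slot("nu", v, "", spec.groups[0])
        if slot is not None and slot.free:
            out.append(("nu", v, ""))
    return out


def constrain_level(spec: SemSpec, level: str, freed=()) -> SemSpec:
    """Return a copy of ``spec`` constrained to an invariance level.

    ``freed`` lists parameter identifiers exempted from cross-group
    equality (partial invariance): ``("lam", indicator, factor)`` or
    ``("nu", indicator, "")``.  The returned spec is nested in the input.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown invariance level {level!r}")
    out = spec.copy()
    if level == "configural":
        if freed:
            raise ValueError("configural level admits no freed parameters")
        return out
    freed = {tuple(f) for f in freed}
    constrained = set(_loading_slots(out))
    if level == "scalar":
        constrained |= set(_intercept_slots(out))
    unknown = freed - constrained
    if unknown:
        raise ValueError(
            f"freed parameters not constrained at level {level!r}: {sorted(unknown)}"
        )
    for mat, row, col in sorted(constrained - freed):
        out.constrain_equal(mat, row, col)
    # with loadings equal, factor scale may differ: free the (residual)
    # variance in non-reference groups
    for f in out.factors:
        if f in out.manifests:
            continue
        for g in out.groups[1:]:
            out.set_parameter("psi", f, f, group=g, free=True, value=1.0)
    if level == "scalar":
        # with intercepts equal, latent means may differ
        for f in out.factors:
            if f in out.manifests:
                continue
            for g in out.groups[1:]:
                out.set_parameter("alpha", f, "", group=g, free=True, value=0.0)
    return out


def invariance_ladder(
    imputed_tables,
    spec: SemSpec,
    group_col: str = "gender",
    alpha: float = 0.05,
    max_freed: int = 5,
) -> pd.DataFrame:
    """Run the configural -> metric -> scalar ladder on m imputed tables.

    Returns one row per tested comparison with the D2-pooled F statistic,
    reference dfs and p-value; on rejection, parameters freed by the
    greedy partial-invariance search are listed in ``freed``.  A rung that
    cannot be fitted (non-convergence) or refined (no identifiable partial
    model) is recorded with a reason rather than raising.
    """
    tables = list(imputed_tables)
    if len(tables) < 2:
        raise ValueError("invariance pooling needs >= 2 imputations")

    def fit_all(s):
        fits = []
        for t in tables:
            f = fit(s, data=t, group_col=group_col, se=False)
            if not f.converged:
                return None, f.warnings
            fits.append(f)
        return fits, None

    rows = []
    freed_total: list[tuple] = []
    prev_spec = constrain_level(spec, "configural")
    prev_fits, err = fit_all(prev_spec)
    if prev_fits is None:
        return pd.DataFrame(
            [{"comparison": "configural", "skipped": True, "reason": str(err)}]
        )

    for level in ("metric", "scalar"):
        freed_level: list[tuple] = []
        while True:
            cur_spec = constrain_level(spec, level, freed=freed_total + freed_level)
            cur_fits, err = fit_all(cur_spec)
            label = f"{level} vs " + (
                "configural" if level == "metric" else "metric"
            )
            if freed_level or (level == "scalar" and freed_total):
                label = "partial " + label
            if cur_fits is None:
                rows.append(
                    {
                        "comparison": label,
                        "skipped": True,
                        "reason": f"non-convergence: {err}",
                    }
                )
                cur_fits, cur_spec = prev_fits, prev_spec
                break
            dchi = np.array([c.chi2 - p.chi2 for c, p in zip(cur_fits, prev_fits)])
            ddf = cur_fits[0].df - prev_fits[0].df
            if ddf <= 0:
                rows.append(
                    {
                        "comparison": label,
                        "skipped": True,
                        "reason": "partial invariance not estimable "
                        "(too few constrained parameters remain)",
                    }
                )
                cur_fits, cur_spec = prev_fits, prev_spec
                break
            if (dchi < -1e-6 * max(abs(prev_fits[0].chi2), 1.0) - 1e-2).any():
                raise RuntimeError("ladder not nested: chi-square decreased")
            F, df1, df2, p = d2_pool_chisq(np.clip(dchi, 0, None), ddf)
            row = {
                "comparison": label,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "freed": list(freed_total + freed_level),
                "skipped": False,
                "reason": None,
            }
            if p >= alpha or len(freed_total) + len(freed_level) >= max_freed:
                rows.append(row)
                break
            rows.append({**row, "comparison": label + " (rejected)"})
            # release the constrained parameter whose freeing most improves
            # fit, scored by exact single-release refits on the first table
            candidates = (
                _loading_slots(spec) if level == "metric" else _intercept_slots(spec)
            )
            candidates = [
                c for c in candidates if c not in freed_total + freed_level
            ]
            best, best_gain = None, -np.inf
            for cand in sorted(candidates):
                cand_spec = constrain_level(
                    spec, level, freed=freed_total + freed_level + [cand]
                )
                cand_fit = fit(
                    cand_spec, data=tables[0], group_col=group_col, se=False
                )
                if not cand_fit.converged:
                    continue
                if cand_fit.df - prev_fits[0].df <= 0:
                    continue  # would leave nothing to test
                gain = cur_fits[0].chi2 - cand_fit.chi2
                if gain > best_gain:
                    best, best_gain = cand, gain
            if best is None:
                rows[-1]["comparison"] = label + " (partial not estimable)"
                break
            freed_level.append(best)
        freed_total += freed_level
        prev_spec, prev_fits = cur_spec, cur_fits

    return pd.DataFrame(rows)
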