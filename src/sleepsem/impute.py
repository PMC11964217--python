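"""Multiple imputation by chained equations with predictive mean matching.

Each incomplete variable is regressed on all others among its observed
rows; the coefficients are perturbed by a draw from their posterior
(Bayesian, "type-1" matching), predictions for missing rows are matched to
the ``k`` observed rows with nearest (unperturbed) predictions, and the
imputed value is drawn uniformly among those donors' *observed* values --
so imputations are always members of the observed support (ordinal items
stay in range with no rounding rule).  The chained sweeps visit variables
in ascending order of missingness; the whole procedure is repeated ``m``
times on independent RNG substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ImputationSet", "pmm_impute_variable", "chained_impute"]

DEFAULT_K = 5
DEFAULT_ITERS = 5


@dataclass
class ImputationSet:
    """m completed copies of an input table, identical to it on every
    observed cell."""

    completed_tables: list
    m: int
    k_donors: int
    n_iterations: int
    seed: int
    visit_sequence: list
    missing_fraction: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "m": self.m,
            "k_donors": self.k_donors,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "visit_sequence": list(self.visit_sequence),
            "missing_fraction": dict(self.missing_fraction),
            "predictor_matrix": "all-variables-predict-all",
        }


def pmm_impute_variable(
    target: np.ndarray,
    predictors: np.ndarray,
    k: int = DEFAULT_K,
    rng: np.random.Generator | None = None,
    bayes: bool = True,
) -> np.ndarray:
    """Impute the missing entries of ``target`` by predictive mean matching.

    ``predictors`` must be complete (n x p, no intercept column; one is
    added).  With ``bayes=False`` the coefficient perturbation is disabled
    (useful for deterministic toy checks).  Donor-distance ties are broken
    by an RNG draw, not row order.
    """
    rng = rng or np.random.default_rng()
    y = np.asarray(target, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(predictors, dtype=float)])
    if np.isnan(X).any():
        raise ValueError("predictors must be complete")
    obs = ~np.isnan(y)
    mis = ~obs
    if not mis.any():
        return y.copy()
    n_obs = int(obs.sum())
    p = X.shape[1]
    if n_obs < p + 2:
        raise ValueError(
            f"rank deficiency: {n_obs} observed rows for {p} regression "
            "coefficients (need at least p + 2)"
        )
    if n_obs < k:
        raise ValueError(f"fewer observed values ({n_obs}) than donors k={k}")

    Xo, yo = X[obs], y[obs]
    beta_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    yhat_obs = Xo @ beta_hat

    if bayes:
        resid = yo - yhat_obs
        dof = max(n_obs - p, 1)
        sigma2_star = resid @ resid / rng.chisquare(dof)
        xtx = Xo.T @ Xo
        # ridge against collinear predictors (ordinal items can be near-collinear)
        xtx += np.eye(p) * 1e-8 * np.trace(xtx) / p
        try:
            L = np.linalg.cholesky(np.linalg.inv(xtx))
            beta_star = beta_hat + np.sqrt(sigma2_star) * (L @ rng.standard_normal(p))
        except np.linalg.LinAlgError:
            beta_star = beta_hat
    else:
        beta_star = beta_hat

    yhat_mis = X[mis] @ beta_star
    out = y.copy()
    mis_ix = np.flatnonzero(mis)
    kk = min(k, n_obs)
    # the k nearest observed predictions lie inside a window of width 2k
    # around each missing prediction's insertion point in the sorted
    # observed predictions; search only that window (vectorized)
    order = np.argsort(yhat_obs, kind="stable")
    ys, yvals = yhat_obs[order], yo[order]
    w = min(2 * kk, n_obs)
    pos = np.searchsorted(ys, yhat_mis)
    start = np.clip(pos - kk, 0, n_obs - w)
    cand = start[:, None] + np.arange(w)[None, :]
    d = np.abs(ys[cand] - yhat_mis[:, None])
    # break donor-distance ties by RNG, not row order: shuffle candidate
    # columns before the partial sort
    perm = rng.permutation(w)
    cand, d = cand[:, perm], d[:, perm]
    if w > kk:
        nearest = np.argpartition(d, kk - 1, axis=1)[:, :kk]
    else:
        nearest = np.tile(np.arange(w), (len(mis_ix), 1))
    pick = nearest[np.arange(len(mis_ix)), rng.integers(kk, size=len(mis_ix))]
    out[mis_ix] = yvals[cand[np.arange(len(mis_ix)), pick]]
    return out


def chained_impute(
    panel: pd.DataFrame,
    m: int = 5,
    iters: int = DEFAULT_ITERS,
    k: int = DEFAULT_K,
    seed: int = 0,
    columns: list | None = None,
    predictors_extra: list | None = None,
) -> ImputationSet:
    """MICE-PMM over the numeric columns of ``panel``.

    ``columns`` restricts which variables are imputed (default: every
    numeric column containing missing values); ``predictors_extra`` names
    complete numeric columns used as predictors only.  Gender is encoded
    0/1 and always used as a predictor when present.  Observed cells are
    never altered.
    """
    work = panel.copy()
    numeric = work.select_dtypes(include=[np.number]).columns.tolist()
    numeric = [c for c in numeric if not c.startswith("latent_") and c != "person_id"]
    if columns is None:
        columns = [c for c in numeric if work[c].isna().any()]
    else:
        columns = list(columns)
    for c in columns:
        if work[c].notna().sum() == 0:
            raise ValueError(f"unimputable variable (fully missing): {c}")

    pred_cols = list(dict.fromkeys(columns + (predictors_extra or [])))
    aux = {}
    if "gender" in work.columns:
        aux["_girl"] = (work["gender"] == "girl").astype(float).to_numpy()

    miss_frac = {c: float(work[c].isna().mean()) for c in columns}
    visit = sorted(columns, key=lambda c: (miss_frac[c], c))

    base = {c: work[c].to_numpy(dtype=float) for c in pred_cols}
    base.update(aux)
    mask = {c: np.isnan(base[c]) for c in columns}

    ss = np.random.SeedSequence(int(seed))
    completed = []
    for child in ss.spawn(m):
        rng = np.random.default_rng(child)
        cur = {c: v.copy() for c, v in base.items()}
        # initialize missing cells from random observed draws
        for c in columns:
            obs_vals = base[c][~mask[c]]
            nm = int(mask[c].sum())
            if nm:
                cur[c][mask[c]] = rng.choice(obs_vals, size=nm, replace=True)
        for _ in range(iters):
            for c in visit:
                if not mask[c].any():
                    continue
                y = base[c].copy()  # observed values + NaN holes
                preds = [cur[o] for o in cur if o != c]
                filled = pmm_impute_variable(
                    y, np.column_stack(preds), k=k, rng=rng
                )
                cur[c] = filled
        out = work.copy()
        for c in columns:
            out[c] = cur[c]
        completed.append(out)

    return ImputationSet(
        completed_tables=completed,
        m=m,
        k_donors=k,
        n_iterations=iters,
        seed=int(seed),
        visit_sequence=visit,
        missing_fraction=miss_frac,
    )
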