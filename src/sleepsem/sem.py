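"""Multigroup maximum-likelihood structural equation modelling.

A small, self-contained SEM engine in the all-y LISREL form.  For each
group g the model-implied moments are

    Sigma_g = Lam (I - B)^-1 Psi (I - B)^-T Lam^T + Theta
    mu_g    = nu + Lam (I - B)^-1 alpha

where ``Lam`` maps structural nodes (latent factors and manifest variables
promoted to single-indicator nodes) onto observed indicators, ``B`` holds
directed structural paths, ``Psi`` the (residual) covariances of the
structural nodes, ``Theta`` the unique variances, ``nu`` indicator
intercepts and ``alpha`` structural means.  The normal-theory discrepancy

    F_g = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p + (xbar-mu)' Sigma^-1 (xbar-mu)

is minimised over the free parameters (weighted n_g/N across groups) by
L-BFGS-B with analytic gradients; chi-square = sum_g n_g F_g at the
optimum.  Identification follows the fixed-variance convention (each
latent's (residual) variance fixed to 1) unless a loading is fixed
instead.  Standard errors come from the inverse observed information.

Ordinal items are treated as continuous at fit time; the chi-square is the
plain normal-theory statistic (no robust scaling correction).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats

__all__ = [
    "SemSpec",
    "GroupMoments",
    "FitResult",
    "moments_from_data",
    "implied_moments",
    "ml_discrepancy",
    "fit",
    "standardize",
    "fit_indices",
    "srmr",
    "reliability",
    "chisq_diff",
]

_MATRICES = ("lam", "beta", "psi", "theta", "nu", "alpha")
_SYMMETRIC = {"psi", "theta"}
_PENALTY = 1e12


# ----------------------------------------------------------------------
# specification


@dataclass
class _Slot:
    free: bool
    value: float  # fixed value, or start hint (nan = derive from data)
    label: str | None = None


class SemSpec:
    """Declarative multigroup model specification.

    Build with :meth:`add_factor`, :meth:`add_manifest`,
    :meth:`add_regression` and :meth:`add_covariance`; impose cross-group
    equality with :meth:`constrain_equal`.  Slots never mentioned are fixed
    at zero.
    """

    def __init__(self, groups=("all",)):
        self.groups = [str(g) for g in groups]
        self.observed: list[str] = []
        self.eta: list[str] = []
        self.factors: dict[str, list[str]] = {}
        self.manifests: set[str] = set()
        self._slots: dict[tuple, _Slot] = {}

    # -- construction ---------------------------------------------------
    def _set(self, mat, row, col, group, free, value, label=None):
        if mat in _SYMMETRIC and row != col:
            # canonical order for symmetric entries
            ia, ib = self._index(mat, row, col)
            if ia > ib:
                row, col = col, row
        self._slots[(mat, row, col, group)] = _Slot(free, float(value), label)

    def _index(self, mat, row, col):
        if mat == "psi":
            return self.eta.index(row), self.eta.index(col)
        if mat == "theta":
            return self.observed.index(row), self.observed.index(col)
        raise AssertionError(mat)

    def _register_observed(self, name):
        if name not in self.observed:
            self.observed.append(name)
            for g in self.groups:
                self._slots[("theta", name, name, g)] = _Slot(True, np.nan)
                self._slots[("nu", name, "", g)] = _Slot(True, np.nan)

    def add_factor(self, name, indicators, variance=1.0, loadings="free"):
        """Add a latent factor.  ``variance`` is a fixed value or "free"
        (then fix a loading yourself); ``loadings`` is "free" or a sequence
        of fixed values / None-for-free per indicator."""
        if name in self.eta:
            raise ValueError(f"duplicate structural node {name!r}")
        self.eta.append(name)
        self.factors[name] = list(indicators)
        for ind in indicators:
            self._register_observed(ind)
        for j, ind in enumerate(indicators):
            for g in self.groups:
                if loadings == "free":
                    self._slots[("lam", ind, name, g)] = _Slot(True, np.nan)
                else:
                    lv = loadings[j]
                    if lv is None:
                        self._slots[("lam", ind, name, g)] = _Slot(True, np.nan)
                    else:
                        self._slots[("lam", ind, name, g)] = _Slot(False, float(lv))
        for g in self.groups:
            if variance == "free":
                self._slots[("psi", name, name, g)] = _Slot(True, 1.0)
            else:
                self._slots[("psi", name, name, g)] = _Slot(False, float(variance))
        return self

    def add_manifest(self, name):
        """Promote an observed variable to a structural node (loading fixed
        1, zero uniqueness, free residual variance and mean)."""
        if name in self.eta:
            raise ValueError(f"duplicate structural node {name!r}")
        self.eta.append(name)
        self.factors[name] = [name]
        self.manifests.add(name)
        if name not in self.observed:
            self.observed.append(name)
        for g in self.groups:
            self._slots[("lam", name, name, g)] = _Slot(False, 1.0)
            self._slots[("theta", name, name, g)] = _Slot(False, 0.0)
            self._slots[("nu", name, "", g)] = _Slot(False, 0.0)
            self._slots[("psi", name, name, g)] = _Slot(True, np.nan)
            self._slots[("alpha", name, "", g)] = _Slot(True, np.nan)
        return self

    def add_regression(self, target, source, free=True, value=0.0, groups=None):
        for g in groups or self.groups:
            self._slots[("beta", target, source, g)] = _Slot(free, value)
        return self

    def add_covariance(self, a, b, free=True, value=0.0, groups=None):
        for g in groups or self.groups:
            self._set("psi", a, b, g, free, value)
        return self

    def set_parameter(self, mat, row, col, *, group=None, free, value, label=None):
        for g in [group] if group else self.groups:
            self._set(mat, row, col, g, free, value, label)
        return self

    def constrain_equal(self, mat, row, col, label=None):
        """Force one parameter slot equal across all groups."""
        if mat in _SYMMETRIC and row != col:
            ia, ib = self._index(mat, row, col)
            if ia > ib:
                row, col = col, row
        label = label or f"eq_{mat}_{row}_{col}"
        for g in self.groups:
            slot = self._slots.get((mat, row, col, g))
            if slot is None or not slot.free:
                raise ValueError(f"cannot constrain non-free slot {(mat, row, col, g)}")
            slot.label = label
        return self

    def slot(self, mat, row, col, group):
        if mat in _SYMMETRIC and row != col:
            ia, ib = self._index(mat, row, col)
            if ia > ib:
                row, col = col, row
        return self._slots.get((mat, row, col, group))

    def copy(self) -> "SemSpec":
        return copy.deepcopy(self)

    # -- validation -----------------------------------------------------
    def _scaled(self, f, g, seen=()):
        """A node's scale is set by a fixed variance, a fixed loading, or a
        cross-group equality-constrained loading shared with a scaled
        group (as in metric-invariance models)."""
        var_slot = self._slots.get(("psi", f, f, g))
        if var_slot is not None and not var_slot.free:
            return True
        lam_slots = [
            (k, s)
            for k, s in self._slots.items()
            if k[0] == "lam" and k[2] == f and k[3] == g
        ]
        if any(not s.free for _, s in lam_slots):
            return True
        for (m, r, c, gg), s in lam_slots:
            if s.label is None:
                continue
            for g2 in self.groups:
                if g2 == g or g2 in seen:
                    continue
                s2 = self._slots.get(("lam", r, c, g2))
                if s2 is not None and s2.label == s.label and self._scaled(
                    f, g2, seen + (g,)
                ):
                    return True
        return False

    def validate(self):
        for f in self.eta:
            for g in self.groups:
                if not self._scaled(f, g):
                    raise ValueError(
                        f"node {f!r} (group {g!r}) needs a scaling rule: "
                        "fixed variance or one fixed loading"
                    )

    # -- parameter table ------------------------------------------------
    def param_slots(self):
        """Deterministically ordered list of (mat, row, col, group, slot)."""
        out = []
        for mat in _MATRICES:
            if mat == "lam":
                keys = [
                    (mat, r, c, g)
                    for c in self.eta
                    for r in self.observed
                    for g in self.groups
                    if (mat, r, c, g) in self._slots
                ]
            elif mat == "beta":
                keys = [
                    (mat, r, c, g)
                    for r in self.eta
                    for c in self.eta
                    for g in self.groups
                    if (mat, r, c, g) in self._slots
                ]
            elif mat == "psi":
                keys = [
                    (mat, r, c, g)
                    for i, r in enumerate(self.eta)
                    for c in self.eta[i:]
                    for g in self.groups
                    if (mat, r, c, g) in self._slots
                ]
            elif mat == "theta":
                keys = [
                    (mat, r, c, g)
                    for i, r in enumerate(self.observed)
                    for c in self.observed[i:]
                    for g in self.groups
                    if (mat, r, c, g) in self._slots
                ]
            else:
                names = self.observed if mat == "nu" else self.eta
                keys = [
                    (mat, r, "", g)
                    for r in names
                    for g in self.groups
                    if (mat, r, "", g) in self._slots
                ]
            out.extend([k + (self._slots[k],) for k in keys])
        return out

    def n_free(self) -> int:
        labels = set()
        n = 0
        for *_, slot in self.param_slots():
            if slot.free:
                if slot.label is None:
                    n += 1
                elif slot.label not in labels:
                    labels.add(slot.label)
                    n += 1
        return n

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "observed": self.observed,
            "eta": self.eta,
            "factors": self.factors,
            "manifests": sorted(self.manifests),
            "slots": [
                {
                    "matrix": m,
                    "row": r,
                    "col": c,
                    "group": g,
                    "free": s.free,
                    "value": None if np.isnan(s.value) else s.value,
                    "label": s.label,
                }
                for (m, r, c, g), s in sorted(self._slots.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SemSpec":
        spec = cls(d["groups"])
        spec.observed = list(d["observed"])
        spec.eta = list(d["eta"])
        spec.factors = {k: list(v) for k, v in d["factors"].items()}
        spec.manifests = set(d.get("manifests", []))
        for s in d["slots"]:
            spec._slots[(s["matrix"], s["row"], s["col"], s["group"])] = _Slot(
                s["free"],
                np.nan if s["value"] is None else float(s["value"]),
                s.get("label"),
            )
        return spec


# ----------------------------------------------------------------------
# moments


@dataclass
class GroupMoments:
    S: np.ndarray
    mean: np.ndarray
    n: int


def moments_from_data(
    data: pd.DataFrame, observed, groups, group_col="gender", ddof=0
) -> dict[str, GroupMoments]:
    """Listwise-complete sample moments per group (ML denominator n by
    default)."""
    out = {}
    for g in groups:
        sub = data.loc[data[group_col] == g, list(observed)].dropna()
        X = sub.to_numpy(dtype=float)
        n = X.shape[0]
        if n <= len(observed):
            raise ValueError(f"group {g!r}: n={n} <= p={len(observed)}")
        xbar = X.mean(axis=0)
        Xc = X - xbar
        S = Xc.T @ Xc / (n - ddof)
        out[g] = GroupMoments(S=S, mean=xbar, n=n)
    return out


# ----------------------------------------------------------------------
# compiled model


class _Compiled:
    def __init__(self, spec: SemSpec):
        spec.validate()
        self.spec = spec
        self.p = len(spec.observed)
        self.q = len(spec.eta)
        self.obs_ix = {v: i for i, v in enumerate(spec.observed)}
        self.eta_ix = {v: i for i, v in enumerate(spec.eta)}
        self.slots = spec.param_slots()

        # map free slots -> theta indices (labels share one index)
        self.free_map = []  # (mat, i, j, group_index, theta_index)
        label_ix: dict[str, int] = {}
        self.theta_labels: list[str] = []
        k = 0
        self.start_hints = []
        for mat, r, c, g, slot in self.slots:
            if not slot.free:
                continue
            gi = spec.groups.index(g)
            if slot.label is not None and slot.label in label_ix:
                idx = label_ix[slot.label]
            else:
                idx = k
                if slot.label is not None:
                    label_ix[slot.label] = idx
                self.theta_labels.append(slot.label or f"{mat}[{r},{c}]@{g}")
                self.start_hints.append((mat, r, c, g, slot.value))
                k += 1
            i, j = self._ij(mat, r, c)
            self.free_map.append((mat, i, j, gi, idx))
        self.n_free = k

        # fixed bases per group
        G = len(spec.groups)
        self.base = {
            "lam": np.zeros((G, self.p, self.q)),
            "beta": np.zeros((G, self.q, self.q)),
            "psi": np.zeros((G, self.q, self.q)),
            "theta": np.zeros((G, self.p, self.p)),
            "nu": np.zeros((G, self.p)),
            "alpha": np.zeros((G, self.q)),
        }
        for mat, r, c, g, slot in self.slots:
            if slot.free:
                continue
            gi = spec.groups.index(g)
            i, j = self._ij(mat, r, c)
            if mat in ("nu", "alpha"):
                self.base[mat][gi, i] = slot.value
            else:
                self.base[mat][gi, i, j] = slot.value
                if mat in _SYMMETRIC:
                    self.base[mat][gi, j, i] = slot.value

    def _ij(self, mat, r, c):
        if mat == "lam":
            return self.obs_ix[r], self.eta_ix[c]
        if mat == "beta":
            return self.eta_ix[r], self.eta_ix[c]
        if mat == "psi":
            return self.eta_ix[r], self.eta_ix[c]
        if mat == "theta":
            return self.obs_ix[r], self.obs_ix[c]
        if mat == "nu":
            return self.obs_ix[r], 0
        return self.eta_ix[r], 0

    # -- parameter -> matrices -----------------------------------------
    def matrices(self, theta, gi):
        mats = {m: self.base[m][gi].copy() for m in _MATRICES}
        for mat, i, j, g2, idx in self.free_map:
            if g2 != gi:
                continue
            v = theta[idx]
            if mat in ("nu", "alpha"):
                mats[mat][i] = v
            else:
                mats[mat][i, j] = v
                if mat in _SYMMETRIC:
                    mats[mat][j, i] = v
        return mats

    def implied(self, theta, gi):
        m = self.matrices(theta, gi)
        I = np.eye(self.q)
        try:
            A = np.linalg.solve(I - m["beta"], I)
        except np.linalg.LinAlgError as exc:
            raise ValueError("non-recursive model: (I - B) is singular") from exc
        M = m["lam"] @ A
        Sigma = M @ m["psi"] @ M.T + m["theta"]
        mu = m["nu"] + M @ m["alpha"]
        return Sigma, mu, m, A, M

    # -- discrepancy + gradient ----------------------------------------
    def value_grad(self, theta, moments, want_grad=True):
        spec = self.spec
        total = 0.0
        grad = np.zeros(self.n_free) if want_grad else None
        N = sum(moments[g].n for g in spec.groups)
        for gi, g in enumerate(spec.groups):
            mo = moments[g]
            w = mo.n / N
            Sigma, mu, m, A, M = self.implied(theta, gi)
            try:
                cF = sla.cho_factor(Sigma, lower=True, check_finite=False)
            except (sla.LinAlgError, ValueError):
                return _PENALTY, (np.zeros(self.n_free) if want_grad else None)
            logdet_sigma = 2.0 * np.log(np.diag(cF[0])).sum()
            iS = sla.cho_solve(cF, np.eye(self.p), check_finite=False)
            sign, logdet_s = np.linalg.slogdet(mo.S)
            if sign <= 0:
                raise ValueError("sample covariance is not positive definite")
            d = mo.mean - mu
            Fg = (
                logdet_sigma
                - logdet_s
                + float(np.sum(iS * mo.S))
                - self.p
                + float(d @ iS @ d)
            )
            total += w * Fg
            if not want_grad:
                continue
            Gm = iS - iS @ (mo.S + np.outer(d, d)) @ iS
            g_mu = -2.0 * (iS @ d)
            dM = 2.0 * Gm @ M @ m["psi"] + np.outer(g_mu, m["alpha"])
            dmats = {
                "theta": Gm,
                "psi": M.T @ Gm @ M,
                "lam": dM @ A.T,
                "beta": A.T @ m["lam"].T @ dM @ A.T,
                "nu": g_mu,
                "alpha": M.T @ g_mu,
            }
            for mat, i, j, g2, idx in self.free_map:
                if g2 != gi:
                    continue
                if mat in ("nu", "alpha"):
                    gval = dmats[mat][i]
                elif mat in _SYMMETRIC and i != j:
                    gval = 2.0 * dmats[mat][i, j]
                else:
                    gval = dmats[mat][i, j]
                grad[idx] += w * gval
        return total, grad

    # -- start values ---------------------------------------------------
    def start(self, moments):
        spec = self.spec
        theta0 = np.empty(self.n_free)
        # count how many factors load each indicator (bifactor start damping)
        nfac = {v: 0 for v in spec.observed}
        for f, inds in spec.factors.items():
            for v in inds:
                nfac[v] += 1
        # principal-axis loadings per factor from the pooled covariance
        Gn = sum(moments[g].n for g in spec.groups)
        S_pool = sum(moments[g].n / Gn * moments[g].S for g in spec.groups)
        mean_pool = sum(moments[g].n / Gn * moments[g].mean for g in spec.groups)
        pa = {}
        for f, inds in spec.factors.items():
            ix = [self.obs_ix[v] for v in inds]
            sub = S_pool[np.ix_(ix, ix)]
            if len(ix) == 1:
                pa[f] = {inds[0]: np.sqrt(sub[0, 0])}
                continue
            w, v = np.linalg.eigh(sub)
            lead = v[:, -1] * np.sqrt(max(w[-1], 1e-6))
            if lead.sum() < 0:
                lead = -lead
            pa[f] = {
                ind: lead[k] / np.sqrt(nfac[ind]) for k, ind in enumerate(inds)
            }
        for idx, (mat, r, c, g, hint) in enumerate(self.start_hints):
            if np.isfinite(hint):
                theta0[idx] = hint
                continue
            if mat == "lam":
                theta0[idx] = pa.get(c, {}).get(r, 0.5)
            elif mat == "theta":
                theta0[idx] = 0.5 * S_pool[self.obs_ix[r], self.obs_ix[r]]
            elif mat == "psi":
                if r == c:
                    if r in spec.manifests:
                        theta0[idx] = 0.8 * S_pool[self.obs_ix[r], self.obs_ix[r]]
                    else:
                        theta0[idx] = 0.5
                else:
                    theta0[idx] = 0.0
            elif mat == "beta":
                theta0[idx] = 0.0
            elif mat == "nu":
                theta0[idx] = mean_pool[self.obs_ix[r]]
            else:  # alpha
                theta0[idx] = mean_pool[self.obs_ix[r]] if r in spec.manifests else 0.0
        return theta0


# ----------------------------------------------------------------------
# public operations


def implied_moments(spec: SemSpec, theta=None):
    """Per-group model-implied (Sigma, mu) at ``theta`` (defaults to the
    spec's fixed/start values; free slots with no numeric hint start at
    heuristic defaults only when data are available, so fully-fixed specs
    are evaluated exactly)."""
    comp = _Compiled(spec)
    if theta is None:
        theta = np.array([h if np.isfinite(h) else 0.0 for *_, h in comp.start_hints])
    out = {}
    for gi, g in enumerate(spec.groups):
        Sigma, mu, *_ = comp.implied(np.asarray(theta, dtype=float), gi)
        out[g] = (Sigma, mu)
    return out


def ml_discrepancy(moments: dict[str, GroupMoments], implied) -> float:
    """Normal-theory ML discrepancy, groups weighted by n_g/N."""
    total = 0.0
    N = sum(m.n for m in moments.values())
    for g, mo in moments.items():
        Sigma, mu = implied[g]
        p = Sigma.shape[0]
        sign, logdet_sigma = np.linalg.slogdet(Sigma)
        if sign <= 0:
            raise ValueError("implied covariance is not positive definite")
        _, logdet_s = np.linalg.slogdet(mo.S)
        iS = np.linalg.inv(Sigma)
        d = mo.mean - mu
        Fg = logdet_sigma - logdet_s + float(np.sum(iS * mo.S)) - p + float(d @ iS @ d)
        total += mo.n / N * Fg
    return total


@dataclass
class FitResult:
    """Estimates, test statistic and fit indices of one model fit."""

    spec: SemSpec
    estimates: pd.DataFrame
    theta: np.ndarray
    chi2: float
    df: int
    baseline_chi2: float
    baseline_df: int
    n_per_group: dict
    fmin: float
    converged: bool
    n_iter: int
    grad_norm: float
    rmsea: float | None = None
    srmr: float | None = None
    cfi: float | None = None
    tli: float | None = None
    loglik: float | None = None
    aic: float | None = None
    bic: float | None = None
    warnings: list = field(default_factory=list)
    moments: dict | None = None

    @property
    def N(self):
        return sum(self.n_per_group.values())

    def param(self, mat, row, col="", group=None, column="estimate"):
        df = self.estimates
        sel = (df["matrix"] == mat) & (df["row"] == row) & (df["col"] == col)
        if group is not None:
            sel &= df["group"] == group
        vals = df.loc[sel, column]
        if len(vals) == 0:
            # symmetric slots are stored in canonical order
            sel = (df["matrix"] == mat) & (df["row"] == col) & (df["col"] == row)
            if group is not None:
                sel &= df["group"] == group
            vals = df.loc[sel, column]
        if len(vals) == 0:
            raise KeyError((mat, row, col, group))
        return float(vals.iloc[0]) if len(vals) == 1 else vals.to_numpy()


def _baseline(moments, chisq_mode):
    """Independence baseline (free variances + means): closed-form."""
    chi2 = 0.0
    for mo in moments.values():
        _, logdet_s = np.linalg.slogdet(mo.S)
        Fg = float(np.log(np.diag(mo.S)).sum() - logdet_s)
        nn = mo.n if chisq_mode == "ml" else mo.n - 1
        chi2 += nn * Fg
    p = next(iter(moments.values())).S.shape[0]
    G = len(moments)
    df = G * (p * (p - 1) // 2)
    return chi2, df


def srmr(moments, implied) -> float:
    """Standardized root-mean-square residual (covariances and means),
    group-averaged with weights n_g/N."""
    N = sum(m.n for m in moments.values())
    out = 0.0
    for g, mo in moments.items():
        Sigma, mu = implied[g]
        sd = np.sqrt(np.diag(mo.S))
        R = (mo.S - Sigma) / np.outer(sd, sd)
        rm = (mo.mean - mu) / sd
        p = len(sd)
        iu = np.triu_indices(p)
        ss = float(np.sum(R[iu] ** 2) + np.sum(rm**2))
        out += mo.n / N * np.sqrt(ss / (p * (p + 1) / 2 + p))
    return out


def fit_indices(chi2, df, baseline_chi2, baseline_df, N, G=1):
    """RMSEA / CFI / TLI from the chi-squares (df > 0 required)."""
    if df <= 0 or baseline_df <= 0:
        return {"rmsea": None, "cfi": None, "tli": None}
    rmsea = np.sqrt(G) * np.sqrt(max(chi2 - df, 0.0) / (df * N))
    denom = max(baseline_chi2 - baseline_df, chi2 - df, 0.0)
    cfi = 1.0 - (max(chi2 - df, 0.0) / denom if denom > 0 else 0.0)
    br = baseline_chi2 / baseline_df
    tli = (br - chi2 / df) / (br - 1.0) if br != 1.0 else 1.0
    return {"rmsea": float(rmsea), "cfi": float(cfi), "tli": float(tli)}


def _count_moments(p, G):
    return G * (p * (p + 3) // 2)


def fit(
    spec: SemSpec,
    data: pd.DataFrame | None = None,
    moments: dict[str, GroupMoments] | None = None,
    group_col: str = "gender",
    se: bool = True,
    chisq_mode: str = "ml",
    maxiter: int = 2000,
    align_signs: bool = True,
) -> FitResult:
    """Fit the model by normal-theory maximum likelihood.

    Either raw ``data`` (listwise-complete per group) or precomputed
    ``moments`` must be given.  Non-convergence is reported via
    ``converged=False``, never silently; Heywood cases (negative variance
    estimates) and a near-singular information matrix are recorded in
    ``warnings``.
    """
    comp = _Compiled(spec)
    if moments is None:
        if data is None:
            raise ValueError("provide data or moments")
        ddof = 0 if chisq_mode == "ml" else 1
        moments = moments_from_data(data, spec.observed, spec.groups, group_col, ddof)
    for g in spec.groups:
        if g not in moments:
            raise ValueError(f"moments missing for group {g!r}")

    theta0 = comp.start(moments)
    x = theta0
    n_iter = 0
    for attempt in range(3):
        res = optimize.minimize(
            lambda t: comp.value_grad(t, moments),
            x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7, "maxcor": 30},
        )
        x = res.x
        n_iter += int(res.nit)
        _, grad = comp.value_grad(x, moments)
        if res.success or (comp.n_free and np.max(np.abs(grad)) < 1e-5):
            break
        # restart with fresh curvature memory: stalls on flat ridges
    theta_hat = x
    fmin, grad = comp.value_grad(theta_hat, moments)
    grad_norm = float(np.max(np.abs(grad))) if comp.n_free else 0.0
    # bifactor-style models can leave an essentially flat ridge (near
    # empirical underidentification); a stalled optimizer with a small
    # gradient is converged for all practical purposes, while the
    # information-matrix check below still reports the flat direction
    converged = bool(res.success or grad_norm < 1e-3)
    warns = []
    if not converged:
        warns.append(f"optimizer did not converge: {res.message}")

    N = sum(moments[g].n for g in spec.groups)
    if chisq_mode == "ml":
        # sum_g n_g F_g = N * sum_g (n_g/N) F_g
        chi2 = N * fmin
    else:
        # Wishart convention: sum_g (n_g - 1) F_g
        chi2 = 0.0
        for gi, g in enumerate(spec.groups):
            Sigma, mu, *_ = comp.implied(theta_hat, gi)
            Fg = ml_discrepancy({g: moments[g]}, {g: (Sigma, mu)})
            chi2 += (moments[g].n - 1) * Fg
    chi2 = max(float(chi2), 0.0)
    df = _count_moments(comp.p, len(spec.groups)) - comp.n_free
    if df < 0:
        raise ValueError(f"model not identified: negative df ({df})")

    # estimate table
    est_rows = []
    theta_index = {}
    label_seen = {}
    k = 0
    for mat, r, c, g, slot in comp.slots:
        if not slot.free:
            continue
        if slot.label is not None and slot.label in label_seen:
            theta_index[(mat, r, c, g)] = label_seen[slot.label]
        else:
            theta_index[(mat, r, c, g)] = k
            if slot.label is not None:
                label_seen[slot.label] = k
            k += 1

    se_vec = np.full(comp.n_free, np.nan)
    if se and comp.n_free:
        H = _numeric_hessian(comp, theta_hat, moments)
        # observed information of -2lnL is (N/2) * Hessian(F)
        info = 0.5 * N * H
        cond = np.linalg.cond(info)
        if not np.isfinite(cond) or cond > 1e10:
            warns.append(
                f"information matrix near-singular (cond={cond:.2e}); "
                "standard errors from pseudo-inverse"
            )
            acov = np.linalg.pinv(info)
        else:
            acov = np.linalg.inv(info)
        diag = np.diag(acov).copy()
        diag[diag < 0] = np.nan
        se_vec = np.sqrt(diag)

    for mat, r, c, g, slot in comp.slots:
        if slot.free:
            idx = theta_index[(mat, r, c, g)]
            val = theta_hat[idx]
            sev = se_vec[idx] if se else np.nan
        else:
            val, sev = slot.value, np.nan
        est_rows.append(
            {
                "matrix": mat,
                "row": r,
                "col": c,
                "group": g,
                "free": slot.free,
                "label": slot.label,
                "estimate": float(val),
                "se": float(sev) if np.isfinite(sev) else np.nan,
            }
        )
    est = pd.DataFrame(est_rows)

    heywood = est[
        (est.matrix.isin(["psi", "theta"]))
        & (est.row == est.col)
        & (est.free)
        & (est.estimate < 0)
    ]
    if len(heywood):
        warns.append(
            "Heywood case: negative variance estimate(s) at "
            + ", ".join(f"{m}[{r}]@{g}" for m, r, g in zip(heywood.matrix, heywood.row, heywood.group))
        )

    if align_signs:
        est = _align_loading_signs(spec, est)

    imp = {}
    for gi, g in enumerate(spec.groups):
        Sigma, mu, *_ = comp.implied(theta_hat, gi)
        imp[g] = (Sigma, mu)
    b_chi2, b_df = _baseline(moments, chisq_mode)
    idx = fit_indices(chi2, df, b_chi2, b_df, N, G=len(spec.groups))
    srmr_val = srmr(moments, imp)

    # log-likelihood (for information criteria)
    loglik = 0.0
    for g in spec.groups:
        mo = moments[g]
        Sigma, mu = imp[g]
        p = comp.p
        sign, logdet_sigma = np.linalg.slogdet(Sigma)
        iS = np.linalg.inv(Sigma)
        d = mo.mean - mu
        loglik += -0.5 * mo.n * (
            p * np.log(2 * np.pi)
            + logdet_sigma
            + float(np.sum(iS * mo.S))
            + float(d @ iS @ d)
        )
    k_free = comp.n_free
    aic = -2 * loglik + 2 * k_free
    bic = -2 * loglik + k_free * np.log(N)

    return FitResult(
        spec=spec,
        estimates=est,
        theta=theta_hat,
        chi2=chi2,
        df=int(df),
        baseline_chi2=float(b_chi2),
        baseline_df=int(b_df),
        n_per_group={g: moments[g].n for g in spec.groups},
        fmin=float(fmin),
        converged=converged,
        n_iter=n_iter,
        grad_norm=grad_norm,
        rmsea=idx["rmsea"],
        srmr=float(srmr_val),
        cfi=idx["cfi"],
        tli=idx["tli"],
        loglik=float(loglik),
        aic=float(aic),
        bic=float(bic),
        warnings=warns,
        moments=moments,
    )


def _numeric_hessian(comp, theta, moments, eps=1e-5):
    n = len(theta)
    H = np.zeros((n, n))
    for i in range(n):
        tp = theta.copy()
        tp[i] += eps
        _, gp = comp.value_grad(tp, moments)
        tm = theta.copy()
        tm[i] -= eps
        _, gm = comp.value_grad(tm, moments)
        H[i] = (gp - gm) / (2 * eps)
    return 0.5 * (H + H.T)


def _align_loading_signs(spec, est):
    """Resolve the sign indeterminacy of fixed-variance factors: flip a
    factor (jointly with its paths, covariances and mean) when its loading
    sum is negative."""
    est = est.copy()
    for f in spec.eta:
        if f in spec.manifests:
            continue
        lam_rows = (est.matrix == "lam") & (est.col == f) & est.free
        if not lam_rows.any():
            continue
        shared = est.loc[lam_rows, "label"].notna().any()
        group_sets = [spec.groups] if shared else [[g] for g in spec.groups]
        for gset in group_sets:
            sel = lam_rows & est.group.isin(gset)
            if est.loc[sel, "estimate"].sum() >= 0:
                continue
            gmask = est.group.isin(gset)
            est.loc[sel, "estimate"] *= -1
            for mat, rc in (("beta", "row"), ("beta", "col")):
                m = (est.matrix == "beta") & gmask & (est[rc] == f)
                est.loc[m, "estimate"] *= -1
            pm = (
                (est.matrix == "psi")
                & gmask
                & ((est.row == f) ^ (est.col == f))
            )
            est.loc[pm, "estimate"] *= -1
            am = (est.matrix == "alpha") & gmask & (est.row == f)
            est.loc[am, "estimate"] *= -1
    return est


def standardize(result: FitResult) -> pd.DataFrame:
    """Fully standardized solution (std.all): every coefficient rescaled by
    the model-implied standard deviations of its source and target."""
    spec = result.spec
    comp = _Compiled(spec)
    frames = []
    for gi, g in enumerate(spec.groups):
        Sigma, mu, m, A, M = comp.implied(result.theta, gi)
        Veta = A @ m["psi"] @ A.T
        sd_eta = np.sqrt(np.clip(np.diag(Veta), 0, None))
        sd_y = np.sqrt(np.clip(np.diag(Sigma), 0, None))
        if np.any(sd_eta == 0) or np.any(sd_y == 0):
            raise ValueError("zero implied variance: standardization undefined")
        sub = result.estimates[result.estimates.group == g].copy()
        stds = []
        for _, row in sub.iterrows():
            v = row.estimate
            if row.matrix == "lam":
                s = v * sd_eta[comp.eta_ix[row.col]] / sd_y[comp.obs_ix[row.row]]
            elif row.matrix == "beta":
                s = v * sd_eta[comp.eta_ix[row.col]] / sd_eta[comp.eta_ix[row.row]]
            elif row.matrix == "psi":
                s = v / (sd_eta[comp.eta_ix[row.row]] * sd_eta[comp.eta_ix[row.col]])
            elif row.matrix == "theta":
                s = v / (sd_y[comp.obs_ix[row.row]] * sd_y[comp.obs_ix[row.col]])
            elif row.matrix == "nu":
                s = v / sd_y[comp.obs_ix[row.row]]
            else:
                s = v / sd_eta[comp.eta_ix[row.row]]
            stds.append(s)
        sub["std"] = stds
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def reliability(items: pd.DataFrame) -> tuple[float, float]:
    """Internal consistency of an item set: Cronbach's alpha and total
    omega from a one-factor fit."""
    X = items.dropna()
    k = X.shape[1]
    if k < 2:
        raise ValueError("reliability needs >= 2 items")
    S = np.cov(X.to_numpy(dtype=float).T, ddof=0)
    total_var = S.sum()
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    alpha = k / (k - 1) * (1.0 - np.trace(S) / total_var)

    sign, _ = np.linalg.slogdet(S)
    if sign <= 0:
        # singular item covariance (e.g. duplicated items): alpha is still
        # defined, the one-factor ML fit for omega is not
        return float(alpha), float("nan")

    spec = SemSpec(["all"])
    spec.add_factor("f", list(X.columns), variance=1.0)
    res = fit(spec, data=X.assign(gender="all"), se=False)
    lam = np.array(
        [res.param("lam", c, "f", "all") for c in X.columns]
    )
    theta = np.array([res.param("theta", c, c, "all") for c in X.columns])
    omega = lam.sum() ** 2 / (lam.sum() ** 2 + theta.sum())
    return float(alpha), float(omega)


def chisq_diff(nested: FitResult, full: FitResult, tol=1e-6):
    """Likelihood-ratio comparison of nested models: (d_chi2, d_df)."""
    d_df = nested.df - full.df
    d_chi2 = nested.chi2 - full.chi2
    if d_df < 0:
        raise ValueError("models are not nested: nested model has more free parameters")
    scale = max(abs(full.chi2), 1.0)
    if d_chi2 < -tol * scale - 1e-2:
        raise ValueError(
            f"non-nesting detected: chi-square decreased by {-d_chi2:.4g} "
            "under added constraints"
        )
    return max(float(d_chi2), 0.0), int(d_df)
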