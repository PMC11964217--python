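"""Model specifications for the screen-sleep-depression analysis.

Builders for the measurement models (screen-time factor, SQI factor,
BDI-II 2+1 bifactor) and the structural mediation models:

* *primary* model: mediators SQI (latent), WASD and chronotype/MSF
  (manifest);
* *secondary* model: social jetlag replaces chronotype (the two correlate
  too strongly to co-model).

Identification uses the fixed-(residual-)variance convention: every latent
(residual) variance is fixed to 1 and all loadings are free.  The bifactor
is orthogonal in CFA mode; replication mode frees the three factor
covariances (x, y, z), which risks empirical underidentification -- the
fitter then reports a near-singular information matrix rather than failing
silently.
"""

from __future__ import annotations

from .sem import SemSpec
from .syndata import BDI_ITEMS, GROUPS, SCREEN_ITEMS, SQI_ITEMS

#: Mediators of the primary and secondary structural models, in the
#: pre-specified anticipation order.
PRIMARY_MEDIATORS = ("sqi", "wasd", "msf")
SECONDARY_MEDIATORS = ("sqi", "wasd", "sjl")

CA_ITEMS = BDI_ITEMS[:10]
SV_ITEMS = BDI_ITEMS[10:]


def screen_cfa_spec(groups=GROUPS) -> SemSpec:
    """One-factor CFA of the three screen-time indicators."""
    spec = SemSpec(groups)
    spec.add_factor("screen", SCREEN_ITEMS, variance=1.0)
    return spec


def sqi_cfa_spec(groups=GROUPS) -> SemSpec:
    """One-factor CFA of the four Sleep Quality Index items."""
    spec = SemSpec(groups)
    spec.add_factor("sqi", SQI_ITEMS, variance=1.0)
    return spec


def bdi_bifactor_spec(groups=GROUPS, mode: str = "cfa") -> SemSpec:
    """BDI-II 2+1 bifactor: all 21 items load G; items 1-10 also load CA,
    items 11-21 also load SV.  ``mode="cfa"`` keeps the factors orthogonal;
    ``mode="sem"`` frees the three factor covariances (x, y, z)."""
    spec = SemSpec(groups)
    spec.add_factor("g", BDI_ITEMS, variance=1.0)
    spec.add_factor("ca", CA_ITEMS, variance=1.0)
    spec.add_factor("sv", SV_ITEMS, variance=1.0)
    free = mode == "sem"
    spec.add_covariance("g", "ca", free=free, value=0.0)
    spec.add_covariance("g", "sv", free=free, value=0.0)
    spec.add_covariance("ca", "sv", free=free, value=0.0)
    return spec


def cpath_spec(groups=GROUPS, bifactor_mode: str = "cfa") -> SemSpec:
    """Bivariate C-path model: latent screen time predicting G-factor
    depression with no mediators."""
    spec = bdi_bifactor_spec(groups, mode=bifactor_mode)
    spec.add_factor("screen", SCREEN_ITEMS, variance=1.0)
    spec.add_regression("g", "screen")
    spec.add_regression("ca", "screen", free=False, value=0.0)
    spec.add_regression("sv", "screen", free=False, value=0.0)
    return spec


def mediation_spec(
    groups=GROUPS,
    mediators=PRIMARY_MEDIATORS,
    bifactor_mode: str = "cfa",
    n_mediator_covs: int = 3,
) -> SemSpec:
    """Full structural mediation model.

    ``mediators`` names up to three competing sleep facets: ``"sqi"`` is
    modelled as a latent factor over its four items, the diary-derived
    facets (``"wasd"``, ``"msf"``, ``"sjl"``) as manifest variables.
    A-paths run screen -> facet, B-paths facet -> G, plus the direct path
    c' (screen -> G).  ``n_mediator_covs`` frees 3 (all pairwise, the
    figure's Cov.1-3) or 2 (only the WASD pairs, as in the text) mediator
    residual covariances.
    """
    if n_mediator_covs not in (2, 3):
        raise ValueError("n_mediator_covs must be 2 or 3")
    spec = bdi_bifactor_spec(groups, mode=bifactor_mode)
    spec.add_factor("screen", SCREEN_ITEMS, variance=1.0)
    for med in mediators:
        if med == "sqi":
            spec.add_factor("sqi", SQI_ITEMS, variance=1.0)
        else:
            spec.add_manifest(med)
    for med in mediators:
        spec.add_regression(med, "screen")  # A-paths
        spec.add_regression("g", med)  # B-paths
    spec.add_regression("g", "screen")  # c'
    # the redundant regressions onto the specific factors are fixed to zero
    spec.add_regression("ca", "screen", free=False, value=0.0)
    spec.add_regression("sv", "screen", free=False, value=0.0)
    # mediator residual covariances (Cov.1-3)
    pairs = [(a, b) for i, a in enumerate(mediators) for b in mediators[i + 1 :]]
    if n_mediator_covs == 2:
        pairs = [p for p in pairs if "wasd" in p]
    for a, b in pairs:
        spec.add_covariance(a, b)
    return spec


def primary_mediation_spec(groups=GROUPS, **kw) -> SemSpec:
    return mediation_spec(groups, PRIMARY_MEDIATORS, **kw)


def secondary_mediation_spec(groups=GROUPS, **kw) -> SemSpec:
    return mediation_spec(groups, SECONDARY_MEDIATORS, **kw)
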