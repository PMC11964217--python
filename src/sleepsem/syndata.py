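"""Synthetic three-wave adolescent panel generator.

Emulates a three-wave school panel (N ~ 4810 in two gender groups) with the
latent structure assumed by the screen-time -> sleep -> depression mediation
analysis:

* wave 1: a latent screen-time factor with three ordinal 1-6 indicators;
* wave 2: four latent sleep facets (SQI, WASD, chronotype/MSF, social
  jetlag) regressed on the screen factor (A-paths) with correlated
  residuals, expressed as diary times plus four ordinal SQI items;
* wave 3: a bifactor depression outcome (General + Cognitive-Affective +
  Somatic-Vegetative) whose G factor is regressed on the facets (B-paths)
  and directly on screen time (c').

Ordinal items are produced graded-response style by thresholding a
continuous latent response; diary times invert the facet formulas of
:mod:`sleepsem.sleepmetrics` deterministically and add Gaussian jitter, so
derived facets recover the generating latent targets up to noise.
Missingness is applied wave-wise (block dropout) with missing-at-random
dependence on the depression latent score and gender.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

GROUPS = ("boy", "girl")
FACETS = ("sqi", "wasd", "msf", "sjl")

SCREEN_ITEMS = [f"s{i}" for i in range(1, 4)]
SQI_ITEMS = [f"q{i}" for i in range(1, 5)]
BDI_ITEMS = [f"d{i}" for i in range(1, 22)]
DIARY_FIELDS = [
    "bed_school",
    "bed_free",
    "wake_school",
    "wake_free",
    "lat_school",
    "lat_free",
]
WAVE_COLUMNS = {
    1: SCREEN_ITEMS,
    2: DIARY_FIELDS + SQI_ITEMS,
    3: BDI_ITEMS,
}
LATENT_COLUMNS = [
    "latent_screen",
    "latent_sqi",
    "latent_wasd",
    "latent_msf",
    "latent_sjl",
    "latent_g",
    "latent_ca",
    "latent_sv",
]


def _per_group(boy, girl):
    return {"boy": boy, "girl": girl}


@dataclass
class GenConfig:
    """Generator configuration; defaults are calibrated to the study's
    printed path coefficients, loadings and descriptive summaries."""

    n_per_group: dict = field(default_factory=lambda: _per_group(2446, 2364))

    # standardized factor loadings of the three screen items, per group
    # (school-day internet, weekend internet, normal-day screen time)
    loadings_screen: dict = field(
        default_factory=lambda: _per_group((0.87, 0.86, 0.44), (0.91, 0.85, 0.53))
    )
    # SQI items: repeated awakenings, disturbed sleep, difficulty falling
    # asleep, early awakenings
    loadings_sqi: dict = field(
        default_factory=lambda: _per_group(
            (0.67, 0.64, 0.57, 0.47), (0.80, 0.77, 0.60, 0.56)
        )
    )
    # BDI-II bifactor: 21 G loadings; items 1-10 also load CA, items 11-21
    # also load SV (2+1 structure); final item (21) deliberately weak.
    loadings_bdi_g: dict = field(
        default_factory=lambda: _per_group(
            (
                0.70, 0.62, 0.66, 0.58, 0.55, 0.68, 0.64, 0.60, 0.72, 0.57,
                0.63, 0.59, 0.65, 0.61, 0.56, 0.67, 0.54, 0.62, 0.58, 0.60,
                0.35,
            ),
            (
                0.66, 0.58, 0.62, 0.55, 0.52, 0.64, 0.60, 0.57, 0.68, 0.54,
                0.60, 0.56, 0.62, 0.58, 0.53, 0.63, 0.51, 0.59, 0.55, 0.57,
                0.30,
            ),
        )
    )
    loadings_bdi_ca: dict = field(
        default_factory=lambda: _per_group(
            (0.40, 0.35, 0.38, 0.33, 0.30, 0.42, 0.36, 0.32, 0.44, 0.31),
            (0.42, 0.37, 0.40, 0.35, 0.32, 0.44, 0.38, 0.34, 0.46, 0.33),
        )
    )
    loadings_bdi_sv: dict = field(
        default_factory=lambda: _per_group(
            (0.38, 0.34, 0.36, 0.32, 0.30, 0.40, 0.33, 0.35, 0.31, 0.37, 0.25),
            (0.40, 0.36, 0.38, 0.34, 0.32, 0.42, 0.35, 0.37, 0.33, 0.39, 0.27),
        )
    )

    # structural paths on the standardized latent scale, per group,
    # facet order (sqi, wasd, msf, sjl)
    a_paths: dict = field(
        default_factory=lambda: _per_group(
            (0.052, -0.202, 0.261, 0.189), (0.141, -0.234, 0.304, 0.227)
        )
    )
    b_paths: dict = field(
        default_factory=lambda: _per_group(
            (0.085, -0.018, 0.014, 0.011), (0.142, -0.042, 0.037, 0.026)
        )
    )
    c_prime: dict = field(default_factory=lambda: _per_group(0.021, 0.015))

    # residual covariances among the three primary-model mediators on the
    # latent scale: (sqi, wasd), (wasd, msf), (sqi, msf)
    mediator_residual_cov: tuple = (-0.15, -0.25, 0.10)
    # residual correlation coupling social jetlag to chronotype (the two
    # correlate too strongly to co-model, hence the secondary model)
    sjl_msf_residual_corr: float = 0.80
    sjl_other_residual_cov: tuple = (0.05, -0.20)  # (sqi, wasd) with sjl

    # group mean shift of the depression G factor (girls score higher;
    # calibrated to the printed ~2.2x girls/boys BDI total ratio)
    g_mean_shift: dict = field(default_factory=lambda: _per_group(0.0, 0.919))
    # group location shift of the SQI item responses (girls report more
    # disturbed-sleep symptoms; calibrated to printed item means)
    sqi_item_shift: dict = field(default_factory=lambda: _per_group(0.0, 0.43))

    # real-unit facet anchors (mean, SD), per group, from the printed
    # descriptive table
    wasd_hours: dict = field(
        default_factory=lambda: _per_group((8.35, 0.99), (8.10, 1.07))
    )
    msf_hours: dict = field(
        default_factory=lambda: _per_group((5.42, 1.36), (5.13, 1.22))
    )
    sjl_hours: dict = field(
        default_factory=lambda: _per_group((2.46, 1.12), (2.22, 1.05))
    )
    latency_hours: float = 0.33
    diary_jitter_sd: float = 0.25

    # strictly increasing cut points on the latent response scale,
    # calibrated against the printed descriptive means (screen ~3.2/6,
    # SQI boys 1.63 / girls 2.04, BDI item means implying the 2.2x ratio)
    thresholds_screen: tuple = (-1.662, -0.662, 0.338, 1.238, 1.938)
    thresholds_sqi: tuple = (0.33, 0.93, 1.53, 2.13, 2.73)
    thresholds_bdi: tuple = (0.962, 1.712, 2.412)

    # missingness mechanism
    complete_fraction: float = 0.40
    mar_coef_depression: float = 0.50
    mar_coef_girl: float = 0.20
    wave_offsets: tuple = (0.0, 0.25, 0.45)

    # replication profile
    m_imputations: int = 70
    age_mean: float = 14.0
    age_sd: float = 0.72
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for g in GROUPS:
            if self.n_per_group[g] < 50:
                raise ValueError("n_per_group must be >= 50 (identification floor)")
            for lam in (
                self.loadings_screen[g]
                + self.loadings_sqi[g]
                + self.loadings_bdi_g[g]
                + self.loadings_bdi_ca[g]
                + self.loadings_bdi_sv[g]
            ):
                if not np.isfinite(lam):
                    raise ValueError("all loadings must be finite")
        for cuts in (self.thresholds_screen, self.thresholds_sqi, self.thresholds_bdi):
            if not all(a < b for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"ordinal thresholds must be strictly increasing: {cuts}")
        if not (0.0 < self.complete_fraction <= 1.0):
            raise ValueError("target complete-case fraction must lie in (0, 1]")

    def facet_residual_cov(self, group: str) -> np.ndarray:
        """Residual covariance of the four facet latents (order: FACETS),
        scaled so every facet has unit total variance."""
        a = np.asarray(self.a_paths[group])
        diag = 1.0 - a**2
        psi = np.diag(diag)
        c_sw, c_wm, c_sm = self.mediator_residual_cov
        psi[0, 1] = psi[1, 0] = c_sw
        psi[1, 2] = psi[2, 1] = c_wm
        psi[0, 2] = psi[2, 0] = c_sm
        psi[2, 3] = psi[3, 2] = self.sjl_msf_residual_corr * np.sqrt(diag[2] * diag[3])
        c_qj, c_wj = self.sjl_other_residual_cov
        psi[0, 3] = psi[3, 0] = c_qj
        psi[1, 3] = psi[3, 1] = c_wj
        return psi

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    @classmethod
    def from_dict(cls, d: dict) -> "GenConfig":
        kwargs = dict(d)
        for key in list(kwargs):
            val = kwargs[key]
            if isinstance(val, dict):
                kwargs[key] = {
                    g: tuple(v) if isinstance(v, list) else v for g, v in val.items()
                }
            elif isinstance(val, list):
                kwargs[key] = tuple(val)
        return cls(**kwargs)


def default_config() -> GenConfig:
    """The calibrated replication configuration (printed path coefficients,
    loadings, descriptive anchors, 40% longitudinally complete cases,
    m = 70 imputations)."""
    return GenConfig()


# ----------------------------------------------------------------------
# generation


def _cut_ordinal(latent: np.ndarray, cuts, base: int) -> np.ndarray:
    """Threshold a continuous response into ordered categories starting at
    ``base``."""
    return base + np.searchsorted(np.asarray(cuts), latent, side="left").astype(
        np.int64
    )


def generate_panel(config: GenConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a fully complete three-wave panel (one row per person).

    Missingness is applied separately via :func:`apply_missingness`.
    Latent bookkeeping columns (``latent_*``) are retained for testing and
    for the MAR mechanism; they are not part of the observed data model.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    frames = []
    for gi, group in enumerate(GROUPS):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), gi]))
        n = int(config.n_per_group[group])

        x = rng.standard_normal(n)  # screen factor, variance 1
        a = np.asarray(config.a_paths[group])
        psi = config.facet_residual_cov(group)
        L = np.linalg.cholesky(psi)
        resid = rng.standard_normal((n, 4)) @ L.T
        facets = x[:, None] * a[None, :] + resid  # unit-variance latents

        b = np.asarray(config.b_paths[group])
        cp = float(config.c_prime[group])
        cov_f = np.outer(a, a) + psi
        var_pred = b @ cov_f @ b + cp**2 + 2.0 * cp * (b @ a)
        if var_pred >= 1.0:
            raise ValueError("structural paths imply explained variance >= 1")
        g_lat = (
            config.g_mean_shift[group]
            + facets @ b
            + cp * x
            + np.sqrt(1.0 - var_pred) * rng.standard_normal(n)
        )
        ca = rng.standard_normal(n)
        sv = rng.standard_normal(n)

        data = {
            "person_id": np.arange(n) + gi * 1_000_000,
            "gender": group,
            "age_years": np.clip(
                config.age_mean + config.age_sd * rng.standard_normal(n), 12.0, 16.0
            ),
        }

        # wave 1: screen items
        for j, name in enumerate(SCREEN_ITEMS):
            lam = config.loadings_screen[group][j]
            y = lam * x + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
            data[name] = _cut_ordinal(y, config.thresholds_screen, base=1)

        # wave 2: diary times inverting the facet formulas + jitter
        mw, sw = config.wasd_hours[group]
        mf, sf = config.msf_hours[group]
        mj, sj = config.sjl_hours[group]
        wasd_h = mw + sw * facets[:, 1]
        msf_h = mf + sf * facets[:, 2]
        sjl_h = mj + sj * facets[:, 3]
        msw_h = msf_h - sjl_h
        lat0 = config.latency_hours
        jit = config.diary_jitter_sd

        onset_s = msw_h - wasd_h / 2.0
        onset_f = msf_h - wasd_h / 2.0
        lat_school = np.maximum(lat0 + jit * rng.standard_normal(n), 0.0)
        lat_free = np.maximum(lat0 + jit * rng.standard_normal(n), 0.0)
        data["bed_school"] = onset_s - lat_school + jit * rng.standard_normal(n)
        data["bed_free"] = onset_f - lat_free + jit * rng.standard_normal(n)
        data["wake_school"] = onset_s + wasd_h + jit * rng.standard_normal(n)
        data["wake_free"] = onset_f + wasd_h + jit * rng.standard_normal(n)
        data["lat_school"] = lat_school
        data["lat_free"] = lat_free

        shift = config.sqi_item_shift[group]
        for j, name in enumerate(SQI_ITEMS):
            lam = config.loadings_sqi[group][j]
            y = shift + lam * facets[:, 0] + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
            data[name] = _cut_ordinal(y, config.thresholds_sqi, base=1)

        # wave 3: BDI-II items, 2+1 bifactor
        lam_g = config.loadings_bdi_g[group]
        lam_ca = config.loadings_bdi_ca[group]
        lam_sv = config.loadings_bdi_sv[group]
        for j, name in enumerate(BDI_ITEMS):
            lg = lam_g[j]
            if j < 10:
                ls, spec_fac = lam_ca[j], ca
            else:
                ls, spec_fac = lam_sv[j - 10], sv
            uniq = 1.0 - lg**2 - ls**2
            if uniq <= 0:
                raise ValueError(f"BDI item {name}: loadings imply negative uniqueness")
            y = lg * g_lat + ls * spec_fac + np.sqrt(uniq) * rng.standard_normal(n)
            data[name] = _cut_ordinal(y, config.thresholds_bdi, base=0)

        data["latent_screen"] = x
        data["latent_sqi"] = facets[:, 0]
        data["latent_wasd"] = facets[:, 1]
        data["latent_msf"] = facets[:, 2]
        data["latent_sjl"] = facets[:, 3]
        data["latent_g"] = g_lat
        data["latent_ca"] = ca
        data["latent_sv"] = sv
        frames.append(pd.DataFrame(data))

    return pd.concat(frames, ignore_index=True)


def apply_missingness(
    panel: pd.DataFrame, config: GenConfig, seed: int | None = None
) -> pd.DataFrame:
    """Impose wave-block missingness (MAR in depression score and gender).

    A person missing at a wave is missing all of that wave's items.  The
    base rates are solved so the expected longitudinally-complete-case
    fraction equals ``config.complete_fraction``; with target 1.0 the panel
    is returned unchanged.
    """
    config.validate()
    if config.complete_fraction >= 1.0:
        return panel.copy()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))

    dep = panel["latent_g"].to_numpy(dtype=float)
    girl = (panel["gender"] == "girl").to_numpy(dtype=float)
    lin = config.mar_coef_depression * dep + config.mar_coef_girl * girl
    offsets = np.asarray(config.wave_offsets)

    def complete_prob(delta: float) -> float:
        p_present = 1.0 - expit(delta + offsets[None, :] + lin[:, None])
        return float(p_present.prod(axis=1).mean())

    target = config.complete_fraction
    delta = brentq(lambda d: complete_prob(d) - target, -20.0, 20.0, xtol=1e-10)

    out = panel.copy()
    for w, cols in WAVE_COLUMNS.items():
        p_miss = expit(delta + offsets[w - 1] + lin)
        miss = rng.random(len(out)) < p_miss
        out.loc[miss, cols] = np.nan
    return out


def complete_case_mask(panel: pd.DataFrame) -> pd.Series:
    """True for rows observed at all three waves (longitudinally complete)."""
    mask = pd.Series(True, index=panel.index)
    for cols in WAVE_COLUMNS.values():
        mask &= panel[cols].notna().all(axis=1)
    return mask


# ----------------------------------------------------------------------
# CSV round-trip


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    """Deterministic wide-format CSV export (missing cells empty)."""
    panel.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_panel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "gender" in df and df["gender"].isna().any():
        raise ValueError("gender must be non-missing for all rows")
    return df
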