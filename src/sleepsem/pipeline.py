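"""End-to-end orchestration of the analysis.

One call runs: panel acquisition (synthetic or CSV) -> facet derivation
(re-derived *after* imputation of the raw diary fields and items) ->
MICE-PMM imputation -> bivariate C-path fit (no mediators) -> gender-
separated multigroup fits of the primary (SQI, WASD, chronotype) and
secondary (social jetlag for chronotype) mediation models per imputation
-> Rubin/D2 pooling -> mediation and invariance tables -> a machine-
readable summary JSON and a human-readable report that flags every fit
index against the conventional cut-offs (RMSEA/SRMR <= 0.08,
CFI/TLI >= 0.95).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models, syndata
from .impute import chained_impute
from .invariance import invariance_ladder
from .pooling import d2_pool_chisq, pooled_mediation_report
from .sem import fit
from .sleepmetrics import derive_sleep_facets

__all__ = ["RunConfig", "run", "compare_single_vs_multigroup"]

log = logging.getLogger("sleepsem")

DEFAULT_CUTOFFS = {"rmsea": 0.08, "srmr": 0.08, "cfi": 0.95, "tli": 0.95}

#: Columns imputed by the pipeline (raw items and diary fields; facets are
#: re-derived per completed dataset, never imputed directly).
IMPUTED_COLUMNS = (
    syndata.SCREEN_ITEMS + syndata.DIARY_FIELDS + syndata.SQI_ITEMS + syndata.BDI_ITEMS
)


@dataclass
class RunConfig:
    gen_config: syndata.GenConfig | None = None
    panel_csv: str | None = None
    m: int = 5
    k: int = 5
    iters: int = 5
    seed: int = 0
    model: str = "both"  # primary | secondary | both
    complete_case_validation: bool = False
    run_invariance: bool = True
    invariance_scales: tuple = ("screen", "sqi")
    bifactor_mode: str = "cfa"
    outdir: str = "sleepsem_run"
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))

    def validate(self):
        if self.model not in ("primary", "secondary", "both"):
            raise ValueError(f"unknown model choice {self.model!r}")
        if any(v <= 0 for v in self.cutoffs.values()):
            raise ValueError("fit cut-offs must be positive")
        if self.gen_config is None and self.panel_csv is None:
            raise ValueError("provide a generator config or a panel CSV")


def _spec_hash(spec) -> str:
    return hashlib.sha256(
        json.dumps(spec.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]


def _fit_block(tables, spec, mediators, cutoffs):
    """Fit one structural model on every imputed table and pool."""
    fits = []
    for t in tables:
        fits.append(fit(spec, data=t, se=True))
    ok = [f for f in fits if f.converged]
    if len(fits) - len(ok) > 0.10 * len(fits):
        raise RuntimeError(
            f"stage fit: {len(fits)-len(ok)}/{len(fits)} fits failed to converge"
        )
    med = pooled_mediation_report(fits, mediators=mediators)
    chi2s = np.array([f.chi2 for f in ok])
    F, df1, df2, p = d2_pool_chisq(chi2s, ok[0].df) if len(ok) > 1 else (
        float("nan"), ok[0].df, float("nan"), float("nan"),
    )
    indices = {
        key: float(np.mean([getattr(f, key) for f in ok]))
        for key in ("rmsea", "srmr", "cfi", "tli")
    }
    flags = {
        "rmsea": indices["rmsea"] <= cutoffs["rmsea"],
        "srmr": indices["srmr"] <= cutoffs["srmr"],
        "cfi": indices["cfi"] >= cutoffs["cfi"],
        "tli": indices["tli"] >= cutoffs["tli"],
    }
    return {
        "fits": fits,
        "mediation": med,
        "pooled_chi2": {
            "mean_chi2": float(chi2s.mean()),
            "df": int(ok[0].df),
            "d2_F": F,
            "d2_df1": df1,
            "d2_df2": df2,
            "d2_p": p,
        },
        "mean_fit_indices": indices,
        "cutoff_flags": flags,
        "n_converged": len(ok),
    }


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    log.info("stage 1: panel acquisition")
    if config.panel_csv:
        panel = syndata.read_panel_csv(config.panel_csv)
    else:
        gc = config.gen_config
        panel = syndata.generate_panel(gc, seed=config.seed)
        if gc.complete_fraction < 1.0:
            panel = syndata.apply_missingness(panel, gc, seed=config.seed + 1)
        syndata.write_panel_csv(panel, outdir / "panel.csv")
    cc_mask = syndata.complete_case_mask(panel)

    log.info("stage 2: imputation (m=%d)", config.m)
    imp = chained_impute(
        panel,
        m=config.m,
        iters=config.iters,
        k=config.k,
        seed=config.seed + 2,
        columns=[c for c in IMPUTED_COLUMNS if panel[c].isna().any()],
        predictors_extra=["age_years"],
    )
    (outdir / "imputation_manifest.json").write_text(
        json.dumps(imp.manifest(), indent=2, sort_keys=True)
    )

    log.info("stage 3: facet derivation per completed dataset")
    tables = [derive_sleep_facets(t) for t in imp.completed_tables]

    summary = {
        "software": {"package": "sleepsem", "version": __version__},
        "seed": config.seed,
        "n": int(len(panel)),
        "n_complete_cases": int(cc_mask.sum()),
        "complete_fraction": float(cc_mask.mean()),
        "m": config.m,
        "models": {},
    }

    log.info("stage 4: bivariate C-path model (no mediators)")
    cspec = models.cpath_spec(bifactor_mode=config.bifactor_mode)
    summary["spec_hashes"] = {"cpath": _spec_hash(cspec)}
    cfits = [fit(cspec, data=t, se=True) for t in tables]
    cok = [f for f in cfits if f.converged]
    from .pooling import rubin_pool
    from .sem import standardize

    cpath = {}
    for g in cspec.groups:
        est = np.array([f.param("beta", "g", "screen", g) for f in cok])
        ses = np.array([f.param("beta", "g", "screen", g, "se") for f in cok])
        pooled = rubin_pool(est, ses**2)
        from scipy import stats as _st

        tstat = pooled.qbar / pooled.se if pooled.se > 0 else float("nan")
        pval = 2 * _st.t.sf(abs(tstat), pooled.df_rubin)
        std_c = float(
            np.mean(
                [
                    standardize(f)
                    .query(
                        "matrix=='beta' and row=='g' and col=='screen' "
                        f"and group=='{g}'"
                    )["std"]
                    .iloc[0]
                    for f in cok
                ]
            )
        )
        cpath[g] = {
            "c_path": pooled.qbar,
            "se": pooled.se,
            "t": float(tstat),
            "p": float(pval),
            "std_c_path": std_c,
            "significant_05": bool(pval < 0.05),
        }
    summary["bivariate_cpath"] = cpath

    wanted = (
        ["primary", "secondary"] if config.model == "both" else [config.model]
    )
    for name in wanted:
        log.info("stage 5: %s mediation model", name)
        if name == "primary":
            spec = models.primary_mediation_spec(bifactor_mode=config.bifactor_mode)
            mediators = models.PRIMARY_MEDIATORS
        else:
            spec = models.secondary_mediation_spec(bifactor_mode=config.bifactor_mode)
            mediators = models.SECONDARY_MEDIATORS
        summary["spec_hashes"][name] = _spec_hash(spec)
        block = _fit_block(tables, spec, mediators, config.cutoffs)
        block["mediation"].to_csv(outdir / f"mediation_{name}.csv", index=False)
        summary["models"][name] = {
            "pooled_chi2": block["pooled_chi2"],
            "mean_fit_indices": block["mean_fit_indices"],
            "cutoff_flags": block["cutoff_flags"],
            "n_converged": block["n_converged"],
            "mediation_rows": block["mediation"].to_dict("records"),
        }
        if config.complete_case_validation:
            cc = derive_sleep_facets(panel[cc_mask])
            vfit = fit(spec, data=cc, se=False)
            summary["models"][name]["complete_case_validation"] = {
                "n": int(cc_mask.sum()),
                "chi2": vfit.chi2,
                "df": vfit.df,
                "rmsea": vfit.rmsea,
                "srmr": vfit.srmr,
                "cfi": vfit.cfi,
                "tli": vfit.tli,
                "converged": vfit.converged,
            }

    if config.run_invariance:
        log.info("stage 6: measurement invariance ladders")
        inv_specs = {
            "screen": models.screen_cfa_spec(),
            "sqi": models.sqi_cfa_spec(),
            "bdi": models.bdi_bifactor_spec(),
        }
        summary["invariance"] = {}
        for scale in config.invariance_scales:
            ladder = invariance_ladder(tables, inv_specs[scale])
            ladder.to_csv(outdir / f"invariance_{scale}.csv", index=False)
            summary["invariance"][scale] = json.loads(
                ladder.to_json(orient="records")
            )

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float)
    )
    _write_report(outdir / "report.txt", summary, config)
    log.info("run complete: %s", outdir)
    return outdir


def _write_report(path: Path, summary: dict, config: RunConfig):
    lines = [
        "sleepsem analysis report",
        "========================",
        f"seed {summary['seed']}; N = {summary['n']} "
        f"({summary['n_complete_cases']} longitudinally complete, "
        f"{summary['complete_fraction']:.1%}); m = {summary['m']} imputations",
        "",
        "Bivariate C-path (screen time -> depression, no mediators):",
    ]
    for g, row in summary["bivariate_cpath"].items():
        sig = "significant" if row["significant_05"] else "not significant"
        lines.append(
            f"  {g}: std c = {row['std_c_path']:.3f} (p = {row['p']:.3f}, {sig})"
        )
    for name, blk in summary["models"].items():
        lines += ["", f"{name.capitalize()} mediation model:"]
        idx = blk["mean_fit_indices"]
        flags = blk["cutoff_flags"]
        cuts = config.cutoffs
        for key in ("rmsea", "srmr", "cfi", "tli"):
            verdict = "PASS" if flags[key] else "FAIL"
            rel = "<=" if key in ("rmsea", "srmr") else ">="
            lines.append(
                f"  {key.upper()} = {idx[key]:.3f} ({rel} {cuts[key]}: {verdict})"
            )
        for row in blk["mediation_rows"]:
            pm = row["pm"]
            pm_txt = f"PM = {pm:.0f}%" if np.isfinite(pm) else f"flag: {row['flag']}"
            lines.append(
                f"  {row['group']}/{row['mediator']}: a = {row['a']:.3f}, "
                f"b = {row['b']:.3f}, c' = {row['c_prime']:.3f}, "
                f"indirect = {row['indirect']:.3f}, {pm_txt}"
            )
    path.write_text("\n".join(lines) + "\n")


def compare_single_vs_multigroup(
    panel: pd.DataFrame, spec_builder, group_col: str = "gender"
) -> pd.DataFrame:
    """Information-criteria comparison of single-group vs gender-separated
    fits on complete-case data.  ``spec_builder(groups)`` must return a
    SemSpec for the given group labels."""
    multi = spec_builder(tuple(sorted(panel[group_col].dropna().unique())))
    fit_multi = fit(multi, data=panel, group_col=group_col, se=False)
    single_data = panel.copy()
    single_data[group_col] = "all"
    single = spec_builder(("all",))
    fit_single = fit(single, data=single_data, group_col=group_col, se=False)
    return pd.DataFrame(
        [
            {
                "variant": "single-group",
                "n_free": len(fit_single.estimates[fit_single.estimates.free]),
                "loglik": fit_single.loglik,
                "aic": fit_single.aic,
                "bic": fit_single.bic,
                "converged": fit_single.converged,
            },
            {
                "variant": "multigroup",
                "n_free": len(fit_multi.estimates[fit_multi.estimates.free]),
                "loglik": fit_multi.loglik,
                "aic": fit_multi.aic,
                "bic": fit_multi.bic,
                "converged": fit_multi.converged,
            },
        ]
    )
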