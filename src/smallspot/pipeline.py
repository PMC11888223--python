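"""Pipeline stages gluing the modules into the end-to-end analysis, plus
the run configuration used by the command-line interface.

Stage order: synthesize -> sample (per-locus sampling table and the
Monte Carlo site-selection null) -> fit-thresholds (delivery filter +
Weibull fits) -> detection model (ratio vs proportion L, RMSE scan) ->
color naming (response matrices, tertiles, GLMM with LR test).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import colornaming, detection
from .exceptions import ConfigError, NonIdentifiableError
from .io import write_table
from .optics import build_aperture_map, diffraction_psf, retinal_light_distribution
from .psychophysics import delivery_filter, fit_weibull_threshold
from .sampling import (
    effective_cone_counts,
    monte_carlo_sampling_null,
    proportion_L_with_range,
)
from .synthesize import (
    StudyData,
    SubjectConfig,
    SyntheticStudyConfig,
    subject_excitations,
    synthesize_study,
    write_study,
)

log = logging.getLogger("smallspot")


# ---------------------------------------------------------------------------
# stage: per-locus sampling table
# ---------------------------------------------------------------------------

def locus_sampling_table(study: StudyData) -> pd.DataFrame:
    """Full-grid aperture sampling at each locus's nominal centre.

    Gives per-class effective counts, proportion L with its
    unclassified-reassignment range, and heterogeneity.
    """
    cfg = study.config
    rows = []
    for sid, mosaic in study.mosaics.items():
        apertures = build_aperture_map(mosaic)
        psf = diffraction_psf(
            543.0, cfg.pupil_diameter, cfg.residual_defocus, cfg.pixel_pitch, cfg.grid_size
        )
        for _, locus in study.loci[study.loci["subject_id"] == sid].iterrows():
            light = retinal_light_distribution(
                cfg.stimulus_side, psf, (locus["x_arcmin"], locus["y_arcmin"])
            )
            counts = effective_cone_counts(light, apertures)
            res = proportion_L_with_range(counts)
            rows.append(
                {
                    "subject_id": sid,
                    "locus_id": locus["locus_id"],
                    "count_L": counts["L"],
                    "count_M": counts["M"],
                    "count_S": counts["S"],
                    "count_U": counts["U"],
                    "p_L": res.proportion_L,
                    "p_L_min": res.p_L_range[0],
                    "p_L_max": res.p_L_range[1],
                    "heterogeneity": res.heterogeneity,
                }
            )
    return pd.DataFrame(rows)


def sampling_null_tables(study: StudyData, n_iterations: int = 10_000,
                         seed: int = 0) -> dict[str, pd.DataFrame]:
    """Monte Carlo null histograms of tested proportion L per subject."""
    cfg = study.config
    out = {}
    for sid, mosaic in study.mosaics.items():
        n_loc = int((study.loci["subject_id"] == sid).sum())
        psf = diffraction_psf(
            543.0, cfg.pupil_diameter, cfg.residual_defocus, cfg.pixel_pitch, cfg.grid_size
        )
        light = retinal_light_distribution(cfg.stimulus_side, psf)
        null = monte_carlo_sampling_null(
            mosaic, light, n_locations=n_loc, n_iterations=n_iterations, seed=seed
        )
        out[sid] = pd.DataFrame(
            {
                "bin_left": null.bin_edges[:-1],
                "bin_right": null.bin_edges[1:],
                "mean_count": null.mean_counts,
                "sd_count": null.sd_counts,
            }
        )
    return out


# ---------------------------------------------------------------------------
# stage: thresholds
# ---------------------------------------------------------------------------

def fit_study_thresholds(
    study: StudyData,
    criterion: float = 0.75,
    include_catch: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Delivery-filter the trial log and fit per-locus Weibull thresholds.

    Returns (measurements, filtered_trials, inclusion percentage per
    subject).  Measurements carry fitted 543/680 sensitivities (reciprocal
    thresholds), their ratio, and the trial-averaged proportion L.
    """
    included, _ = delivery_filter(study.trials, criterion)
    inclusion = {
        sid: 100.0 * (included["subject_id"] == sid).sum() / (study.trials["subject_id"] == sid).sum()
        for sid in study.trials["subject_id"].unique()
    }
    if not include_catch:
        included = included[included["source"] == "staircase"]
    rows = []
    for (sid, locus), g in included.groupby(["subject_id", "locus_id"]):
        rec = {"subject_id": sid, "locus_id": locus}
        ok = True
        for w, name in ((543.0, "543"), (680.0, "680")):
            gw = g[g["wavelength"] == w]
            try:
                _, thr, _ = fit_weibull_threshold(
                    gw["intensity"].to_numpy(), gw["seen"].to_numpy()
                )
            except NonIdentifiableError:
                log.warning("threshold not identifiable at %s / %s nm", locus, name)
                ok = False
                break
            rec[f"threshold_{name}"] = thr
            rec[f"sensitivity_{name}"] = 1.0 / thr
        if not ok:
            continue
        rec["ratio_680_543"] = rec["sensitivity_680"] / rec["sensitivity_543"]
        rec["proportion_L"] = float(g["proportion_L"].mean())
        rows.append(rec)
    measurements = pd.DataFrame(rows)
    return measurements, included, inclusion


def trials_with_fitted_multiples(included: pd.DataFrame, measurements: pd.DataFrame) -> pd.DataFrame:
    """Re-express trial intensity as multiples of the fitted local threshold."""
    thr = {}
    for _, r in measurements.iterrows():
        thr[(r["locus_id"], 543.0)] = r["threshold_543"]
        thr[(r["locus_id"], 680.0)] = r["threshold_680"]
    keys = list(zip(included["locus_id"], included["wavelength"]))
    have = [k in thr for k in keys]
    out = included[have].copy()
    out["intensity_multiple"] = [
        i / thr[k] for i, k in zip(out["intensity"], (k for k, h in zip(keys, have) if h))
    ]
    return out


# ---------------------------------------------------------------------------
# stage: detection model
# ---------------------------------------------------------------------------

def detection_analysis(
    study: StudyData,
    measurements: pd.DataFrame,
    lambda_grid: np.ndarray | None = None,
    domain: str = "linear",
) -> dict:
    """Spearman correlation of fitted ratio vs proportion L per subject,
    plus the RMSE-vs-lambda_max scan (unit and 1.5x M-weight variants)."""
    cfg = study.config
    out: dict = {"spearman": {}, "rmse_scans": {}, "best_lambda_max": {}, "m_weight_effect": {}}
    grid = detection.DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid
    for sub in cfg.subjects:
        m = measurements[measurements["subject_id"] == sub.subject_id]
        if len(m) < 3:
            continue
        rho, p = spearmanr(m["proportion_L"], m["ratio_680_543"])
        out["spearman"][sub.subject_id] = {"rho": float(rho), "p": float(p), "n": len(m)}
        _, media, pigment = subject_excitations(cfg, sub)
        scan = detection.rmse_vs_lambda_max(m, media, pigment, grid, domain=domain)
        scan15 = detection.rmse_vs_lambda_max(m, media, pigment, grid, m_weight=1.5, domain=domain)
        out["rmse_scans"][sub.subject_id] = scan
        out["best_lambda_max"][sub.subject_id] = detection.best_lambda_max(scan)
        out["m_weight_effect"][sub.subject_id] = {
            "rmse_w1_at_best": float(scan["rmse"].min()),
            "rmse_w1.5_at_best": float(
                scan15.loc[scan["rmse"].idxmin(), "rmse"]
            ),
        }
    return out


# ---------------------------------------------------------------------------
# stage: color naming
# ---------------------------------------------------------------------------

def color_analysis(trials: pd.DataFrame, min_n: int = 10) -> dict:
    """Response matrices, heterogeneity tertiles, GLMM + LR test."""
    seen = trials[trials["seen"].astype(bool)]
    intensity_edges = np.geomspace(
        max(seen["intensity_multiple"].min(), 0.25),
        seen["intensity_multiple"].max() * (1 + 1e-9),
        7,
    )
    pL_edges = np.linspace(0, 1, 9)
    matrices = {
        w: colornaming.build_response_matrix(
            trials[trials["wavelength"] == w], intensity_edges, pL_edges, min_n
        )
        for w in sorted(trials["wavelength"].unique())
    }
    tertiles = colornaming.tertile_analysis(trials)
    full = colornaming.fit_color_glmm(trials)
    reduced = colornaming.fit_color_glmm(
        trials, predictors=["log2_intensity", "s_cone_distance"]
    )
    lr, ddf, daic, p = colornaming.likelihood_ratio_test(full, reduced)
    return {
        "matrices": matrices,
        "tertiles": tertiles,
        "glmm": full,
        "glmm_reduced": reduced,
        "lr_test": {"lr_stat": lr, "delta_df": ddf, "delta_aic": daic, "p": p},
    }


# ---------------------------------------------------------------------------
# run configuration + full pipeline
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"seed", "outdir", "stages", "synth", "montecarlo_iterations",
               "rmse_domain", "min_n", "verbosity"}
_ALL_STAGES = ("simulate", "sample", "fit-thresholds", "scan-lmax", "fit-colors")


@dataclass
class RunConfig:
    """Validated pipeline configuration (rejects unknown keys)."""

    seed: int = 0
    outdir: str = "results"
    stages: tuple[str, ...] = _ALL_STAGES
    synth: dict = field(default_factory=dict)
    montecarlo_iterations: int = 10_000
    rmse_domain: str = "linear"
    min_n: int = 10
    verbosity: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = set(cfg.stages) - set(_ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def study_config(self) -> SyntheticStudyConfig:
        d = dict(self.synth)
        subs = d.pop("subjects", None)
        cfg = SyntheticStudyConfig(master_seed=self.seed)
        known = {f.name for f in dataclasses.fields(SyntheticStudyConfig)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown synth keys: {sorted(unknown)}")
        cfg = dataclasses.replace(cfg, **d)
        if subs is not None:
            cfg.subjects = [SubjectConfig(**s) for s in subs]
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and write their tables under outdir.

    Returns the run report (also written as YAML).  Deterministic for a
    fixed config and seed.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages)}

    study = synthesize_study(config.study_config())
    report["sub_seeds"] = study.manifest["sub_seeds"]
    if "simulate" in config.stages:
        write_study(study, out / "study")
        log.info("synthesized %d trials over %d loci", len(study.trials), len(study.loci))

    if "sample" in config.stages:
        table = locus_sampling_table(study)
        write_table(table, out / "locus_sampling.tsv", {"master_seed": config.seed})
        nulls = sampling_null_tables(study, config.montecarlo_iterations, seed=config.seed)
        for sid, df in nulls.items():
            write_table(df, out / f"montecarlo_null_{sid}.tsv", {"master_seed": config.seed})
        report["sample"] = {"n_loci": len(table)}

    measurements = None
    if {"fit-thresholds", "scan-lmax", "fit-colors"} & set(config.stages):
        measurements, included, inclusion = fit_study_thresholds(study)
        write_table(measurements, out / "threshold_measurements.tsv", {"master_seed": config.seed})
        report["thresholds"] = {
            "n_measurements": len(measurements),
            "inclusion_pct": {k: round(v, 2) for k, v in inclusion.items()},
        }

    if "scan-lmax" in config.stages and measurements is not None:
        det = detection_analysis(study, measurements, domain=config.rmse_domain)
        for sid, scan in det["rmse_scans"].items():
            write_table(scan, out / f"rmse_scan_{sid}.tsv", {"master_seed": config.seed})
        report["detection"] = {
            "spearman": det["spearman"],
            "best_lambda_max": det["best_lambda_max"],
            "m_weight_effect": det["m_weight_effect"],
        }

    if "fit-colors" in config.stages and measurements is not None:
        color_trials = trials_with_fitted_multiples(included, measurements)
        colors = color_analysis(color_trials, min_n=config.min_n)
        write_table(colors["tertiles"], out / "tertiles.tsv", {"master_seed": config.seed})
        glmm = colors["glmm"]
        write_table(
            glmm.odds_factors.reset_index(names="term"),
            out / "glmm_odds_factors.tsv",
            {"master_seed": config.seed},
        )
        report["colors"] = {
            "odds_factors": {
                k: float(v) for k, v in glmm.odds_factors["odds_factor"].items()
            },
            "sigmas": glmm.result.sigmas,
            "adjusted_r2": glmm.adjusted_r2,
            "lr_test": colors["lr_test"],
            "n_seen_trials": glmm.n_trials,
        }

    with open(out / "run_report.yaml", "w") as fh:
        yaml.safe_dump(_plain(report), fh, sort_keys=True)
    return report


def _plain(obj):
    """Recursively convert numpy scalars for YAML serialization."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
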