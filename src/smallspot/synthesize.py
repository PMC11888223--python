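"""End-to-end synthetic study generator.

Emulates a two-subject small-spot microstimulation study: classified
trichromatic mosaics with the subjects' global L/M ratios, test loci
spanning the local proportion-L range (with optional deliberate
oversampling of majority-M pockets), per-locus 543/680 nm thresholds set
by the additive L+M model plus lognormal locus noise, QUEST+ staircase
sessions with catch trials and per-frame delivery jitter, and trial-level
color naming drawn from the logistic model in log2 intensity,
heterogeneity, and S-cone distance.

Every stochastic stage receives a sub-seed derived from the master seed,
so the same configuration and seed reproduce the output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .mosaic import ConeMosaic, cone_spacing, generate_mosaic, nearest_s_distance, write_mosaic
from .optics import build_aperture_map, diffraction_psf, retinal_light_distribution
from .photoreceptors import (
    OcularMediaModel,
    PigmentModel,
    background_isomerization_rate,
    build_fundamentals,
    excitation_table,
    default_mpod_field_size_function,
    mpod_peak,
    unbleached_fraction,
)
from .detection import additive_sensitivity_ratio
from .psychophysics import (
    OFFSET_COLUMNS,
    PsychometricModel,
    run_questplus_block,
    simulate_delivery_offsets,
)
from .sampling import ConeCountKernel, heterogeneity, proportion_L_at_centers

WAVELENGTHS = (543.0, 680.0)


@dataclass
class SubjectConfig:
    """Per-subject study conditions (defaults mirror the two observers)."""

    subject_id: str
    lm_ratio: float                 # global L:M ratio of the classified patch
    n_loci: int
    eccentricity_deg: float
    os_length_um: float
    lambda_max_L: float
    age: float
    n_cones: int = 5000
    spacing: float = 1.1            # arcmin
    s_fraction: float = 0.05
    unclassified_fraction: float = 0.02
    jitter_sd_frac: float = 0.10    # positional jitter as a fraction of spacing
    min_majority_M: int = 0         # deliberate majority-M oversampling
    contamination_rate: float = 0.12  # heavy-tail delivery failures
    base_threshold_543: float = 0.002  # median 543 nm threshold, max-intensity units

    @property
    def fraction_L(self) -> float:
        return self.lm_ratio / (1.0 + self.lm_ratio)


def default_subjects() -> list[SubjectConfig]:
    return [
        SubjectConfig(
            subject_id="S1", lm_ratio=1.47, n_loci=32, eccentricity_deg=2.0,
            os_length_um=35.7, lambda_max_L=563.4, age=40.0,
            n_cones=5200, spacing=1.1, contamination_rate=0.124,
        ),
        SubjectConfig(
            subject_id="S2", lm_ratio=3.66, n_loci=26, eccentricity_deg=2.5,
            os_length_um=32.9, lambda_max_L=558.9, age=27.0,
            n_cones=2200, spacing=1.25, min_majority_M=3, contamination_rate=0.164,
        ),
    ]


@dataclass
class SyntheticStudyConfig:
    """Full study configuration; all rates in [0, 1]."""

    subjects: list[SubjectConfig] = field(default_factory=default_subjects)
    # psychophysics
    trials_per_staircase: int = 25
    n_staircases: int = 2
    catch_rate: float = 0.2
    weibull_beta: float = 3.0
    lapse: float = 0.02
    max_intensity: float = 1.0
    # locus threshold noise (log10 units); calibrated so the synthetic
    # 543 nm sensitivity IQR falls in the observed 0.12-0.16 log10 range
    # and the 680 nm IQR (noise plus topography signal) near 0.22-0.34
    sigma_log10_543: float = 0.10
    sigma_log10_ratio: float = 0.10
    # color-naming logistic model (logit scale)
    beta0: float = -4.0
    beta1: float = float(np.log(2.94))  # per intensity doubling
    beta2: float = float(np.log(5.51))  # per unit heterogeneity
    beta3: float = 0.0                  # per cone spacing of S distance
    sigma_subject: float = 0.3
    sigma_wavelength: float = 1.0
    nonexpected_rate: float = 0.01
    # optics / delivery
    stimulus_side: float = 2.25   # arcmin
    pupil_diameter: float = 6.5   # mm
    residual_defocus: float = 0.05  # diopters
    pixel_pitch: float = 0.11     # arcmin
    grid_size: int = 192
    delivery_sd: tuple[float, float] = (0.09, 0.10)
    recenter_per_trial: bool = True
    master_seed: int = 0

    def validate(self) -> None:
        for name in ("catch_rate", "lapse", "nonexpected_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigError(f"{name} must lie in [0, 1)")
        for s in self.subjects:
            if not 0 < s.fraction_L < 1:
                raise ConfigError("lm_ratio must be positive and finite")
            if s.n_loci < 1:
                raise ConfigError("n_loci must be >= 1")
            footprint = self.stimulus_side + 4.0
            patch = np.sqrt(s.n_cones) * s.spacing  # rough linear patch size
            if patch < 3 * footprint:
                raise ConfigError(
                    f"subject {s.subject_id}: mosaic too small for the stimulus footprint"
                )


@dataclass
class StudyData:
    """Everything the downstream analyses consume."""

    config: SyntheticStudyConfig
    mosaics: dict[str, ConeMosaic]
    loci: pd.DataFrame      # per-locus ground truth
    trials: pd.DataFrame    # one row per trial
    manifest: dict


def subject_excitations(cfg: SyntheticStudyConfig, sub: SubjectConfig,
                        background_cd_m2: float = 1702.0):
    """Observer-specific excitation table via the full receptoral chain."""
    half_stim_deg = (cfg.stimulus_side / 60.0) / 2.0
    mp = mpod_peak(
        sub.eccentricity_deg - half_stim_deg,
        sub.eccentricity_deg + half_stim_deg,
        default_mpod_field_size_function,
    )
    media = OcularMediaModel(age=sub.age, mpod_peak=mp)
    rate = background_isomerization_rate(background_cd_m2, cfg.pupil_diameter)
    pigment = PigmentModel(
        outer_segment_length=sub.os_length_um,
        unbleached_fraction=unbleached_fraction(rate),
    )
    pigment = replace(pigment, lambda_max={**pigment.lambda_max, "L": sub.lambda_max_L})
    fund = build_fundamentals(media, pigment, classes=("L", "M"))
    return excitation_table(fund), media, pigment


def _select_loci(mosaic, kernel, n_loci, min_majority_M, rng, n_candidates=3000, margin=4.0):
    """Quantile-spread locus selection over random candidate sites."""
    hw = mosaic.patch_extent[0] / 2 - margin
    hh = mosaic.patch_extent[1] / 2 - margin
    cand = np.column_stack(
        [rng.uniform(-hw, hw, n_candidates), rng.uniform(-hh, hh, n_candidates)]
    )
    p = proportion_L_at_centers(mosaic, kernel, cand)
    ok = ~np.isnan(p)
    cand, p = cand[ok], p[ok]
    order = np.argsort(p, kind="stable")
    take = order[np.linspace(0, len(order) - 1, n_loci).round().astype(int)]
    take = list(dict.fromkeys(take.tolist()))
    # top up if quantile rounding collapsed duplicates
    pool = [i for i in order.tolist() if i not in set(take)]
    while len(take) < n_loci and pool:
        take.append(pool.pop(rng.integers(len(pool))))
    # deliberate majority-M oversampling
    n_maj_m = int(np.sum(p[take] < 0.5))
    if n_maj_m < min_majority_M:
        extra = [i for i in order.tolist() if p[i] < 0.5 and i not in set(take)]
        replace_idx = [i for i in np.argsort(-p[take]) if p[take][i] >= 0.5]
        for k in range(min(min_majority_M - n_maj_m, len(extra))):
            take[replace_idx[k]] = extra[k]
    return cand[take], p[take]


def synthesize_study(config: SyntheticStudyConfig | None = None) -> StudyData:
    """Generate mosaics, ground-truth loci, and the full trial log."""
    cfg = config or SyntheticStudyConfig()
    cfg.validate()
    ss = np.random.SeedSequence(cfg.master_seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["intercepts"] + [f"subject:{s.subject_id}" for s in cfg.subjects],
            ss.spawn(1 + len(cfg.subjects)),
        )
    }
    rng_top = np.random.default_rng(seeds["intercepts"])
    b_subject = {s.subject_id: float(rng_top.normal(0, cfg.sigma_subject)) for s in cfg.subjects}
    b_wavelength = {w: float(rng_top.normal(0, cfg.sigma_wavelength)) for w in WAVELENGTHS}

    mosaics: dict[str, ConeMosaic] = {}
    loci_rows = []
    trial_frames = []
    for sub in cfg.subjects:
        rng = np.random.default_rng(seeds[f"subject:{sub.subject_id}"])
        mosaic = generate_mosaic(
            n_cones=sub.n_cones,
            spacing=sub.spacing,
            jitter_sd=sub.jitter_sd_frac * sub.spacing,
            fraction_L_of_LM=sub.fraction_L,
            fraction_S=sub.s_fraction,
            fraction_unclassified=sub.unclassified_fraction,
            seed=rng,
            eccentricity_deg=sub.eccentricity_deg,
        )
        mosaics[sub.subject_id] = mosaic
        spacing = cone_spacing(mosaic)
        apertures = build_aperture_map(mosaic)
        kernels = {}
        for w in WAVELENGTHS:
            psf = diffraction_psf(
                w, cfg.pupil_diameter, cfg.residual_defocus,
                cfg.pixel_pitch, cfg.grid_size,
            )
            light = retinal_light_distribution(cfg.stimulus_side, psf)
            kernels[w] = ConeCountKernel(light, apertures)

        exc, _, _ = subject_excitations(cfg, sub)
        centers, p_nominal = _select_loci(
            mosaic, kernels[543.0], sub.n_loci, sub.min_majority_M, rng
        )

        observers = {}
        locus_meta = {}
        for k, (center, pL) in enumerate(zip(centers, p_nominal)):
            locus_id = f"{sub.subject_id}-L{k:02d}"
            thr_543 = sub.base_threshold_543 * 10 ** rng.normal(0, cfg.sigma_log10_543)
            ratio_pred = float(additive_sensitivity_ratio(pL, exc))
            ratio_true = ratio_pred * 10 ** rng.normal(0, cfg.sigma_log10_ratio)
            thr_680 = thr_543 / ratio_true
            s_dist = nearest_s_distance(mosaic, center, spacing=spacing)
            loci_rows.append(
                {
                    "subject_id": sub.subject_id,
                    "locus_id": locus_id,
                    "x_arcmin": center[0],
                    "y_arcmin": center[1],
                    "proportion_L_nominal": pL,
                    "heterogeneity_nominal": heterogeneity(pL),
                    "s_cone_distance": s_dist,
                    "threshold_543": thr_543,
                    "threshold_680": thr_680,
                    "ratio_true": ratio_true,
                    "ratio_additive_pred": ratio_pred,
                }
            )
            for w, thr in ((543.0, thr_543), (680.0, thr_680)):
                observers[(locus_id, w)] = PsychometricModel.from_threshold50(
                    thr, cfg.weibull_beta, gamma=0.0, lapse=cfg.lapse
                )
            locus_meta[locus_id] = {"center": center, "s_dist": s_dist, "pL": pL}

        sessions = run_questplus_block(
            observers,
            subject_id=sub.subject_id,
            n_trials_per_staircase=cfg.trials_per_staircase,
            n_staircases=cfg.n_staircases,
            catch_rate=cfg.catch_rate,
            max_intensity=cfg.max_intensity,
            seed=rng,
        )

        for sess in sessions:
            df = sess.trials.copy()
            n = len(df)
            meta = locus_meta[sess.locus_id]
            offsets = simulate_delivery_offsets(
                n, rng, *cfg.delivery_sd, contamination_rate=sub.contamination_rate
            )
            for c, col in enumerate(OFFSET_COLUMNS):
                df[col] = offsets[:, c]
            if cfg.recenter_per_trial:
                mean_off = np.column_stack(
                    [offsets[:, 0::2].mean(axis=1), offsets[:, 1::2].mean(axis=1)]
                )
                p_trial = proportion_L_at_centers(
                    mosaic, kernels[sess.wavelength], meta["center"] + mean_off
                )
                p_trial = np.where(np.isnan(p_trial), meta["pL"], p_trial)
            else:
                p_trial = np.full(n, meta["pL"])
            df["proportion_L"] = p_trial
            df["heterogeneity"] = heterogeneity(np.clip(p_trial, 0.0, 1.0))
            df["s_cone_distance"] = meta["s_dist"]
            thr_true = observers[(sess.locus_id, sess.wavelength)].threshold(0.5)
            df["intensity_multiple"] = df["intensity"] / thr_true

            # trial-level color naming from the generating logistic model
            seen = df["seen"].to_numpy(dtype=bool)
            im = np.clip(df["intensity_multiple"].to_numpy(dtype=float), 1e-6, None)
            logit = (
                cfg.beta0
                + cfg.beta1 * np.log2(im)
                + cfg.beta2 * df["heterogeneity"].to_numpy(dtype=float)
                + cfg.beta3 * meta["s_dist"]
                + b_subject[sub.subject_id]
                + b_wavelength[sess.wavelength]
            )
            p_exp = 1.0 / (1.0 + np.exp(-logit))
            expected = rng.random(n) < p_exp
            nonexp = rng.random(n) < cfg.nonexpected_rate
            exp_color = "green" if sess.wavelength == 543.0 else "red"
            other_color = "red" if exp_color == "green" else "green"
            resp = np.where(expected, exp_color, np.where(nonexp, other_color, "achromatic"))
            df["color_response"] = np.where(seen, resp, "not_seen")
            trial_frames.append(df)

    trials = pd.concat(trial_frames, ignore_index=True)
    loci = pd.DataFrame(loci_rows)
    manifest = {
        "master_seed": cfg.master_seed,
        "sub_seeds": seeds,
        "random_intercepts": {
            "subject": b_subject,
            "wavelength": {str(k): v for k, v in b_wavelength.items()},
        },
        "config": _config_dict(cfg),
    }
    return StudyData(config=cfg, mosaics=mosaics, loci=loci, trials=trials, manifest=manifest)


def _config_dict(cfg: SyntheticStudyConfig) -> dict:
    d = asdict(cfg)
    d["delivery_sd"] = list(cfg.delivery_sd)
    return d


def write_study(study: StudyData, outdir) -> None:
    """Write the study as a tree of delimited-text tables plus a manifest."""
    from pathlib import Path

    out = Path(outdir)
    (out / "mosaics").mkdir(parents=True, exist_ok=True)
    header = {"master_seed": str(study.config.master_seed)}
    for sid, mosaic in study.mosaics.items():
        write_mosaic(mosaic, out / "mosaics" / f"{sid}.tsv", extra_header=header)
    for name, df in (("loci_ground_truth", study.loci), ("trials", study.trials)):
        with open(out / f"{name}.tsv", "w") as fh:
            fh.write(f"# master_seed = {study.config.master_seed}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    with open(out / "ground_truth_manifest.json", "w") as fh:
        json.dump(study.manifest, fh, indent=2, sort_keys=True)


def read_study(indir) -> StudyData:
    """Load a study tree written by :func:`write_study`."""
    from pathlib import Path

    from .io import read_table
    from .mosaic import read_mosaic

    src = Path(indir)
    manifest = json.loads((src / "ground_truth_manifest.json").read_text())
    d = dict(manifest["config"])
    subjects = [SubjectConfig(**s) for s in d.pop("subjects")]
    d["delivery_sd"] = tuple(d["delivery_sd"])
    cfg = SyntheticStudyConfig(subjects=subjects, **d)
    mosaics = {
        p.stem: read_mosaic(p) for p in sorted((src / "mosaics").glob("*.tsv"))
    }
    loci, _ = read_table(src / "loci_ground_truth.tsv")
    trials, _ = read_table(src / "trials.tsv")
    return StudyData(config=cfg, mosaics=mosaics, loci=loci, trials=trials, manifest=manifest)
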