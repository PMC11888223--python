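"""Simulated detection psychophysics: Weibull observers, QUEST+ adaptive
staircases with uniform catch trials, maximum-likelihood threshold fits at
the 50% frequency-of-seeing point, and the per-frame delivery-quality
trial filter.

Trials are kept in pandas DataFrames with one row per trial; see
``TRIAL_COLUMNS`` for the schema (three delivery frames per trial, as
delivered by the 30 Hz scanner over a ~67 ms flash).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import (
    ConfigError,
    InvalidInputError,
    InvalidParameterError,
    NonIdentifiableError,
)

N_DELIVERY_FRAMES = 3
OFFSET_COLUMNS = [f"offset_{ax}_f{i}" for i in range(1, N_DELIVERY_FRAMES + 1) for ax in ("x", "y")]

TRIAL_COLUMNS = [
    "subject_id",
    "locus_id",
    "wavelength",
    "intensity",            # absolute stimulus units (max intensity = 1)
    "intensity_multiple",   # multiples of the locus's true/fitted threshold
    *OFFSET_COLUMNS,        # per-frame delivery offsets, arcmin
    "seen",
    "color_response",       # red / green / achromatic / not_seen
    "source",               # staircase / random_catch
]

#: per-frame delivery-error criterion, arcmin
DELIVERY_CRITERION = 0.75


@dataclass
class PsychometricModel:
    """Weibull frequency-of-seeing function.

    p(seen | I) = gamma + (1 - gamma - lapse) * (1 - exp(-(I/alpha)^beta))
    """

    alpha: float
    beta: float
    gamma: float = 0.0
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidParameterError("alpha and beta must be > 0")
        if self.gamma < 0 or self.lapse < 0 or self.gamma + self.lapse >= 1:
            raise InvalidParameterError("need gamma, lapse >= 0 and gamma + lapse < 1")

    def p_seen(self, intensity: float | np.ndarray) -> float | np.ndarray:
        i = np.asarray(intensity, dtype=float)
        p = self.gamma + (1 - self.gamma - self.lapse) * (
            1 - np.exp(-((i / self.alpha) ** self.beta))
        )
        return float(p) if p.ndim == 0 else p

    def threshold(self, p: float = 0.5) -> float:
        """Intensity at overall seeing probability p (default 50%)."""
        top = 1 - self.gamma - self.lapse
        q = (p - self.gamma) / top
        if not 0 < q < 1:
            raise InvalidParameterError(f"p={p} not attainable for this model")
        return self.alpha * (-np.log(1 - q)) ** (1.0 / self.beta)

    @classmethod
    def from_threshold50(
        cls, threshold_50: float, beta: float, gamma: float = 0.0, lapse: float = 0.02
    ) -> "PsychometricModel":
        """Construct a model whose 50% frequency-of-seeing point is given."""
        probe = cls(alpha=1.0, beta=beta, gamma=gamma, lapse=lapse)
        return cls(alpha=threshold_50 / probe.threshold(0.5), beta=beta, gamma=gamma, lapse=lapse)


def simulate_detection_response(
    model: PsychometricModel, intensity: float, rng: np.random.Generator
) -> bool:
    """One Bernoulli seen/not-seen draw from the observer model."""
    if intensity < 0:
        raise InvalidParameterError("intensity must be >= 0")
    return bool(rng.random() < model.p_seen(intensity))


# ---------------------------------------------------------------------------
# QUEST+
# ---------------------------------------------------------------------------

class QuestPlus:
    """Bayesian adaptive staircase over a (threshold, slope) parameter grid.

    The posterior starts uniform; each adaptive trial is placed at the
    stimulus intensity minimizing the expected posterior entropy, and the
    posterior is updated with the Bernoulli likelihood of the outcome.
    Guess and lapse rates are fixed.
    """

    def __init__(
        self,
        intensities: np.ndarray | None = None,
        alphas: np.ndarray | None = None,
        betas: np.ndarray | None = None,
        gamma: float = 0.0,
        lapse: float = 0.02,
        max_intensity: float = 1.0,
    ) -> None:
        if intensities is None:
            intensities = np.geomspace(max_intensity * 1e-3, max_intensity, 60)
        if alphas is None:
            alphas = np.geomspace(max_intensity * 1e-3, max_intensity, 60)
        if betas is None:
            betas = np.geomspace(0.5, 8.0, 12)
        self.intensities = np.asarray(intensities, dtype=float)
        aa, bb = np.meshgrid(np.asarray(alphas, float), np.asarray(betas, float), indexing="ij")
        self.alpha_grid = aa.ravel()
        self.beta_grid = bb.ravel()
        # p_seen[i, j]: stimulus i, parameter point j
        ratio = self.intensities[:, None] / self.alpha_grid[None, :]
        self.p_seen = gamma + (1 - gamma - lapse) * (
            1 - np.exp(-(ratio ** self.beta_grid[None, :]))
        )
        self.posterior = np.full(self.alpha_grid.size, 1.0 / self.alpha_grid.size)
        if not np.isfinite(self.posterior).all() or self.posterior.sum() <= 0:
            raise ConfigError("degenerate QUEST+ prior")

    @staticmethod
    def _entropy(p: np.ndarray, axis=None) -> np.ndarray:
        q = np.clip(p, 1e-300, None)
        return -np.sum(q * np.log(q), axis=axis)

    def next_intensity(self) -> float:
        """Intensity minimizing the expected posterior entropy."""
        joint_seen = self.p_seen * self.posterior[None, :]
        p_yes = joint_seen.sum(axis=1)
        post_yes = joint_seen / np.clip(p_yes[:, None], 1e-300, None)
        joint_no = (1 - self.p_seen) * self.posterior[None, :]
        p_no = joint_no.sum(axis=1)
        post_no = joint_no / np.clip(p_no[:, None], 1e-300, None)
        expected = p_yes * self._entropy(post_yes, axis=1) + p_no * self._entropy(post_no, axis=1)
        return float(self.intensities[int(np.argmin(expected))])

    def update(self, intensity: float, seen: bool) -> None:
        i = int(np.argmin(np.abs(self.intensities - intensity)))
        like = self.p_seen[i] if seen else 1 - self.p_seen[i]
        self.posterior *= like
        s = self.posterior.sum()
        if s <= 0:
            raise ConfigError("QUEST+ posterior collapsed to zero mass")
        self.posterior /= s

    def posterior_mode_alpha(self) -> float:
        return float(self.alpha_grid[int(np.argmax(self.posterior))])

    def posterior_entropy(self) -> float:
        return float(self._entropy(self.posterior))


@dataclass
class StaircaseSession:
    """All trials collected at one locus x wavelength, plus the fit."""

    subject_id: str
    locus_id: str
    wavelength: float
    trials: pd.DataFrame
    fitted: PsychometricModel | None = None
    threshold_50: float = float("nan")
    diagnostics: dict = field(default_factory=dict)


def run_questplus_block(
    observers: dict[tuple[str, float], PsychometricModel],
    subject_id: str = "synthetic",
    n_trials_per_staircase: int = 25,
    n_staircases: int = 2,
    catch_rate: float = 0.2,
    max_intensity: float = 1.0,
    start_fractions: tuple[float, ...] = (0.25, 0.75),
    seed: int | np.random.Generator = 0,
    quest_kwargs: dict | None = None,
) -> list[StaircaseSession]:
    """Simulate one measurement block of randomly interleaved staircases.

    ``observers`` maps (locus_id, wavelength) to the generating Weibull
    model.  Per condition, ``n_staircases`` staircases of
    ``n_trials_per_staircase`` adaptive trials each run in parallel; the
    first trial of staircase k starts at ``start_fractions[k]`` of the
    maximum intensity.  On a ``catch_rate`` fraction of trials the QUEST+
    suggestion is replaced by an intensity drawn uniformly on
    [0, max_intensity].  The interleaving order is seeded-random.
    """
    if n_trials_per_staircase < 1:
        raise InvalidParameterError("n_trials_per_staircase must be >= 1")
    if not 0 <= catch_rate < 1:
        raise InvalidParameterError("catch_rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    staircases = []
    for key in observers:
        for k in range(n_staircases):
            q = QuestPlus(max_intensity=max_intensity, **(quest_kwargs or {}))
            start = start_fractions[k % len(start_fractions)] * max_intensity
            staircases.append({"key": key, "quest": q, "n_done": 0, "start": start})
    # randomly interleaved global trial order
    order = np.repeat(np.arange(len(staircases)), n_trials_per_staircase)
    rng.shuffle(order)

    rows: dict[tuple[str, float], list] = {key: [] for key in observers}
    for si in order:
        sc = staircases[si]
        key = sc["key"]
        model = observers[key]
        if sc["n_done"] == 0:
            suggested = sc["start"]
        else:
            suggested = sc["quest"].next_intensity()
        # on a catch trial the QUEST+ suggestion is ignored and the
        # intensity drawn uniformly; the outcome still updates the
        # posterior (it is valid data at a known intensity)
        if catch_rate > 0 and rng.random() < catch_rate:
            intensity = float(rng.uniform(0.0, max_intensity))
            source = "random_catch"
        else:
            intensity = suggested
            source = "staircase"
        seen = simulate_detection_response(model, intensity, rng)
        sc["quest"].update(intensity, seen)
        sc["n_done"] += 1
        rows[key].append((intensity, seen, source))

    sessions = []
    for (locus_id, wavelength), recs in rows.items():
        df = pd.DataFrame(recs, columns=["intensity", "seen", "source"])
        df.insert(0, "wavelength", wavelength)
        df.insert(0, "locus_id", locus_id)
        df.insert(0, "subject_id", subject_id)
        sessions.append(
            StaircaseSession(
                subject_id=subject_id, locus_id=locus_id, wavelength=wavelength, trials=df
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# Weibull threshold fit
# ---------------------------------------------------------------------------

def fit_weibull_threshold(
    intensities: np.ndarray,
    seen: np.ndarray,
    gamma: float = 0.0,
    lapse: float = 0.02,
) -> tuple[PsychometricModel, float, dict]:
    """Maximum-likelihood Weibull fit; returns (model, threshold_50, info).

    Threshold is the intensity at 50% overall frequency of seeing on the
    fitted curve (guess and lapse included).  Raises
    :class:`NonIdentifiableError` when responses are all seen or all
    not-seen.
    """
    i = np.asarray(intensities, dtype=float)
    y = np.asarray(seen, dtype=bool)
    if i.size == 0:
        raise InvalidInputError("no trials to fit")
    if y.all() or (~y).all():
        raise NonIdentifiableError(
            "threshold not identifiable: trials are all "
            + ("seen" if y.all() else "not seen")
        )
    pos = i[i > 0]
    scale = float(np.median(pos)) if pos.size else 1.0
    top = 1 - gamma - lapse

    def nll(params: np.ndarray) -> float:
        alpha = scale * np.exp(params[0])
        beta = np.exp(np.clip(params[1], -4.0, 4.0))
        with np.errstate(over="ignore"):
            p = gamma + top * (1 - np.exp(-np.clip((i / alpha) ** beta, 0.0, 7e2)))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(np.where(y, np.log(p), np.log1p(-p))))

    best = None
    for b0 in (np.log(1.0), np.log(3.0)):
        res = minimize(nll, np.array([0.0, b0]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    model = PsychometricModel(
        alpha=scale * float(np.exp(best.x[0])),
        beta=float(np.exp(best.x[1])),
        gamma=gamma,
        lapse=lapse,
    )
    info = {"loglik": -float(best.fun), "converged": bool(best.success), "n_trials": int(i.size)}
    return model, model.threshold(0.5), info


def fit_session(session: StaircaseSession, include_catch: bool = True) -> StaircaseSession:
    """Fit the Weibull threshold to a session's trials, in place."""
    df = session.trials
    if not include_catch:
        df = df[df["source"] == "staircase"]
    model, thr, info = fit_weibull_threshold(df["intensity"].to_numpy(), df["seen"].to_numpy())
    session.fitted = model
    session.threshold_50 = thr
    session.diagnostics = info | {"include_catch": include_catch}
    return session


# ---------------------------------------------------------------------------
# delivery filter
# ---------------------------------------------------------------------------

def delivery_filter(
    trials: pd.DataFrame, criterion: float = DELIVERY_CRITERION
) -> tuple[pd.DataFrame, float]:
    """Keep trials whose every-frame |x| and |y| delivery offsets are within
    the criterion (arcmin).  Returns (included trials, inclusion %)."""
    if len(trials) == 0:
        raise InvalidInputError("empty trial table")
    missing = [c for c in OFFSET_COLUMNS if c not in trials.columns]
    if missing:
        raise InvalidInputError(f"trial table lacks delivery offsets: {missing}")
    ok = (trials[OFFSET_COLUMNS].abs() <= criterion).all(axis=1)
    included = trials[ok]
    return included, 100.0 * len(included) / len(trials)


def simulate_delivery_offsets(
    n_trials: int,
    rng: np.random.Generator,
    sd_x: float = 0.09,
    sd_y: float = 0.10,
    contamination_rate: float = 0.0,
    contamination_range: tuple[float, float] = (0.9, 2.0),
) -> np.ndarray:
    """Per-frame delivery offsets (n_trials, 6): Gaussian tracking jitter
    with an optional heavy-tail contamination that throws one frame of a
    trial beyond the inclusion criterion (emulating microsaccades)."""
    sds = np.tile([sd_x, sd_y], N_DELIVERY_FRAMES)
    out = rng.normal(0.0, 1.0, size=(n_trials, 2 * N_DELIVERY_FRAMES)) * sds
    if contamination_rate > 0:
        bad = rng.random(n_trials) < contamination_rate
        idx = np.flatnonzero(bad)
        col = rng.integers(0, 2 * N_DELIVERY_FRAMES, size=idx.size)
        mag = rng.uniform(*contamination_range, size=idx.size)
        sign = rng.choice([-1.0, 1.0], size=idx.size)
        out[idx, col] = sign * mag
    return out
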