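"""Seeded generative model for the crowding-training study.

Produces (a) 4AFC constant-stimuli trial tables over a multi-day training
schedule and (b) ROI-averaged block-design BOLD runs, with the statistical
structure the downstream analysis assumes:

* per-observer radial/tangential critical spacings shrinking from a
  pre-training to a post-training value along an exponential learning curve;
* trial outcomes from a cumulative-normal psychometric function with fixed
  4AFC guess rate 0.25 and a small lapse rate;
* BOLD runs of alternating fixation/stimulation blocks with four stimulus
  conditions, gamma-HRF responses, linear drift and AR(1) Gaussian noise;
* an optional per-observer latent "training gain" that scales both the
  radial behavioral shrinkage and the training-induced change in radial
  BOLD suppression, so behavioral and BOLD anisotropy changes correlate
  across observers by construction.

Everything is driven by ``numpy.random.Generator`` streams spawned from a
single seed, so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import bold_pipeline as bp
from .errors import ConfigError, DomainError
from .bold_pipeline import AXES, CONDITIONS, HRFParams

GAP_DIRECTIONS = ("left", "right", "up", "down")
SESSIONS = ("pre", "post")

TRIAL_COLUMNS = [
    "subject_id",
    "day",
    "axis",
    "spacing_deg",
    "gap_direction",
    "response",
    "correct",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObserverParams:
    """Ground-truth parameters of one simulated observer.

    ``gain`` is the latent training gain scaling the behavioral shrinkage
    of both axes; 1.0 means an average learner.
    """

    subject_id: str
    c_rad_pre: float
    c_tan_pre: float
    c_rad_post: float
    c_tan_post: float
    learn_tau: float
    sigma_psy: float
    lapse: float
    guess: float = 0.25
    gain: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c_rad_pre", "c_tan_pre", "c_rad_post", "c_tan_post"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.c_rad_pre < self.c_tan_pre:
            raise ConfigError(
                f"radial elongation violated: c_rad_pre={self.c_rad_pre} < "
                f"c_tan_pre={self.c_tan_pre}"
            )
        if self.c_rad_post > self.c_rad_pre or self.c_tan_post > self.c_tan_pre:
            raise ConfigError("post-training spacing must not exceed pre-training")
        if self.learn_tau < 0:
            raise ConfigError(f"learn_tau must be >= 0, got {self.learn_tau}")
        if self.sigma_psy <= 0:
            raise ConfigError(f"sigma_psy must be > 0, got {self.sigma_psy}")
        if not 0 <= self.lapse <= 0.06:
            raise ConfigError(f"lapse must be in [0, 0.06], got {self.lapse}")
        if self.guess != 0.25:
            raise ConfigError("guess is fixed at 0.25 for the 4AFC task")


@dataclass(frozen=True)
class StudyConfig:
    n_subjects: int = 17
    n_days: int = 4
    trials_per_condition_per_day: int = 337
    spacing_levels: tuple[float, ...] = (0.75, 1.25, 1.75, 2.25, 2.75)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_days < 1:
            raise ConfigError(f"n_days must be >= 1, got {self.n_days}")
        if self.trials_per_condition_per_day < 1:
            raise ConfigError("trials_per_condition_per_day must be >= 1")
        levels = self.spacing_levels
        if len(levels) < 1 or any(s <= 0 for s in levels):
            raise ConfigError("spacing levels must be positive")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ConfigError("spacing levels must be strictly increasing")

    @property
    def trials_per_condition(self) -> int:
        return self.n_days * self.trials_per_condition_per_day


@dataclass(frozen=True)
class PopulationParams:
    """Group-level (mean, sd) summaries the observer sampler draws from.

    Pre-training means/SDs and the post-training endpoints implied by the
    shrinkage parameters default to the study group values: 2.16/1.61 deg
    pre and 1.46/1.05 deg post (radial/tangential).
    """

    c_rad_pre: tuple[float, float] = (2.16, 0.20)
    c_tan_pre: tuple[float, float] = (1.61, 0.15)
    #: pre - post shrinkage (deg) at training gain 1
    rad_shrinkage: tuple[float, float] = (0.70, 0.08)
    tan_shrinkage: tuple[float, float] = (0.56, 0.08)
    learn_tau: tuple[float, float] = (1.0, 0.30)
    sigma_psy: tuple[float, float] = (0.45, 0.08)
    lapse: tuple[float, float] = (0.02, 0.012)
    #: spread of the latent training gain around 1; 0 fixes gain = 1
    gain_sd: float = 0.35
    #: tie the radial BOLD amplitude change to each observer's realized
    #: behavioral anisotropy change (standardized across the sample)
    coupling: bool = True

    def __post_init__(self) -> None:
        for name in (
            "c_rad_pre",
            "c_tan_pre",
            "rad_shrinkage",
            "tan_shrinkage",
            "learn_tau",
            "sigma_psy",
            "lapse",
        ):
            mean, sd = getattr(self, name)
            if mean <= 0 and name != "lapse":
                raise ConfigError(f"{name} mean must be > 0, got {mean}")
            if mean < 0:
                raise ConfigError(f"{name} mean must be >= 0, got {mean}")
            if sd < 0:
                raise ConfigError(f"{name} sd must be >= 0, got {sd}")
        if self.gain_sd < 0:
            raise ConfigError(f"gain_sd must be >= 0, got {self.gain_sd}")


@dataclass(frozen=True)
class BoldConfig:
    """Block-design and noise parameters for the BOLD simulator."""

    tr: float = 2.0
    block_duration: float = 16.0
    n_stim_blocks: int = 8
    n_fix_blocks: int = 9
    runs_per_session: int = 8
    #: condition -> plateau amplitude in PSC units, per session
    amplitudes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_AMPLITUDES
    )
    baseline_level: float = 1000.0
    noise_sd: float = 5.0
    ar1_coef: float = 0.3
    drift_slope: float = 0.05  # signal units per volume
    hrf: HRFParams = field(default_factory=HRFParams)
    #: per-subject, per-(condition, session) amplitude jitter sd (PSC units)
    amplitude_jitter_sd: float = 0.04
    #: how strongly a subject's standardized behavioral anisotropy change
    #: scales their radial pre-to-post amplitude change (0 = uncoupled)
    coupling_strength: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.block_duration <= 0:
            raise ConfigError("tr and block_duration must be > 0")
        bpv = self.block_duration / self.tr
        if abs(bpv - round(bpv)) > 1e-9:
            raise ConfigError("block_duration must be an integer number of TRs")
        if self.n_stim_blocks % len(CONDITIONS) != 0:
            raise ConfigError(
                f"n_stim_blocks must be a multiple of {len(CONDITIONS)}"
            )
        if self.n_fix_blocks != self.n_stim_blocks + 1:
            raise ConfigError(
                "fixation blocks must interleave stimulation blocks "
                "(n_fix_blocks = n_stim_blocks + 1)"
            )
        if not 0 <= self.ar1_coef < 1:
            raise ConfigError(f"ar1_coef must be in [0, 1), got {self.ar1_coef}")
        if self.noise_sd < 0 or self.baseline_level <= 0:
            raise ConfigError("noise_sd must be >= 0 and baseline_level > 0")

    @property
    def block_volumes(self) -> int:
        return int(round(self.block_duration / self.tr))

    @property
    def run_volumes(self) -> int:
        return (self.n_stim_blocks + self.n_fix_blocks) * self.block_volumes


#: Defaults chosen so the pipeline reproduces the qualitative group pattern:
#: pre-training radial suppression (present < absent), tangential facilitation,
#: and a post-training sign reversal of the radial crowding index.  These are
#: generator configuration, not empirical ground truth.
DEFAULT_AMPLITUDES: dict[str, dict[str, float]] = {
    "pre": {
        "radial_present": 0.45,
        "radial_absent": 0.80,
        "tangential_present": 0.85,
        "tangential_absent": 0.70,
    },
    "post": {
        "radial_present": 0.75,
        "radial_absent": 0.72,
        "tangential_present": 0.82,
        "tangential_absent": 0.70,
    },
}


@dataclass
class BoldRun:
    """One ROI-averaged run: signal, stimulation-block schedule, TR.

    ``schedule`` rows are ``(onset_volume, duration_volumes, condition)``;
    fixation fills the gaps (runs start and end with fixation).
    """

    signal: np.ndarray
    schedule: list[tuple[int, int, str]]
    tr: float
    session: str = "pre"
    subject_id: str | None = None
    run_index: int | None = None


# ---------------------------------------------------------------------------
# observer sampling
# ---------------------------------------------------------------------------


def _trunc_draw(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lower: float,
    upper: float,
) -> float:
    """One truncated-normal draw; degenerate sd returns the mean."""
    if sd == 0:
        return float(np.clip(mean, lower, upper))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_observers(
    config: StudyConfig,
    population: PopulationParams = PopulationParams(),
    rng: np.random.Generator | None = None,
) -> list[ObserverParams]:
    """Draw ``config.n_subjects`` observer parameter sets.

    Spacing-like parameters come from normals truncated at 0.1 deg below
    and twice the mean above.  Radial elongation (c_rad_pre >= c_tan_pre)
    is enforced by rejection; post-training values are pre minus a
    gain-scaled non-negative shrinkage, floored at 0.1 deg.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    observers = []
    for i in range(config.n_subjects):
        for _ in range(1000):
            c_rad_pre = _trunc_draw(rng, *population.c_rad_pre, 0.1, 2 * population.c_rad_pre[0])
            c_tan_pre = _trunc_draw(rng, *population.c_tan_pre, 0.1, 2 * population.c_tan_pre[0])
            if c_rad_pre >= c_tan_pre:
                break
        else:  # pragma: no cover - pathological population settings
            raise ConfigError("could not sample c_rad_pre >= c_tan_pre in 1000 tries")
        gain = 1.0
        if population.gain_sd > 0:
            gain = _trunc_draw(rng, 1.0, population.gain_sd, 0.2, 1.8)
        d_rad = gain * _trunc_draw(rng, *population.rad_shrinkage, 0.0, 2 * population.rad_shrinkage[0])
        d_tan = gain * _trunc_draw(rng, *population.tan_shrinkage, 0.0, 2 * population.tan_shrinkage[0])
        observers.append(
            ObserverParams(
                subject_id=f"S{i + 1:02d}",
                c_rad_pre=c_rad_pre,
                c_tan_pre=c_tan_pre,
                c_rad_post=max(c_rad_pre - d_rad, 0.1),
                c_tan_post=max(c_tan_pre - d_tan, 0.1),
                learn_tau=_trunc_draw(rng, *population.learn_tau, 0.05, 2 * population.learn_tau[0]),
                sigma_psy=_trunc_draw(rng, *population.sigma_psy, 0.05, 2 * population.sigma_psy[0]),
                lapse=_trunc_draw(rng, *population.lapse, 0.0, 0.06),
                gain=gain,
            )
        )
    return observers


# ---------------------------------------------------------------------------
# psychophysical trials
# ---------------------------------------------------------------------------


def true_threshold(
    observer: ObserverParams, axis: str, day: int, n_days: int = 4
) -> float:
    """True critical spacing on ``day`` (1-based), exponential learning curve.

    C(day) = C_post + (C_pre - C_post) * exp(-(day - 1) / learn_tau);
    monotone non-increasing in day.
    """
    if axis not in AXES:
        raise DomainError(f"axis must be one of {AXES}, got {axis!r}")
    if not 1 <= day <= n_days:
        raise DomainError(f"day must be in [1, {n_days}], got {day}")
    if axis == "radial":
        c_pre, c_post = observer.c_rad_pre, observer.c_rad_post
    else:
        c_pre, c_post = observer.c_tan_pre, observer.c_tan_post
    if observer.learn_tau == 0:
        return c_pre if day == 1 else c_post
    return c_post + (c_pre - c_post) * float(np.exp(-(day - 1) / observer.learn_tau))


def response_probability(
    observer: ObserverParams, axis: str, day: int, spacing, n_days: int = 4
):
    """P(correct | spacing) on the given day.

    The location of the cumulative normal is set so that accuracy equals
    0.68 exactly at the day's true critical spacing.
    """
    c_day = true_threshold(observer, axis, day, n_days)
    span = 1.0 - observer.guess - observer.lapse
    z_criterion = stats.norm.ppf((0.68 - observer.guess) / span)
    mu = c_day - observer.sigma_psy * z_criterion
    return observer.guess + span * stats.norm.cdf(
        (np.asarray(spacing, dtype=float) - mu) / observer.sigma_psy
    )


def _level_allocation(levels: Sequence[float], n_trials: int) -> np.ndarray:
    """Per-level trial counts: even split, remainder to the largest spacings."""
    n_levels = len(levels)
    counts = np.full(n_levels, n_trials // n_levels, dtype=int)
    rem = n_trials % n_levels
    if rem:
        counts[-rem:] += 1
    return counts


def simulate_training(
    observer: ObserverParams,
    config: StudyConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the full constant-stimuli training schedule for one observer.

    Returns a tidy trial table (one row per trial) with columns
    ``subject_id, day, axis, spacing_deg, gap_direction, response, correct``.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, abs(hash(observer.subject_id)) % 2**32])
        )
    levels = np.asarray(config.spacing_levels)
    counts = _level_allocation(config.spacing_levels, config.trials_per_condition_per_day)
    frames = []
    for day in range(1, config.n_days + 1):
        for axis in AXES:
            spacing = rng.permutation(np.repeat(levels, counts))
            p = response_probability(observer, axis, day, spacing, config.n_days)
            gap = rng.choice(GAP_DIRECTIONS, size=len(spacing))
            correct = rng.random(len(spacing)) < p
            response = gap.copy()
            wrong = ~correct
            if wrong.any():
                # errors pick uniformly among the three other directions
                offsets = rng.integers(1, 4, size=int(wrong.sum()))
                gap_idx = np.array(
                    [GAP_DIRECTIONS.index(g) for g in gap[wrong]]
                )
                response[wrong] = np.asarray(GAP_DIRECTIONS)[(gap_idx + offsets) % 4]
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": observer.subject_id,
                        "day": day,
                        "axis": axis,
                        "spacing_deg": spacing,
                        "gap_direction": gap,
                        "response": response,
                        "correct": correct,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------


def make_schedule(config: BoldConfig, rng: np.random.Generator) -> list[tuple[int, int, str]]:
    """Randomized stimulation-block schedule; each condition appears
    n_stim_blocks / 4 times, alternating with fixation (fixation first)."""
    reps = config.n_stim_blocks // len(CONDITIONS)
    order = list(CONDITIONS) * reps
    rng.shuffle(order)
    bpv = config.block_volumes
    return [(bpv * (2 * k + 1), bpv, cond) for k, cond in enumerate(order)]


def subject_amplitudes(
    config: BoldConfig,
    coupling_score: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, float]]:
    """Per-subject condition amplitudes for both sessions.

    ``coupling_score`` is the subject's standardized behavioral
    anisotropy change; it scales the pre-to-post change of the two radial
    amplitudes (the change in radial suppression) by
    ``1 + coupling_strength * score``, so larger behavioral changes come
    with larger BOLD changes.  All amplitudes additionally receive
    independent Gaussian jitter when an rng is supplied.
    """
    base = config.amplitudes
    for session in SESSIONS:
        if session not in base:
            raise ConfigError(f"amplitudes missing session {session!r}")
        missing = [c for c in CONDITIONS if c not in base[session]]
        if missing:
            raise ConfigError(
                f"amplitudes[{session!r}] missing conditions: {', '.join(missing)}"
            )
    out: dict[str, dict[str, float]] = {s: dict(base[s]) for s in SESSIONS}
    scale = 1.0 + config.coupling_strength * coupling_score
    for cond in ("radial_present", "radial_absent"):
        delta = base["post"][cond] - base["pre"][cond]
        out["post"][cond] = base["pre"][cond] + scale * delta
    if rng is not None and config.amplitude_jitter_sd > 0:
        for session in SESSIONS:
            for cond in CONDITIONS:
                out[session][cond] += float(
                    rng.normal(0.0, config.amplitude_jitter_sd)
                )
    return out


def anisotropy_change_scores(observers: Sequence[ObserverParams]) -> dict[str, float]:
    """Standardized true behavioral anisotropy change per observer.

    z-scored (post - pre) change of (C_r - C_t)/(C_r + C_t); all zeros
    when there is no between-observer variation.
    """
    deltas = np.array(
        [
            (o.c_rad_post - o.c_tan_post) / (o.c_rad_post + o.c_tan_post)
            - (o.c_rad_pre - o.c_tan_pre) / (o.c_rad_pre + o.c_tan_pre)
            for o in observers
        ]
    )
    sd = deltas.std(ddof=1) if len(deltas) > 1 else 0.0
    scores = (deltas - deltas.mean()) / sd if sd > 0 else np.zeros_like(deltas)
    return {o.subject_id: float(z) for o, z in zip(observers, scores)}


def simulate_bold_run(
    config: BoldConfig,
    session: str = "pre",
    rng: np.random.Generator | int | None = None,
    amplitudes: Mapping[str, float] | None = None,
) -> BoldRun:
    """Simulate one ROI-averaged block-design run.

    signal = baseline * (1 + sum_c amp_c/100 * regressor_c)
             + linear drift + AR(1) Gaussian noise,

    where ``regressor_c`` is exactly the unit-peak HRF-convolved boxcar the
    GLM uses, so a zero-noise run passed back through the pipeline returns
    the configured amplitudes identically.
    """
    if session not in SESSIONS:
        raise ConfigError(f"session must be one of {SESSIONS}, got {session!r}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    if amplitudes is None:
        if session not in config.amplitudes:
            raise ConfigError(f"amplitudes missing session {session!r}")
        amplitudes = config.amplitudes[session]
    missing = [c for c in CONDITIONS if c not in amplitudes]
    if missing:
        raise ConfigError(f"missing condition amplitudes: {', '.join(missing)}")

    schedule = make_schedule(config, rng)
    volumes = config.run_volumes
    kernel = bp.hrf_kernel(config.hrf, config.tr)
    design = bp.build_design(schedule, kernel, volumes, config.tr)
    signal = np.full(volumes, 1.0)
    for cond in CONDITIONS:
        signal += amplitudes[cond] / 100.0 * design.column(cond)
    signal *= config.baseline_level
    t = np.arange(volumes, dtype=float)
    signal += config.drift_slope * (t - t.mean())
    if config.noise_sd > 0:
        phi = config.ar1_coef
        innov_sd = config.noise_sd * np.sqrt(1 - phi**2)
        noise = np.empty(volumes)
        noise[0] = rng.normal(0.0, config.noise_sd)
        eps = rng.normal(0.0, innov_sd, size=volumes - 1)
        for i in range(1, volumes):
            noise[i] = phi * noise[i - 1] + eps[i - 1]
        signal = signal + noise
    return BoldRun(signal=signal, schedule=schedule, tr=config.tr, session=session)


def simulate_session(
    config: BoldConfig,
    session: str,
    rng: np.random.Generator,
    amplitudes: Mapping[str, float] | None = None,
    subject_id: str | None = None,
) -> list[BoldRun]:
    """All runs of one scanning session for one subject."""
    runs = []
    for r in range(config.runs_per_session):
        run = simulate_bold_run(config, session, rng, amplitudes)
        run.subject_id = subject_id
        run.run_index = r + 1
        runs.append(run)
    return runs


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    observers: list[ObserverParams]
    trials: pd.DataFrame
    bold_runs: dict[tuple[str, str], list[BoldRun]]  # (subject_id, session) -> runs
    study_config: StudyConfig
    bold_config: BoldConfig
    population: PopulationParams


def simulate_study(
    study_config: StudyConfig = StudyConfig(),
    population: PopulationParams = PopulationParams(),
    bold_config: BoldConfig = BoldConfig(),
    include_bold: bool = True,
) -> StudyData:
    """Generate the complete synthetic study from one seed."""
    root = np.random.SeedSequence(study_config.seed)
    obs_ss, *subject_ss = root.spawn(1 + study_config.n_subjects)
    observers = sample_observers(
        study_config, population, np.random.default_rng(obs_ss)
    )
    scores = anisotropy_change_scores(observers)
    trial_frames = []
    bold_runs: dict[tuple[str, str], list[BoldRun]] = {}
    for obs, ss in zip(observers, subject_ss):
        trial_ss, amp_ss, bold_ss = ss.spawn(3)
        trial_frames.append(
            simulate_training(obs, study_config, np.random.default_rng(trial_ss))
        )
        if include_bold:
            amps = subject_amplitudes(
                bold_config,
                scores[obs.subject_id] if population.coupling else 0.0,
                np.random.default_rng(amp_ss),
            )
            bold_rng = np.random.default_rng(bold_ss)
            for session in SESSIONS:
                bold_runs[(obs.subject_id, session)] = simulate_session(
                    bold_config, session, bold_rng, amps[session], obs.subject_id
                )
    return StudyData(
        observers=observers,
        trials=pd.concat(trial_frames, ignore_index=True),
        bold_runs=bold_runs,
        study_config=study_config,
        bold_config=bold_config,
        population=population,
    )


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"trial table missing columns: {', '.join(missing)}")
    return df


def write_bold_run(run: BoldRun, csv_path: str | Path) -> None:
    """CSV of (volume, signal) plus a JSON sidecar with schedule and TR."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {"volume": np.arange(len(run.signal)), "signal": run.signal}
    ).to_csv(csv_path, index=False)
    sidecar = {
        "tr": run.tr,
        "session": run.session,
        "subject_id": run.subject_id,
        "run_index": run.run_index,
        "schedule": [
            {"onset_volume": int(o), "duration_volumes": int(d), "condition": c}
            for o, d, c in run.schedule
        ],
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_bold_run(csv_path: str | Path) -> BoldRun:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return BoldRun(
        signal=df["signal"].to_numpy(),
        schedule=[
            (b["onset_volume"], b["duration_volumes"], b["condition"])
            for b in meta["schedule"]
        ],
        tr=float(meta["tr"]),
        session=meta.get("session", "pre"),
        subject_id=meta.get("subject_id"),
        run_index=meta.get("run_index"),
    )
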