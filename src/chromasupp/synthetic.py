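"""Seeded generators for schedules and synthetic datasets.

No raw data from the experiments is deposited, so every analysis stage
runs on synthetic inputs with the statistical structure the analysis
assumes: block-design BOLD time courses generated from the two-Gaussian
model plus noise, and 2AFC trial tables from a Bernoulli observer obeying
the cumulative-Gaussian psychometric function.  All generators are pure
functions of (config, seed); seeds are derived hierarchically from one
master seed and recorded in the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .hrf import (
    CONDITIONS,
    BlockTimeCourse,
    ConditionParams,
    HRFTemporalParams,
    TimeGrid,
    model_response,
)
from .psychometrics import CONTRAST_GRID

__all__ = [
    "FmriSchedule",
    "ScheduleConfig",
    "BoldSimConfig",
    "ObserverConfig",
    "schedule_fmri",
    "simulate_bold",
    "simulate_2afc",
    "condition_params_for_peak",
    "study_bold_cohort",
    "study_2afc_cohort",
    "STUDY_PEAK_OFFSETS",
    "STUDY_SIGMAS",
]


@dataclass(frozen=True)
class ScheduleConfig:
    """Block-design session structure of the imaging experiment."""

    n_runs: int = 18
    blocks_per_run: int = 12          # excluding the leading dummy block
    conditions: tuple = CONDITIONS
    per_run_multiplicity: int = 3     # each condition three times per run
    stim_duration_s: float = 15.0
    rest_duration_s: float = 15.0
    awareness_tasks_per_run: int = 13  # one change-detection task per block
    awareness_accuracy: float = 0.987  # per-task success probability
    awareness_error_limit: int = 3     # run excluded if errors exceed this

    def __post_init__(self):
        if self.per_run_multiplicity * len(self.conditions) != self.blocks_per_run:
            raise ValueError(
                "blocks_per_run must equal per_run_multiplicity x n_conditions"
            )


@dataclass
class FmriSchedule:
    """Seeded realisation: per-run condition orders and awareness errors."""

    config: ScheduleConfig
    run_orders: list          # per run: tuple of condition labels (no dummy)
    dummy_conditions: list    # condition shown in each run's dummy block
    awareness_errors: list    # error count per run
    excluded_runs: set = field(default_factory=set)
    seed: int = 0

    def __post_init__(self):
        limit = self.config.awareness_error_limit
        self.excluded_runs = set(self.excluded_runs) | {
            i for i, e in enumerate(self.awareness_errors) if e > limit
        }

    def mark_excluded(self, run_index: int) -> None:
        self.excluded_runs.add(run_index)

    def retained_runs(self) -> list:
        return [i for i in range(self.config.n_runs) if i not in self.excluded_runs]

    def blocks_per_condition(self, include_excluded: bool = False) -> dict:
        runs = range(self.config.n_runs) if include_excluded else self.retained_runs()
        counts = {c: 0 for c in self.config.conditions}
        for i in runs:
            for c in self.run_orders[i]:
                counts[c] += 1
        return counts

    def total_blocks(self, include_excluded: bool = False) -> int:
        return sum(self.blocks_per_condition(include_excluded).values())

    def awareness_accuracy(self) -> float:
        """Realised proportion of correct awareness-task responses."""
        total = self.config.n_runs * self.config.awareness_tasks_per_run
        return 1.0 - sum(self.awareness_errors) / total


def schedule_fmri(config: ScheduleConfig = ScheduleConfig(), seed: int = 0) -> FmriSchedule:
    """Draw one seeded schedule satisfying the multiplicity constraints.

    Each run holds one dummy block followed by `blocks_per_run` blocks in
    pseudorandom order with every condition appearing exactly
    `per_run_multiplicity` times.  Awareness-task errors are Bernoulli
    failures at the configured accuracy; runs with more than
    `awareness_error_limit` errors are excluded.
    """
    rng = np.random.default_rng(seed)
    base = list(config.conditions) * config.per_run_multiplicity
    run_orders, dummies, errors = [], [], []
    for _ in range(config.n_runs):
        order = list(rng.permutation(base))
        run_orders.append(tuple(order))
        dummies.append(str(rng.choice(list(config.conditions))))
        errors.append(int(rng.binomial(config.awareness_tasks_per_run,
                                       1.0 - config.awareness_accuracy)))
    return FmriSchedule(config=config, run_orders=run_orders,
                        dummy_conditions=dummies, awareness_errors=errors,
                        seed=int(seed))


@dataclass(frozen=True)
class BoldSimConfig:
    """Generative settings for one subject's averaged BOLD time courses.

    `noise_sd` is the per-sample Gaussian standard deviation of a single
    block's response in % signal change; averaging over N retained blocks
    shrinks it by sqrt(N).  An optional lag-1 autocorrelation shapes the
    within-block noise.
    """

    temporal: HRFTemporalParams
    per_condition: dict               # condition -> ConditionParams
    noise_sd: float = 0.16            # per block, per sample
    ar1: float = 0.0
    mode: str = "averaged"            # "averaged" | "per_block"
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if self.mode not in ("averaged", "per_block"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")


def _block_noise(rng, n_samples: int, sd: float, ar1: float) -> np.ndarray:
    w = rng.normal(0.0, 1.0, n_samples)
    if ar1 > 0:
        e = np.empty(n_samples)
        e[0] = w[0]
        for i in range(1, n_samples):
            e[i] = ar1 * e[i - 1] + np.sqrt(1 - ar1**2) * w[i]
        w = e
    return sd * w


def simulate_bold(schedule: FmriSchedule, config: BoldSimConfig, seed: int = 0) -> dict:
    """One subject's per-condition block-averaged time courses.

    Returns a mapping condition -> :class:`BlockTimeCourse`.  In
    ``per_block`` mode every retained block of the schedule receives its
    own noise draw before averaging; ``averaged`` mode (default) adds
    equivalent sqrt(N)-scaled noise directly to the mean curve, which is
    what the downstream analysis consumes.
    """
    rng = np.random.default_rng(seed)
    n_samples = len(config.grid.times)
    counts = schedule.blocks_per_condition()
    out = {}
    for c in schedule.config.conditions:
        clean = model_response(config.temporal, config.per_condition[c], config.grid)
        n_blocks = counts[c]
        if config.mode == "per_block":
            acc = np.zeros(n_samples)
            for _ in range(n_blocks):
                acc += clean + _block_noise(rng, n_samples, config.noise_sd, config.ar1)
            avg = acc / n_blocks
        else:
            avg = clean + _block_noise(rng, n_samples,
                                       config.noise_sd / np.sqrt(n_blocks),
                                       config.ar1)
        out[c] = BlockTimeCourse(condition=c, responses=avg,
                                 n_blocks_averaged=n_blocks, grid=config.grid)
    return out


def condition_params_for_peak(
    temporal: HRFTemporalParams,
    target_peak: float,
    condition: str = "/0",
    undershoot_ratio: float = 0.35,
    b: float = 0.004,
    d: float = 0.2,
    grid: TimeGrid = TimeGrid(),
) -> ConditionParams:
    """Condition parameters whose fitted-curve peak equals `target_peak`.

    Keeps the undershoot proportional to the activation (a2 = -ratio*a1)
    and solves for a1 on a dense grid by bisection.
    """
    t = grid.as_array()
    dense = np.arange(t[0], t[-1] + 0.01, 0.01)
    from .hrf import STIM_DURATION, pulse_window_integral

    g1 = pulse_window_integral(temporal.T1, temporal.alpha1, dense - STIM_DURATION, dense)
    g2 = pulse_window_integral(temporal.T2, temporal.alpha2, dense - STIM_DURATION, dense)
    shape = g1 - undershoot_ratio * g2
    drift = b * dense + d

    def peak_minus_target(a1):
        return float((a1 * shape + drift).max()) - target_peak

    hi = max(2.0 * target_peak / max(shape.max(), 1e-9), 1.0)
    a1 = brentq(peak_minus_target, 1e-9, hi, xtol=1e-12)
    return ConditionParams(a1=a1, a2=-undershoot_ratio * a1, b=b, d=d,
                           condition=condition)


@dataclass(frozen=True)
class ObserverConfig:
    """Bernoulli 2AFC observer for one subject.

    Responds "test higher" with probability
    (1 - lapse) * Phi((x - mu_c)/sigma_c) + lapse/2.
    """

    subject: str = "S01"
    mu: dict = field(default_factory=lambda: {c: 0.50 for c in CONDITIONS})
    sigma: dict = field(default_factory=lambda: {c: 0.08 for c in CONDITIONS})
    lapse: float = 0.0
    n_sessions: int = 12
    contrasts: tuple = CONTRAST_GRID
    trials_per_condition_per_session: int = 1
    isi_range_ms: tuple = (1000.0, 2000.0)

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("observer sigma must be positive")
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse rate must lie in [0, 0.5]")


def simulate_2afc(config: ObserverConfig, seed: int = 0) -> pd.DataFrame:
    """Simulate one observer's full session set as a trial table.

    Every session presents each (chroma, contrast) pair
    `trials_per_condition_per_session` times in seeded random order (36
    trials per session at the defaults).  Returns the `trials.csv` schema:
    subject, session, chroma, test_contrast, order, response (+ isi_ms).
    """
    from scipy.special import ndtr

    rng = np.random.default_rng(seed)
    rows = []
    cells = [
        (c, x)
        for c in config.mu
        for x in config.contrasts
        for _ in range(config.trials_per_condition_per_session)
    ]
    for session in range(1, config.n_sessions + 1):
        order = rng.permutation(len(cells))
        for i in order:
            chroma, x = cells[i]
            p = (1 - config.lapse) * ndtr((x - config.mu[chroma]) / config.sigma[chroma]) \
                + config.lapse / 2
            rows.append({
                "subject": config.subject,
                "session": session,
                "chroma": chroma,
                "test_contrast": float(x),
                "order": "test_first" if rng.random() < 0.5 else "test_second",
                "isi_ms": float(rng.uniform(*config.isi_range_ms)),
                "response": bool(rng.random() < p),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort presets mirroring the study conditions.
#
# The fMRI preset reproduces the qualitative suppression pattern: the
# achromatic /0 condition gives the strongest luminance-driven response and
# the weakly saturated /2 the weakest, with /6 > /4 > /2 among the colored
# conditions.  Magnitudes are anchored to the reported group means (V1 mean
# response ~3.14% signal change) and the reported variance decomposition
# (between-subject SD ~0.69, condition-mean spread SD ~0.06, residual
# subject-by-condition SD ~0.10 in % signal change).
# ---------------------------------------------------------------------------

#: Condition offsets (% signal change) around each subject's base peak.
STUDY_PEAK_OFFSETS = {"/0": 0.09, "/2": -0.08, "/4": -0.03, "/6": 0.02}

#: Control experiment (patches on black, no textured background): weak
#: direct patch responses ordered with Chroma but far below significance.
STUDY_CONTROL_OFFSETS = {"/0": -0.015, "/2": -0.005, "/4": 0.005, "/6": 0.015}

#: Study conditions per experiment: group-mean V1 peak, condition offsets,
#: and subject-by-condition interaction SD (all % signal change), anchored
#: to the reported means and ANOVA variance decomposition.
EXPERIMENT_PRESETS = {
    "main": {"mean_peak": 3.14, "offsets": STUDY_PEAK_OFFSETS,
             "interaction_sd": 0.10},
    "control": {"mean_peak": 1.69, "offsets": STUDY_CONTROL_OFFSETS,
                "interaction_sd": 0.19},
}

#: Group-mean psychometric spreads: discrimination is selectively worse
#: (larger sigma) under the weakly saturated /2 patches.
STUDY_SIGMAS = {"/0": 0.080, "/2": 0.105, "/4": 0.068, "/6": 0.075}

STUDY_TEMPORAL = HRFTemporalParams(T1=6.0, T2=16.0, alpha1=2.5, alpha2=4.0)


def study_bold_cohort(
    seed: int,
    n_subjects: int = 13,
    area: str = "V1",
    experiment: str = "main",
    mean_peak: "float | None" = None,
    subject_sd: float = 0.69,
    interaction_sd: "float | None" = None,
    noise_sd_fraction: float = 0.05,
    mode: str = "averaged",
    offsets: "dict | None" = None,
) -> tuple:
    """Simulate a cohort of block-averaged time courses for one area.

    `experiment` selects the study conditions ("main": textured background
    with the suppression pattern /0 > /6 > /4 > /2; "control": black
    background, weak chroma-ordered responses); explicit `mean_peak`,
    `offsets` or `interaction_sd` override the preset.  Per-block noise is
    `noise_sd_fraction` of the cohort mean peak.  Returns
    ``(timecourses, truth)``: a tidy frame in the `timecourses.csv` schema
    (subject, area, condition, t_s, psc, n_blocks) and a frame of the true
    peaks per (subject, condition).
    """
    preset = EXPERIMENT_PRESETS[experiment]
    mean_peak = preset["mean_peak"] if mean_peak is None else mean_peak
    offsets = preset["offsets"] if offsets is None else offsets
    interaction_sd = preset["interaction_sd"] if interaction_sd is None \
        else interaction_sd
    master = np.random.default_rng(seed)
    rows, truth = [], []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        sub_rng = np.random.default_rng(master.integers(2**31))
        base = float(sub_rng.normal(mean_peak, subject_sd))
        base = max(base, 0.8)  # keep responses physiological
        sched = schedule_fmri(seed=int(sub_rng.integers(2**31)))
        per_condition = {}
        for c in CONDITIONS:
            peak = base + offsets[c] \
                + float(sub_rng.normal(0.0, interaction_sd))
            per_condition[c] = condition_params_for_peak(
                STUDY_TEMPORAL, peak, condition=c)
            truth.append({"subject": subject, "area": area,
                          "condition": c, "true_peak": peak})
        cfg = BoldSimConfig(temporal=STUDY_TEMPORAL,
                            per_condition=per_condition,
                            noise_sd=noise_sd_fraction * mean_peak,
                            mode=mode)
        courses = simulate_bold(sched, cfg, seed=int(sub_rng.integers(2**31)))
        for c, tc in courses.items():
            for t, v in zip(tc.grid.times, tc.responses):
                rows.append({"subject": subject, "area": area, "condition": c,
                             "t_s": float(t), "psc": float(v),
                             "n_blocks": tc.n_blocks_averaged})
    return pd.DataFrame(rows), pd.DataFrame(truth)


def study_2afc_cohort(
    seed: int,
    n_subjects: int = 11,
    include_outlier: bool = True,
    subject_sigma_scale_sd: float = 0.15,
    outlier_sigma_factor: float = 4.0,
) -> pd.DataFrame:
    """Simulate the psychophysics cohort as one tidy trial table.

    Subjects share the group-mean sigma pattern up to a lognormal
    per-subject scale; one observer (the last) is generated with
    uniformly inflated sigma to exercise the exclusion rule, as in the
    reported cohort (mean sigma 0.35 against 0.05-0.12).
    """
    master = np.random.default_rng(seed)
    frames = []
    for s in range(n_subjects):
        subject = f"P{s + 1:02d}"
        sub_rng = np.random.default_rng(master.integers(2**31))
        scale = float(np.exp(sub_rng.normal(0.0, subject_sigma_scale_sd)))
        if include_outlier and s == n_subjects - 1:
            scale *= outlier_sigma_factor
        cfg = ObserverConfig(
            subject=subject,
            mu={c: float(0.50 + sub_rng.normal(0.0, 0.005)) for c in CONDITIONS},
            sigma={c: STUDY_SIGMAS[c] * scale for c in CONDITIONS},
        )
        frames.append(simulate_2afc(cfg, seed=int(sub_rng.integers(2**31))))
    return pd.concat(frames, ignore_index=True)
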