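"""Cumulative-Gaussian psychometric analysis of the 2AFC contrast task.

Each trial presents a reference grating (50% max Michelson contrast) and a
test grating (34-66%); the observer reports which had the higher luminance
contrast.  The proportion of "test higher" responses as a function of test
contrast x is fit with the Gaussian CDF

    P(x) = Phi((x - mu) / sigma)

with no lapse parameter.  mu is the contrast of subjective equality and
sigma the spread; under a signal-detection reading a larger sigma means a
lower effective signal-to-noise ratio of the luminance signal, so 1/sigma
serves as the luminance-contrast sensitivity index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

__all__ = [
    "TrialRecord",
    "PsychometricFit",
    "ExclusionResult",
    "CONTRAST_GRID",
    "aggregate_rates",
    "fit_psychometric",
    "threshold_at_criterion",
    "exclude_subjects",
]

#: Nine equally spaced test contrasts spanning the stated 34-66% range.
CONTRAST_GRID = tuple(np.round(np.linspace(0.34, 0.66, 9), 6))

SIGMA_BOUNDS = (1e-4, 1.0)


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial."""

    subject: str
    session: int          # 1-based; the first two sessions are discarded
    chroma: str           # "/0" | "/2" | "/4" | "/6"
    test_contrast: float  # Michelson fraction of the test grating
    order: str            # "test_first" | "test_second"
    response: bool        # True if the test was chosen as higher contrast


@dataclass
class PsychometricFit:
    """Fitted (mu, sigma) of the cumulative-Gaussian psychometric function."""

    mu: float
    sigma: float
    method: str
    goodness: float          # log-likelihood (ml) or -SS on proportions (ls)
    n_trials: int
    flags: list = field(default_factory=list)

    @property
    def sensitivity_index(self) -> float:
        return 1.0 / self.sigma

    def predict(self, x) -> np.ndarray:
        return ndtr((np.asarray(x, float) - self.mu) / self.sigma)


def _trials_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return pd.DataFrame([t.__dict__ for t in trials])


def aggregate_rates(trials, discard_first_sessions: int = 2) -> pd.DataFrame:
    """Per-(chroma, contrast) response counts, discarding early sessions.

    The first `discard_first_sessions` sessions are dropped to avoid the
    strong early learning effect; counts are then pooled over the
    remaining sessions.  Returns columns chroma, test_contrast, n_trials,
    n_chose_test, proportion.
    """
    df = _trials_frame(trials)
    kept = df[df["session"] > discard_first_sessions]
    if kept.empty:
        raise ValueError("no trials remain after discarding the first sessions")
    grouped = (
        kept.groupby(["chroma", "test_contrast"], sort=True)["response"]
        .agg(n_trials="size", n_chose_test="sum")
        .reset_index()
    )
    grouped["n_chose_test"] = grouped["n_chose_test"].astype(int)
    grouped["proportion"] = grouped["n_chose_test"] / grouped["n_trials"]
    return grouped


def _rate_arrays(table: pd.DataFrame):
    x = table["test_contrast"].to_numpy(float)
    n = table["n_trials"].to_numpy(float)
    k = table["n_chose_test"].to_numpy(float)
    return x, n, k


def fit_psychometric(data, method: str = "ml") -> PsychometricFit:
    """Fit (mu, sigma) to one condition's response rates.

    Parameters
    ----------
    data
        Either an aggregated rate table (columns test_contrast, n_trials,
        n_chose_test — a single condition) or raw trials, which are then
        aggregated without session discarding.
    method
        ``"ml"`` (default): trialwise Bernoulli maximum likelihood.
        ``"ls"``: least squares on the observed proportions.

    Degenerate data (all responses identical) produce a boundary fit with
    sigma at its bound, flagged rather than raised.
    """
    if isinstance(data, pd.DataFrame) and "n_trials" in data.columns:
        table = data
    else:
        df = _trials_frame(data)
        table = (
            df.groupby("test_contrast")["response"]
            .agg(n_trials="size", n_chose_test="sum").reset_index()
        )
    x, n, k = _rate_arrays(table)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct contrast levels")
    if method not in ("ml", "ls"):
        raise ValueError(f"unknown fit method {method!r}")

    flags = []
    prop = k / n
    span = x.max() - x.min()
    # moment-style start: interpolate the 0.5 crossing, slope from the
    # probit-transformed proportions
    mu0 = float(np.interp(0.5, np.clip(prop, 1e-3, 1 - 1e-3)[np.argsort(x)],
                          np.sort(x))) if prop.max() > 0.5 > prop.min() \
        else float(x.mean())
    sigma0 = float(np.clip(span / 4, *SIGMA_BOUNDS))

    def negloglik(params):
        mu, log_sigma = params
        p = ndtr((x - mu) / np.exp(log_sigma))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))

    def sq_error(params):
        mu, log_sigma = params
        p = ndtr((x - mu) / np.exp(log_sigma))
        return float(np.sum((prop - p) ** 2))

    objective = negloglik if method == "ml" else sq_error
    log_bounds = (np.log(SIGMA_BOUNDS[0]), np.log(SIGMA_BOUNDS[1]))
    best = None
    for s0 in (sigma0, sigma0 / 4, sigma0 * 4):
        res = minimize(
            objective, np.array([mu0, np.log(np.clip(s0, *SIGMA_BOUNDS))]),
            method="L-BFGS-B",
            bounds=[(x.min() - 2 * span, x.max() + 2 * span), log_bounds],
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = float(best.x[0]), float(np.exp(best.x[1]))

    if np.all(k == 0) or np.all(k == n):
        flags.append("degenerate_responses")
    if sigma <= SIGMA_BOUNDS[0] * 1.01 or sigma >= SIGMA_BOUNDS[1] * 0.99:
        flags.append("sigma_at_bound")
    goodness = -best.fun if method == "ml" else -best.fun
    return PsychometricFit(mu=mu, sigma=sigma, method=method,
                           goodness=float(goodness),
                           n_trials=int(n.sum()), flags=flags)


def threshold_at_criterion(fit: PsychometricFit, criterion: float) -> float:
    """Contrast at which the fitted function reaches `criterion`.

    Closed form mu + sigma * Phi^-1(criterion); the 75% criterion is the
    conventional discrimination threshold.
    """
    if not 0.0 < criterion < 1.0:
        raise ValueError("criterion must lie strictly between 0 and 1")
    return float(fit.mu + fit.sigma * ndtri(criterion))


@dataclass
class ExclusionResult:
    retained: list
    excluded: list
    threshold: float
    margins: dict  # subject -> mean sigma / threshold


def exclude_subjects(mean_sigmas: dict, rule_factor: float = 3.0) -> ExclusionResult:
    """Flag subjects whose mean sigma is far above the cohort.

    A subject whose mean sigma across the four Chroma conditions exceeds
    ``rule_factor`` times the cohort median is excluded (the experiment
    dropped one observer at 0.35 against a 0.05-0.12 cohort).
    """
    if len(mean_sigmas) < 3:
        raise ValueError("exclusion rule needs at least 3 subjects")
    values = np.array(list(mean_sigmas.values()), float)
    threshold = rule_factor * float(np.median(values))
    retained, excluded, margins = [], [], {}
    for subject, s in mean_sigmas.items():
        margins[subject] = float(s / threshold)
        (excluded if s > threshold else retained).append(subject)
    return ExclusionResult(retained=retained, excluded=excluded,
                           threshold=threshold, margins=margins)
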