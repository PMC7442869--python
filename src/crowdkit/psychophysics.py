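"""Psychometric fitting and behavioral crowding-zone geometry.

The observer model for the 4AFC gap-identification task is

    P(correct | s) = guess + (1 - guess - lapse) * Phi((s - mu) / sigma)

with the guess rate fixed at 0.25 and the lapse rate bounded in
[0, 0.06].  The critical spacing is the spacing at which the fitted curve
predicts 68% correct, obtained by analytic inversion of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .errors import DomainError
from .synthetic_data import TRIAL_COLUMNS

GUESS_4AFC = 0.25
LAPSE_MAX = 0.06
CRITERION = 0.68


@dataclass
class PsychometricFit:
    mu: float
    sigma: float
    lapse: float
    loglik: float
    converged: bool
    n_trials: int
    guess: float = GUESS_4AFC

    def predict(self, spacing) -> np.ndarray | float:
        """Predicted P(correct) at the given spacing(s)."""
        z = (np.asarray(spacing, dtype=float) - self.mu) / self.sigma
        p = self.guess + (1.0 - self.guess - self.lapse) * stats.norm.cdf(z)
        return float(p) if np.isscalar(spacing) else p


@dataclass
class CrowdingZone:
    """Radial/tangential critical spacings with derived geometry."""

    c_r: float
    c_t: float

    @property
    def ratio(self) -> float:
        return self.c_r / self.c_t

    @property
    def a_psy(self) -> float:
        return anisotropy_psy(self.c_r, self.c_t)


def _aggregate(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level (spacing, n, k) from a trial table or record sequence."""
    if isinstance(trials, pd.DataFrame):
        spacing = trials["spacing_deg"].to_numpy(dtype=float)
        correct = trials["correct"].to_numpy(dtype=bool)
    else:
        rows = list(trials)
        spacing = np.array([getattr(r, "spacing_deg", None) or r["spacing_deg"] for r in rows], dtype=float)
        correct = np.array([getattr(r, "correct", None) if hasattr(r, "correct") else r["correct"] for r in rows], dtype=bool)
    levels, inv = np.unique(spacing, return_inverse=True)
    n = np.bincount(inv, minlength=len(levels)).astype(float)
    k = np.bincount(inv, weights=correct.astype(float), minlength=len(levels))
    return levels, n, k


_SQRT2PI = math.sqrt(2.0 * math.pi)


def _nll(params, levels, n, k, guess):
    mu, sigma, lapse = params
    # ndtr instead of stats.norm.cdf: ~100x less overhead in the hot loop
    p = guess + (1.0 - guess - lapse) * ndtr((levels - mu) / sigma)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _nll_grad(params, levels, n, k, guess):
    """Negative log-likelihood and its analytic gradient in (mu, sigma, lapse)."""
    mu, sigma, lapse = params
    w = 1.0 - guess - lapse
    z = (levels - mu) / sigma
    cdf = ndtr(z)
    p = np.clip(guess + w * cdf, 1e-9, 1 - 1e-9)
    nll = -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))
    dl_dp = k / p - (n - k) / (1.0 - p)
    pdf = np.exp(-0.5 * z * z) / _SQRT2PI
    g_mu = -float(np.sum(dl_dp * w * pdf * (-1.0 / sigma)))
    g_sigma = -float(np.sum(dl_dp * w * pdf * (-z / sigma)))
    g_lapse = -float(np.sum(dl_dp * (-cdf)))
    return nll, np.array([g_mu, g_sigma, g_lapse])


def fit_psychometric_counts(
    levels: Sequence[float],
    n: Sequence[float],
    k: Sequence[float],
    guess: float = GUESS_4AFC,
) -> PsychometricFit:
    """Maximum-likelihood fit on per-level aggregated counts.

    Multi-start bounded L-BFGS-B over (mu, sigma, lapse); ties in
    log-likelihood are broken toward the smallest sigma.  Degenerate data
    (all correct, all incorrect, or an essentially flat fitted curve) are
    returned with ``converged=False`` and boundary estimates rather than
    as a silent success.
    """
    levels = np.asarray(levels, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if len(levels) < 2:
        raise DomainError("need at least 2 distinct spacing levels")
    if np.any(n <= 0):
        raise DomainError("every spacing level needs at least one trial")
    if np.any(k < 0) or np.any(k > n):
        raise DomainError("per-level correct counts must satisfy 0 <= k <= n")
    n_trials = int(round(n.sum()))
    span = levels.max() - levels.min()

    if k.sum() == 0:
        fit = PsychometricFit(
            mu=float(levels.max() + span), sigma=span, lapse=0.0,
            loglik=-_nll((levels.max() + span, span, 0.0), levels, n, k, guess),
            converged=False, n_trials=n_trials, guess=guess,
        )
        return fit
    if k.sum() == n.sum():
        return PsychometricFit(
            mu=float(levels.min() - span), sigma=span, lapse=0.0,
            loglik=-_nll((levels.min() - span, span, 0.0), levels, n, k, guess),
            converged=False, n_trials=n_trials, guess=guess,
        )

    lo_mu, hi_mu = levels.min() - 3 * span, levels.max() + 3 * span
    bounds = [(lo_mu, hi_mu), (1e-3, 10 * span), (0.0, LAPSE_MAX)]
    starts = [
        (np.quantile(levels, 0.5), 0.3 * span),
        (np.quantile(levels, 0.25), 0.15 * span),
        (np.quantile(levels, 0.25), 0.6 * span),
        (np.quantile(levels, 0.75), 0.15 * span),
        (np.quantile(levels, 0.75), 0.6 * span),
    ]
    best = None
    for mu0, s0 in starts:
        res = optimize.minimize(
            _nll_grad, x0=(mu0, s0, 0.02), args=(levels, n, k, guess),
            method="L-BFGS-B", jac=True, bounds=bounds,
        )
        if best is None or res.fun < best.fun - 1e-9 or (
            abs(res.fun - best.fun) <= 1e-9 and res.x[1] < best.x[1]
        ):
            best = res
    mu, sigma, lapse = best.x
    pred = guess + (1 - guess - lapse) * ndtr((levels - mu) / sigma)
    flat = pred.max() - pred.min() < 0.05
    at_bound = (
        mu <= lo_mu + 1e-6 or mu >= hi_mu - 1e-6 or sigma >= 10 * span - 1e-6
    )
    return PsychometricFit(
        mu=float(mu),
        sigma=float(sigma),
        lapse=float(lapse),
        loglik=-float(best.fun),
        converged=bool(best.success) and not flat and not at_bound,
        n_trials=n_trials,
        guess=guess,
    )


def fit_psychometric(trials, guess: float = GUESS_4AFC) -> PsychometricFit:
    """Fit the 4AFC cumulative-normal model to one subject x axis x day cell."""
    levels, n, k = _aggregate(trials)
    return fit_psychometric_counts(levels, n, k, guess)


def threshold_at(fit: PsychometricFit, criterion: float = CRITERION) -> float:
    """Spacing at which the fitted curve predicts ``criterion`` accuracy.

    Analytic inversion: s* = mu + sigma * Phi^-1((c - guess)/(1 - guess - lapse)).
    """
    span = 1.0 - fit.guess - fit.lapse
    q = (criterion - fit.guess) / span
    if not 0.0 < q < 1.0:
        raise DomainError(
            f"criterion {criterion} outside attainable range "
            f"({fit.guess}, {1 - fit.lapse})"
        )
    return float(fit.mu + fit.sigma * stats.norm.ppf(q))


def anisotropy_psy(c_r: float, c_t: float) -> float:
    """Behavioral anisotropy index (C_r - C_t) / (C_r + C_t)."""
    if c_r <= 0 or c_t <= 0:
        raise DomainError(f"critical spacings must be > 0, got ({c_r}, {c_t})")
    return (c_r - c_t) / (c_r + c_t)


def weber_contrast(stim_luminance: float, background_luminance: float) -> float:
    """|L_stim - L_background| / L_background."""
    if background_luminance <= 0:
        raise DomainError(
            f"background luminance must be > 0, got {background_luminance}"
        )
    return abs(stim_luminance - background_luminance) / background_luminance


def fit_day_thresholds(
    trials: pd.DataFrame, criterion: float = CRITERION
) -> pd.DataFrame:
    """Fit every subject x axis x day cell of a trial table.

    Returns one row per cell with the fit parameters and the critical
    spacing at ``criterion`` (NaN where the fit did not converge or the
    criterion is unattainable).
    """
    rows = []
    for (subject, axis, day), cell in trials.groupby(
        ["subject_id", "axis", "day"], sort=True
    ):
        fit = fit_psychometric(cell)
        try:
            thr = threshold_at(fit, criterion) if fit.converged else math.nan
        except DomainError:
            thr = math.nan
        rows.append(
            {
                "subject_id": subject,
                "axis": axis,
                "day": day,
                "mu": fit.mu,
                "sigma": fit.sigma,
                "lapse": fit.lapse,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "n_trials": fit.n_trials,
                "critical_spacing": thr,
            }
        )
    return pd.DataFrame(rows)


def crowding_zones(fits: pd.DataFrame) -> pd.DataFrame:
    """Per subject x day crowding-zone geometry from a fit table."""
    wide = fits.pivot_table(
        index=["subject_id", "day"], columns="axis", values="critical_spacing"
    ).reset_index()
    wide = wide.rename(columns={"radial": "c_r", "tangential": "c_t"})
    valid = (wide["c_r"] > 0) & (wide["c_t"] > 0)
    wide["ratio"] = np.where(valid, wide["c_r"] / wide["c_t"], np.nan)
    wide["a_psy"] = np.where(
        valid, (wide["c_r"] - wide["c_t"]) / (wide["c_r"] + wide["c_t"]), np.nan
    )
    wide.columns.name = None
    return wide[["subject_id", "day", "c_r", "c_t", "ratio", "a_psy"]]
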