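"""Looming / dimming stimulus profiles and contrast-response psychometrics.

A loom simulates an object of half-size L approaching at constant speed V:
its angular size is theta(t) = 2 * atan((L/V) / (t_c - t)) where t_c is the
time of collision.  The matched dimming control has fixed angular size
(the loom's final size) and dims so that the instantaneous whole-field
luminance change equals the loom's solid-angle-weighted change.

Escape probability versus contrast is fitted with a logistic function whose
lower asymptote is constrained to zero, by maximum likelihood on the
Bernoulli trial counts, with a parametric bootstrap for goodness of fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import binom

# nominal contrast fractions and their projector luminance calibration (lux);
# the lux table is metadata only - analyses use the nominal fractions
CONTRAST_LUX = {1.0: 252.0, 0.8: 268.0, 0.6: 294.0, 0.4: 334.0, 0.2: 392.0}
BACKGROUND_LUX = 464.0


@dataclass
class LoomStimulus:
    l_over_v: float = 0.255        # s (behavior assay); imaging variant 0.490
    start_angle: float = 10.0      # deg
    end_angle: float = 100.0       # deg (imaging variant 70)
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.l_over_v <= 0:
            raise ValueError("l_over_v must be > 0")
        if self.end_angle <= self.start_angle:
            raise ValueError("end_angle must exceed start_angle")

    def time_at_angle(self, theta_deg) -> np.ndarray:
        """Time (s, from expansion start) at which the loom reaches theta.

        Inverse of the angular-size formula: t_c - t = (L/V)/tan(theta/2),
        with t=0 at theta = start_angle.
        """
        theta = np.clip(np.asarray(theta_deg, dtype=float),
                        self.start_angle, self.end_angle)
        ttc = self.l_over_v / np.tan(np.deg2rad(theta) / 2.0)
        ttc0 = self.l_over_v / np.tan(np.deg2rad(self.start_angle) / 2.0)
        return ttc0 - ttc

    @property
    def expansion_duration(self) -> float:
        return float(self.time_at_angle(self.end_angle))


def loom_angle_profile(stim: LoomStimulus, t) -> np.ndarray:
    """Angular size theta(t) in degrees, clipped to [start_angle, end_angle].

    t is seconds from expansion start (when theta = start_angle); times at
    or beyond the end-angle instant return end_angle.
    """
    t = np.asarray(t, dtype=float)
    ttc0 = stim.l_over_v / np.tan(np.deg2rad(stim.start_angle) / 2.0)
    ttc = ttc0 - t
    theta = np.full_like(ttc, stim.end_angle, dtype=float)
    ahead = ttc > 0
    theta[ahead] = 2.0 * np.degrees(np.arctan(stim.l_over_v / ttc[ahead]))
    return np.clip(theta, stim.start_angle, stim.end_angle)


def _solid_angle(theta_deg):
    """Solid angle (sr) of a cone of full angular size theta."""
    return 2.0 * np.pi * (1.0 - np.cos(np.deg2rad(theta_deg) / 2.0))


def dimming_profile(stim: LoomStimulus, t) -> np.ndarray:
    """Intensity deficit (0..contrast) of the luminance-matched dimming disc.

    The disc has fixed angular size equal to the loom's final size; at every
    instant its dimming level makes the integrated (solid-angle-weighted)
    luminance change equal that of the expanding loom:
    c(t) * Omega(end) = contrast * Omega(theta(t)).
    """
    theta = loom_angle_profile(stim, t)
    return stim.contrast * _solid_angle(theta) / _solid_angle(stim.end_angle)


@dataclass
class PsychometricResults:
    """MLE logistic fit of escape probability versus stimulus contrast."""

    alpha: float               # threshold (contrast at half saturation)
    beta: float                # slope, per contrast unit
    lapse: float               # upper-asymptote shortfall (0 unless freed)
    log_likelihood: float
    contrasts: np.ndarray
    escapes: np.ndarray
    trials: np.ndarray
    gof_p: float = np.nan      # bootstrap deviance p-value
    alpha_ci: tuple = (np.nan, np.nan)

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return (1.0 - self.lapse) / (1.0 + np.exp(-self.beta * (c - self.alpha)))

    @property
    def deviance(self) -> float:
        p_sat = np.clip(self.escapes / self.trials, 1e-12, 1 - 1e-12)
        ll_sat = np.sum(self.escapes * np.log(p_sat)
                        + (self.trials - self.escapes) * np.log(1 - p_sat))
        return float(2.0 * (ll_sat - self.log_likelihood))

    def summary(self) -> str:
        lines = ["Psychometric logistic fit (lower asymptote fixed at 0)",
                 f"  alpha (threshold)  {self.alpha:8.4f}"
                 f"   95% CI [{self.alpha_ci[0]:.4f}, {self.alpha_ci[1]:.4f}]",
                 f"  beta  (slope)      {self.beta:8.4f}",
                 f"  lapse              {self.lapse:8.4f}",
                 f"  deviance           {self.deviance:8.4f}"
                 f"   bootstrap GOF p = {self.gof_p:.3f}"]
        return "\n".join(lines)


class NonIdentifiableFitError(ValueError):
    pass


def _nll(params, c, k, n, free_lapse):
    if free_lapse:
        alpha, logbeta, logit_lapse = params
        lapse = 0.25 / (1.0 + np.exp(-logit_lapse))  # lapse in (0, 0.25)
    else:
        alpha, logbeta = params
        lapse = 0.0
    beta = np.exp(logbeta)
    p = (1.0 - lapse) / (1.0 + np.exp(-beta * (c - alpha)))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(k * np.log(p) + (n - k) * np.log(1 - p))


def fit_psychometric(contrasts, escapes, trials, free_lapse: bool = False,
                     n_boot: int = 1000,
                     rng: np.random.Generator | None = None) -> PsychometricResults:
    """Fit P(escape | c) = (1 - lambda) * logistic(beta * (c - alpha)).

    The lower asymptote (guess rate) is zero; the lapse rate is fixed at 0
    by default.  Bootstrap (parametric, default 1000 resamples) yields a
    goodness-of-fit p-value (fraction of simulated deviances exceeding the
    observed) and an alpha confidence interval.
    """
    c = np.asarray(contrasts, dtype=float)
    k = np.asarray(escapes, dtype=float)
    n = np.asarray(trials, dtype=float)
    if len(c) < 3:
        raise ValueError("need >= 3 contrast levels")
    if np.all(k == 0) or np.all(k == n):
        raise NonIdentifiableFitError("all-zero or all-one responses")
    rng = rng or np.random.default_rng(0)

    def fit_once(kk):
        span = c.max() - c.min()
        best = None
        for a0 in np.linspace(c.min(), c.max(), 5):
            for b0 in (2.0 / span, 10.0 / span):
                x0 = [a0, np.log(b0)] + ([0.0] if free_lapse else [])
                res = minimize(_nll, x0, args=(c, kk, n, free_lapse),
                               method="Nelder-Mead",
                               options=dict(xatol=1e-7, fatol=1e-10, maxiter=2000))
                if best is None or res.fun < best.fun:
                    best = res
        return best

    best = fit_once(k)
    alpha = float(best.x[0])
    beta = float(np.exp(best.x[1]))
    lapse = float(0.25 / (1.0 + np.exp(-best.x[2]))) if free_lapse else 0.0
    result = PsychometricResults(alpha=alpha, beta=beta, lapse=lapse,
                                 log_likelihood=float(-best.fun),
                                 contrasts=c, escapes=k, trials=n)
    if n_boot > 0:
        p_hat = result.predict(c)
        dev_obs = result.deviance
        devs = np.empty(n_boot)
        alphas = np.empty(n_boot)
        for b in range(n_boot):
            kk = binom.rvs(n.astype(int), p_hat, random_state=rng)
            if np.all(kk == 0) or np.all(kk == n):
                devs[b] = 0.0
                alphas[b] = alpha
                continue
            rb = fit_once(kk.astype(float))
            alphas[b] = rb.x[0]
            p_sat = np.clip(kk / n, 1e-12, 1 - 1e-12)
            ll_sat = np.sum(kk * np.log(p_sat) + (n - kk) * np.log(1 - p_sat))
            devs[b] = 2.0 * (ll_sat + rb.fun)
        result.gof_p = float(np.mean(devs >= dev_obs))
        result.alpha_ci = (float(np.quantile(alphas, 0.025)),
                           float(np.quantile(alphas, 0.975)))
    return result


def critical_angle_at_escape(stim: LoomStimulus, escape_onset: float,
                             stimulus_onset: float = 0.0) -> float:
    """Angular size of the loom at escape onset (the critical angular size)."""
    return float(loom_angle_profile(stim, escape_onset - stimulus_onset))
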