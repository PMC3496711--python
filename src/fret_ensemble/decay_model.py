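"""Ensemble donor-decay synthesis and exponential fitting.

A binned efficiency distribution maps to a weighted sum of exponential
decays, I(t) = sum_n w_n exp(-t / (tau0D (1 - E_n))), which is then fit
with single or double exponential models; lifetime-derived ("apparent")
average efficiencies follow from the amplitude-weighted mean lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from fret_ensemble.population_sim import EfficiencyDistribution


@dataclass(frozen=True)
class DecayCurve:
    """Time-resolved donor intensity, normalized to 1 at t = 0."""

    times: np.ndarray
    intensities: np.ndarray
    weight_at_zero_lifetime: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", i)
        if t.size != i.size or t.size < 2:
            raise ValueError("times and intensities must match and have >= 2 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DecayCurve":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {"time_ns": self.times, "intensity": self.intensities}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ExpFitResult:
    """Result of a constrained multi-exponential fit.

    Amplitudes are non-negative and sum to 1; lifetimes are sorted
    ascending for two-component fits.  ``converged`` is False (with a
    message) instead of raising when the optimizer fails.
    """

    n_components: int
    amplitudes: np.ndarray
    lifetimes: np.ndarray
    weighted_residuals: np.ndarray
    chi2_reduced: float
    converged: bool = True
    message: str = ""

    @property
    def amplitude_weighted_lifetime(self) -> float:
        return float(np.dot(self.amplitudes, self.lifetimes))


def synthesize_decay(
    dist: EfficiencyDistribution,
    tau0D: float,
    t_max: float | None = None,
    n_points: int = 1024,
) -> DecayCurve:
    """Build the ensemble donor decay from a binned efficiency distribution.

    I(t) = sum_n w_n exp(-t / tau_n) with tau_n = tau0D (1 - E_n) at the
    bin centers and w_n the normalized bin probabilities.  Bins at E = 1
    have zero lifetime (infinitely fast component); they contribute only at
    t = 0 and their weight is recorded on the curve.
    """
    if tau0D <= 0:
        raise ValueError("tau0D must be > 0")
    if n_points < 2:
        raise ValueError("need at least 2 time points")
    weights = dist.probabilities
    total = weights.sum()
    if total <= 0:
        raise ValueError("efficiency distribution carries no probability mass")
    weights = weights / total
    lifetimes = tau0D * (1.0 - dist.bin_centers)

    live = lifetimes > 0
    w_zero = float(weights[~live].sum())
    if t_max is None:
        t_max = 4.0 * tau0D
    t = np.linspace(0.0, t_max, n_points)
    intensity = np.exp(-t[:, None] / lifetimes[live][None, :]) @ weights[live]
    intensity[0] += w_zero  # zero-lifetime mass decays within the first instant
    return DecayCurve(times=t, intensities=intensity, weight_at_zero_lifetime=w_zero)


def _multi_exp(t: np.ndarray, amplitudes: np.ndarray, lifetimes: np.ndarray) -> np.ndarray:
    return np.exp(-t[:, None] / lifetimes[None, :]) @ amplitudes


def fit_exponentials(
    curve: DecayCurve,
    n_components: int = 1,
    weights: np.ndarray | None = None,
) -> ExpFitResult:
    """Constrained least-squares fit of a 1- or 2-exponential decay model.

    The model is sum_i a_i exp(-t/tau_i) with a_i >= 0 and sum a_i = 1
    (enforced by parametrizing the first amplitude as a bounded fraction).
    Residuals are uniformly weighted unless ``weights`` is given (e.g.
    Poisson sqrt(I) weights for noisy data).  Non-convergence is reported
    on the result, not raised.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    t, I = curve.times, curve.intensities
    if t.size < 10:
        raise ValueError("need at least 10 time points to fit")
    w = np.ones_like(I) if weights is None else np.asarray(weights, dtype=float)

    # moment-based initial lifetime: integral of I approx <tau> for a mixture
    tau_guess = max(float(np.trapezoid(I, t)), 1e-3 * (t[-1] - t[0]))

    if n_components == 1:
        def resid(p):
            return (np.exp(-t / p[0]) - I) * w

        p0 = [tau_guess]
        lb, ub = [1e-9], [np.inf]
    else:
        def resid(p):
            f, tau1, tau2 = p
            model = f * np.exp(-t / tau1) + (1.0 - f) * np.exp(-t / tau2)
            return (model - I) * w

        p0 = [0.5, 0.5 * tau_guess, 2.0 * tau_guess]
        lb, ub = [0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]

    sol = least_squares(resid, p0, bounds=(lb, ub))
    if n_components == 1:
        amplitudes = np.array([1.0])
        lifetimes = np.array([sol.x[0]])
    else:
        f, tau1, tau2 = sol.x
        amplitudes = np.array([f, 1.0 - f])
        lifetimes = np.array([tau1, tau2])
        order = np.argsort(lifetimes)
        lifetimes, amplitudes = lifetimes[order], amplitudes[order]

    residuals = resid(sol.x)
    dof = max(t.size - len(sol.x), 1)
    return ExpFitResult(
        n_components=n_components,
        amplitudes=amplitudes,
        lifetimes=lifetimes,
        weighted_residuals=residuals,
        chi2_reduced=float(np.sum(residuals**2) / dof),
        converged=bool(sol.success),
        message=str(sol.message),
    )


def apparent_efficiency(
    dist_or_fit: Union[EfficiencyDistribution, ExpFitResult], tau0D: float
) -> float:
    """Lifetime-derived average FRET efficiency, 1 - <tau>/tau0D.

    For an efficiency distribution, <tau> is the probability-weighted
    (amplitude-weighted) mean of the binned lifetimes tau_n = tau0D (1 - E_n);
    E = 1 bins contribute tau_n = 0.  For a fit result, <tau> is the
    amplitude-weighted mean of the fitted lifetimes.
    """
    if tau0D <= 0:
        raise ValueError("tau0D must be > 0")
    if isinstance(dist_or_fit, ExpFitResult):
        mean_tau = dist_or_fit.amplitude_weighted_lifetime
    else:
        p = dist_or_fit.probabilities
        tau_n = tau0D * (1.0 - dist_or_fit.bin_centers)
        mean_tau = float(np.dot(p, tau_n) / p.sum())
    return 1.0 - mean_tau / tau0D


def add_poisson_noise(
    curve: DecayCurve, peak_counts: float, seed: int | None = None
) -> DecayCurve:
    """Optional realism layer: Poisson counting noise scaled to a peak count."""
    if peak_counts <= 0:
        raise ValueError("peak_counts must be > 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(curve.intensities * peak_counts)
    return DecayCurve(
        times=curve.times,
        intensities=counts / peak_counts,
        weight_at_zero_lifetime=curve.weight_at_zero_lifetime,
    )
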