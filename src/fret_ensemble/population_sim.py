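"""Monte-Carlo population engines for ensemble FRET efficiency distributions.

Distance-heterogeneity, acceptor dark-state, and orientational-regime
simulations, each producing a binned efficiency distribution with summary
statistics.  All simulations use a single seeded numpy Generator so that
identical (parameters, seed) yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from fret_ensemble.forster_core import (
    ForsterSystem,
    efficiency_from_distance,
    efficiency_from_rate,
    transfer_rate,
)
from fret_ensemble.orientation import static_transfer_rate

DEFAULT_N = 100_000
DEFAULT_BIN_WIDTH = 0.01


@dataclass(frozen=True)
class DistancePopulation:
    """A sampled population of donor-acceptor separations (nm).

    Draws at or below zero are dropped, not resampled, so ``n_retained``
    may be smaller than ``n_requested``; summary statistics always use the
    retained values.
    """

    values: np.ndarray
    mean: float
    sd: float
    n_requested: int
    n_retained: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.values <= 0):
            raise ValueError("retained distances must all be > 0")
        if self.n_retained != self.values.size:
            raise ValueError("n_retained inconsistent with values")


@dataclass(frozen=True)
class EfficiencyDistribution:
    """Binned probability density of FRET efficiency over [0, 1].

    ``densities`` are normalized so that sum(density * bin_width) == 1.
    ``mean_E`` and ``sd_E`` are computed from the raw (unbinned) values.
    """

    bin_edges: np.ndarray
    densities: np.ndarray
    mean_E: float
    sd_E: float
    n: int
    seed: int | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def probabilities(self) -> np.ndarray:
        """Per-bin probability mass (density * bin width)."""
        return self.densities * np.diff(self.bin_edges)

    @classmethod
    def from_values(
        cls,
        efficiencies: np.ndarray,
        bin_width: float = DEFAULT_BIN_WIDTH,
        seed: int | None = None,
    ) -> "EfficiencyDistribution":
        """Bin raw efficiency values on a uniform grid over [0, 1].

        The final bin is right-closed (E == 1 falls in the last bin, the
        numpy histogram convention).
        """
        e = np.asarray(efficiencies, dtype=float)
        if e.size == 0:
            raise ValueError("cannot bin an empty set of efficiencies")
        if np.any((e < 0) | (e > 1)):
            raise ValueError("efficiencies must lie in [0, 1]")
        n_bins = int(round(1.0 / bin_width))
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        densities, _ = np.histogram(e, bins=edges, density=True)
        return cls(
            bin_edges=edges,
            densities=densities,
            mean_E=float(np.mean(e)),
            sd_E=float(np.std(e)),
            n=e.size,
            seed=seed,
        )


def sample_gaussian_distances(
    mean: float, sd: float, n: int = DEFAULT_N, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> DistancePopulation:
    """Draw ``n`` separations from Normal(mean, sd), dropping non-positive draws.

    An explicit ``rng`` takes precedence over ``seed``; negatives are
    removed, not resampled, so the retained count is recorded.
    """
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
    kept = draws[draws > 0]
    return DistancePopulation(
        values=kept, mean=mean, sd=sd, n_requested=n, n_retained=kept.size, seed=seed
    )


def simulate_distance_heterogeneity(
    mean: float,
    sd_percent: float,
    system: ForsterSystem,
    n: int = DEFAULT_N,
    seed: int | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> EfficiencyDistribution:
    """Dynamic-regime efficiency distribution from a Gaussian separation population.

    Separations -> transfer rates (kappa^2 = 2/3 embedded in R0) ->
    efficiencies -> binned density.  ``sd_percent`` is the Gaussian SD as a
    percentage of the mean.
    """
    pop = sample_gaussian_distances(mean, mean * sd_percent / 100.0, n, seed)
    e = efficiency_from_rate(transfer_rate(pop.values, system), system.tau0D)
    return EfficiencyDistribution.from_values(e, bin_width=bin_width, seed=seed)


def apply_acceptor_dark_states(
    rates: np.ndarray,
    f_dark: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero each transfer rate independently with probability ``f_dark``.

    Models long-lived acceptor dark states: a dark acceptor cannot receive
    transfer, so the pair's rate (hence efficiency) collapses to zero.
    """
    if not 0.0 <= f_dark <= 1.0:
        raise ValueError(f"f_dark must be in [0, 1], got {f_dark}")
    if rng is None:
        rng = np.random.default_rng(seed)
    bright = rng.random(len(rates)) >= f_dark
    return np.where(bright, rates, 0.0)


def simulate_acceptor_blinking(
    mean: float,
    sd_percent: float,
    system: ForsterSystem,
    f_dark: float,
    n: int = DEFAULT_N,
    seed: int | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> EfficiencyDistribution:
    """Dynamic-regime simulation with a fraction of dark acceptors.

    Produces the characteristic bimodal density with peaks at E = 0 and at
    the no-blinking efficiency, with weights f_dark and 1 - f_dark.
    """
    rng = np.random.default_rng(seed)
    pop = sample_gaussian_distances(mean, mean * sd_percent / 100.0, n, rng=rng)
    rates = transfer_rate(pop.values, system)
    rates = apply_acceptor_dark_states(rates, f_dark, rng=rng)
    e = efficiency_from_rate(rates, system.tau0D)
    return EfficiencyDistribution.from_values(e, bin_width=bin_width, seed=seed)


def simulate_static_regime(
    mean: float,
    sd_percent: float,
    system: ForsterSystem,
    n: int = DEFAULT_N,
    seed: int | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> EfficiencyDistribution:
    """Static random isotropic regime: each pair keeps one fixed kappa^2.

    Separations and kappa^2 values are sampled independently and randomly
    associated; per-pair rates use the explicit-kappa^2 rate (3/2 prefactor
    removing the 2/3 average embedded in R0).  At R_DA = R0 +/- 1% this
    yields a broad asymmetric density with mode in the first bin, a
    secondary peak near E = 0.6, mean ~0.38 and SD ~0.25.
    """
    rng = np.random.default_rng(seed)
    pop = sample_gaussian_distances(mean, mean * sd_percent / 100.0, n, rng=rng)
    x = rng.uniform(0.0, 1.0, size=pop.n_retained)
    y = rng.uniform(0.0, 1.0, size=pop.n_retained)
    kappa2 = y**2 * (1.0 + 3.0 * x**2)
    rates = static_transfer_rate(pop.values, system, kappa2)
    e = efficiency_from_rate(rates, system.tau0D)
    return EfficiencyDistribution.from_values(e, bin_width=bin_width, seed=seed)


def sweep_mean_efficiency(
    mode: str,
    grid: Iterable[float],
    levels: Sequence[float] | None,
    system: ForsterSystem,
    n: int = DEFAULT_N,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean efficiency as a function of mean separation, per perturbation level.

    mode = "distance_sd": ``levels`` are Gaussian SDs in percent of the mean.
    mode = "dark_fraction": ``levels`` are dark-acceptor fractions on a
    fixed-separation (sd = 0) population.
    mode = "regime": ``levels`` ignored; one dynamic and one static curve
    (Gaussian +/- 1%).

    The returned frame has columns (r_da, level, mean_E) plus a
    ``fixed_pair`` reference column giving the fixed-pair efficiency at
    each grid point.
    """
    grid = np.asarray(list(grid), dtype=float)
    if np.any(grid <= 0):
        raise ValueError("grid separations must be > 0")
    rows = []
    fixed = efficiency_from_distance(grid, system)
    if mode == "distance_sd":
        if levels is None:
            raise ValueError("distance_sd mode needs SD levels (percent)")
        for level in levels:
            for r, e_fixed in zip(grid, fixed):
                dist = simulate_distance_heterogeneity(r, level, system, n=n, seed=seed)
                rows.append((r, level, dist.mean_E, e_fixed))
    elif mode == "dark_fraction":
        if levels is None:
            raise ValueError("dark_fraction mode needs dark fractions")
        for level in levels:
            for r, e_fixed in zip(grid, fixed):
                dist = simulate_acceptor_blinking(r, 0.0, system, level, n=n, seed=seed)
                rows.append((r, level, dist.mean_E, e_fixed))
    elif mode == "regime":
        for label, sim in (
            ("dynamic", simulate_distance_heterogeneity),
            ("static", simulate_static_regime),
        ):
            for r, e_fixed in zip(grid, fixed):
                dist = sim(r, 1.0, system, n=n, seed=seed)
                rows.append((r, label, dist.mean_E, e_fixed))
    else:
        raise ValueError(f"unknown sweep mode {mode!r}")
    return pd.DataFrame(rows, columns=["r_da", "level", "mean_E", "fixed_pair"])


def c5v_scenario(
    system: ForsterSystem | None = None,
    mean: float = 3.9,
    sd: float = 0.95,
    n: int = DEFAULT_N,
    seed: int | None = None,
) -> EfficiencyDistribution:
    """Gaussian separation model for the C5V tandem construct.

    R_DA = 3.9 +/- 1.9 nm (mean +/- 2 SD), R0 = 5.4 nm, dynamic regime.
    The resulting mean efficiency exceeds 0.7 — well above the measured
    0.43 — showing that distance heterogeneity alone cannot explain the
    construct's complex decay.
    """
    if system is None:
        system = ForsterSystem(tau0D=3.0, R0=5.4)
    sd_percent = 100.0 * sd / mean
    return simulate_distance_heterogeneity(mean, sd_percent, system, n=n, seed=seed)
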