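"""Poisson foci-overlap mixture model for apparent stoichiometry.

Two foci closer than the optical resolution are detected as one focus of
summed stoichiometry.  For an oligomer of true stoichiometry S, the
apparent stoichiometry x of a detected focus is modelled as a mixture over
the number k of overlapping foci:

    P(x) = sum_{k=1..5} Pois(k; lambda)/Z * N(x; k S, sigma^2 k S)

with lambda the per-cell mean overlap count (foci density times the
resolution disk area), sigma = 0.675 the single-fluorophore width in
molecule units (so a k-fold overlap of S-mers has width sigma sqrt(kS)),
the truncated Poisson weights renormalized over k = 1..5, and the whole
model finally convolved with the same 0.7-molecule Gaussian kernel as the
kernel density estimate of the measured stoichiometries.  Candidate S are
compared by Pearson's chi-squared on 1-molecule bins up to 30 with
dof = used bins - 4 free parameters (lambda, k, sigma, S).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from slimspore.config import Config, DEFAULT_CONFIG


@dataclass
class OverlapModel:
    """One oligomer hypothesis: S-mers overlapping at Poisson rate lambda."""

    S: float
    lam: float
    k_max: int = 5
    sigma: float = 0.675

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("model stoichiometry S must be >= 1")
        if self.lam < 0:
            raise ValueError("overlap rate lambda must be >= 0")

    def truncation_loss(self) -> float:
        """Poisson mass beyond k_max (given at least one focus present)."""
        k = np.arange(1, self.k_max + 1)
        inside = stats.poisson.pmf(k, max(self.lam, 1e-12)).sum()
        total = 1.0 - stats.poisson.pmf(0, max(self.lam, 1e-12))
        return float(max(total - inside, 0.0)) / total if total > 0 else 0.0


@dataclass
class StoichiometryKDE:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def at(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.grid, self.density, left=0.0, right=0.0)


@dataclass
class GoodnessOfFit:
    chi2: float
    dof: int
    p_value: float
    bins: np.ndarray
    observed: np.ndarray
    expected: np.ndarray


# ---------------------------------------------------------------------------


def overlap_rate(n_foci: int, feature_area_um2: float,
                 resolution_nm: float = 250.0) -> float:
    """Mean number of extra foci within one resolution length of a focus,
    lambda = rho pi r^2 for foci density rho; the per-focus overlap
    probability is 1 - exp(-lambda)."""
    if feature_area_um2 <= 0:
        raise ValueError("feature area must be positive")
    if n_foci <= 0:
        return 0.0
    rho = n_foci / feature_area_um2            # foci per um^2
    r_um = resolution_nm * 1e-3
    return float(rho * np.pi * r_um ** 2)


def overlap_probability(lam: float) -> float:
    return float(1.0 - np.exp(-lam))


def model_distribution(model: OverlapModel, grid: np.ndarray,
                       kde_bandwidth: float = 0.7,
                       warn_loss: float = 0.01) -> np.ndarray:
    """Apparent-stoichiometry density P(x) of an overlap model on ``grid``.

    Gaussians at k S with sd sigma sqrt(kS), zero-truncated Poisson weights
    renormalized over k = 1..k_max, convolved with the KDE kernel (added in
    quadrature -- a Gaussian convolved with a Gaussian), and renormalized to
    unit area on the grid.
    """
    import warnings

    lam = max(model.lam, 1e-12)
    if model.truncation_loss() > warn_loss:
        warnings.warn(
            f"overlap model truncation at k_max={model.k_max} loses "
            f"{model.truncation_loss():.1%} of the Poisson mass",
            stacklevel=2)
    k = np.arange(1, model.k_max + 1)
    w = stats.poisson.pmf(k, lam)
    w = w / w.sum()
    x = np.asarray(grid, dtype=float)
    dens = np.zeros_like(x)
    for ki, wi in zip(k, w):
        mu = ki * model.S
        sd = np.sqrt(model.sigma ** 2 * ki * model.S + kde_bandwidth ** 2)
        dens += wi * stats.norm.pdf(x, mu, sd)
    area = np.trapezoid(dens, x)
    if area > 0:
        dens /= area
    return dens


def kde(values: np.ndarray, bandwidth: float = 0.7,
        grid: np.ndarray | None = None) -> StoichiometryKDE:
    """Gaussian kernel density estimate of measured stoichiometries with a
    fixed bandwidth in molecule units, normalized to unit area."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("need at least one stoichiometry value")
    if grid is None:
        lo = min(0.0, values.min() - 4 * bandwidth)
        hi = values.max() + 4 * bandwidth
        grid = np.linspace(lo, hi, max(int((hi - lo) * 20), 100))
    dens = np.zeros_like(grid, dtype=float)
    for v in values:
        dens += stats.norm.pdf(grid, v, bandwidth)
    dens /= len(values)
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens /= area
    return StoichiometryKDE(grid=np.asarray(grid), density=dens,
                            bandwidth=bandwidth, values=values)


# ---------------------------------------------------------------------------
# chi-squared model selection


def population_model(S: float, per_cell_lambda: list[float],
                     grid: np.ndarray, sigma: float = 0.675, k_max: int = 5,
                     kde_bandwidth: float = 0.7) -> np.ndarray:
    """Average the per-cell overlap models over the population (cells with
    lambda = 0 still contribute a pure S-mer peak)."""
    lams = [lam for lam in per_cell_lambda]
    if not lams:
        raise ValueError("no cells with foci")
    dens = np.zeros_like(np.asarray(grid, dtype=float))
    for lam in lams:
        dens += model_distribution(OverlapModel(S, lam, k_max, sigma), grid,
                                   kde_bandwidth)
    dens /= len(lams)
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens /= area
    return dens


def chi_squared_statistic(observed: StoichiometryKDE,
                          expected_density: np.ndarray,
                          max_bin: int = 30, n_params: int = 4,
                          p_convention: str = "upper") -> GoodnessOfFit:
    """Pearson chi-squared between an observed KDE and a model density.

    Both densities are evaluated at 1-molecule bin centres 1..max_bin; bins
    in which the data contain no recorded focus are discarded.
    dof = used bins - n_params.  ``p_convention='upper'`` gives the usual
    tail probability 1 - CDF(chi2; dof); ``'cdf'`` reports CDF(chi2; dof).
    """
    centres = np.arange(1, max_bin + 1, dtype=float)
    have_data = np.array([
        np.any((observed.values >= c - 0.5) & (observed.values < c + 0.5))
        for c in centres
    ]) if observed.values.size else observed.at(centres) > 0
    use = have_data
    if not use.any():
        raise ValueError("no occupied stoichiometry bins")
    O = observed.at(centres[use])
    C = np.interp(centres[use], observed.grid, expected_density,
                  left=0.0, right=0.0)
    C = np.clip(C, 1e-12, None)
    chi2 = float(np.sum((O - C) ** 2 / C))
    dof = max(int(use.sum()) - n_params, 1)
    if p_convention == "cdf":
        p = float(stats.chi2.cdf(chi2, dof))
    else:
        p = float(stats.chi2.sf(chi2, dof))
    return GoodnessOfFit(chi2=chi2, dof=dof, p_value=p, bins=centres[use],
                         observed=O, expected=C)


def chi_squared_fit(values: np.ndarray, candidate_S: list[float],
                    per_cell_lambda: list[float],
                    config: Config = DEFAULT_CONFIG,
                    max_bin: int = 30,
                    p_convention: str = "upper"
                    ) -> tuple[float, dict[float, GoodnessOfFit]]:
    """Select the oligomer model best matching measured stoichiometries.

    Returns (best S, per-candidate goodness of fit); best = smallest chi2.
    """
    if not candidate_S:
        raise ValueError("no candidate models")
    obs = kde(values, config.kde_bandwidth_molecules)
    results: dict[float, GoodnessOfFit] = {}
    for S in candidate_S:
        dens = population_model(S, per_cell_lambda, obs.grid,
                                sigma=config.sigma_single,
                                kde_bandwidth=config.kde_bandwidth_molecules)
        results[S] = chi_squared_statistic(obs, dens, max_bin=max_bin,
                                           p_convention=p_convention)
    best = min(results, key=lambda S: results[S].chi2)
    return best, results


def sample_apparent_stoichiometry(S: float, lam: float, n: int,
                                  sigma: float = 0.675, k_max: int = 5,
                                  seed: int = 0) -> np.ndarray:
    """Draw apparent stoichiometries from an overlap model (generator-side
    counterpart used to validate model selection)."""
    rng = np.random.default_rng(seed)
    k = np.arange(1, k_max + 1)
    w = stats.poisson.pmf(k, max(lam, 1e-12))
    w /= w.sum()
    ks = rng.choice(k, size=n, p=w)
    return rng.normal(ks * S, sigma * np.sqrt(ks * S))
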