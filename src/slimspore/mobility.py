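"""Foci mobility: MSD, diffusion fitting and the membrane drag model.

The 2D mean square displacement of a tracked focus at lag tau = n dt is

    MSD(n dt) = (1/(N-1-n)) sum_i |r(i dt + n dt) - r(i dt)|^2
              = 4 D tau + 4 sigma^2

with sigma the localization precision (~40 nm).  D comes from a linear fit
to the first three MSD points constrained to pass through 4 sigma^2 at
tau = 0, with sigma free in [20, 60] nm.

Lateral drag on a membrane-spanning cylinder of radius a and height h (the
bilayer thickness, ~3 nm) follows the Saffman-Delbrueck hydrodynamics in
the Petrov-Schwille-style small-epsilon form

    gamma = 4 pi (eta_1 + eta_2) a C(eps),   eps = 2 a eta_c / (h eta_m),
    C(eps) ~= 1 / (eps ln(2/eps)),           D = k_B T / gamma,

with eta_1 = eta_2 = eta_c the cytoplasmic viscosity (~1 cP) on both sides
of the membrane and eta_m the membrane viscosity (600 cP vegetative,
1000 cP forespore).  In the eps -> 0 limit this reduces to the classic
Saffman-Delbrueck drag gamma = 4 pi eta_m h / ln(2/eps).  The map D(a) is
strictly decreasing, so the apparent (Stokes) radius of a diffusing
complex is recovered by root-finding on the forward map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

K_BOLTZMANN = 1.380649e-23   # J/K


@dataclass
class MSDCurve:
    lags_ms: np.ndarray
    msd_nm2: np.ndarray
    n_points: int

    def lags_s(self) -> np.ndarray:
        return self.lags_ms * 1e-3


@dataclass
class DiffusionFit:
    D_um2_s: float
    sigma_loc_nm: float
    flagged: bool = False


@dataclass
class PowerLawFit:
    alpha: float
    alpha_stderr: float
    ci95: tuple[float, float]


@dataclass
class MembraneDragModel:
    """Physical parameters of the frictional-drag calculation.

    Viscosities in centipoise (1 cP = 1e-3 Pa s), bilayer thickness in nm,
    temperature in kelvin.
    """

    eta_membrane_cP: float = 1000.0
    eta_cytoplasm_cP: float = 1.0
    bilayer_thickness_nm: float = 3.0
    temperature_K: float = 298.0

    def epsilon(self, a_nm: float) -> float:
        return (2.0 * a_nm * self.eta_cytoplasm_cP
                / (self.bilayer_thickness_nm * self.eta_membrane_cP))


# ---------------------------------------------------------------------------
# MSD and diffusion


def compute_msd(positions_nm: np.ndarray, frame_interval_ms: float,
                max_lag: int | None = None) -> MSDCurve:
    """Time-averaged 2D MSD of one track over lags n = 1..N-2 (the printed
    sum has N-1-n terms, so lags with no pairs are omitted)."""
    r = np.asarray(positions_nm, dtype=float)
    N = len(r)
    if N < 4:
        raise ValueError("need a track of >= 4 points")
    n_max = N - 2 if max_lag is None else min(max_lag, N - 2)
    lags, msds = [], []
    for n in range(1, n_max + 1):
        d = r[n:] - r[:-n]
        # the definition averages over i = 1..N-1-n
        d = d[:N - 1 - n] if N - 1 - n > 0 else d
        if len(d) == 0:
            break
        lags.append(n * frame_interval_ms)
        msds.append(float(np.mean((d ** 2).sum(axis=1))))
    return MSDCurve(lags_ms=np.array(lags), msd_nm2=np.array(msds), n_points=N)


def fit_diffusion(msd: MSDCurve, sigma_bounds_nm: tuple[float, float] = (20, 60),
                  n_fit_points: int = 3) -> DiffusionFit:
    """D and localization error from the first three MSD points.

    Least squares over (D, sigma) for MSD = 4 D tau + 4 sigma^2 with sigma
    constrained to the experimental 20-60 nm range; a negative best-fit
    slope reports D = 0, flagged.
    """
    if len(msd.lags_ms) < n_fit_points:
        raise ValueError(f"need >= {n_fit_points} MSD lags")
    tau_s = msd.lags_s()[:n_fit_points]
    y = msd.msd_nm2[:n_fit_points]           # nm^2
    lo, hi = sigma_bounds_nm

    # For fixed sigma the optimal D is closed-form; scan the 1D profile.
    def best_D(sig):
        num = ((y - 4 * sig ** 2) * 4 * tau_s).sum()
        den = (16 * tau_s ** 2).sum()
        return num / den * 1e-6               # nm^2/s -> um^2/s

    def cost(sig):
        D = max(best_D(sig), 0.0)
        pred = 4 * D * 1e6 * tau_s + 4 * sig ** 2
        return ((y - pred) ** 2).sum()

    res = optimize.minimize_scalar(cost, bounds=(lo, hi), method="bounded")
    sig = float(res.x)
    D = best_D(sig)
    flagged = D < 0
    return DiffusionFit(D_um2_s=max(D, 0.0), sigma_loc_nm=sig, flagged=flagged)


def fit_tracks_diffusion(tracks_nm: list[np.ndarray], frame_interval_ms: float
                         ) -> list[DiffusionFit]:
    fits = []
    for r in tracks_nm:
        if len(r) < 4:
            continue
        fits.append(fit_diffusion(compute_msd(r, frame_interval_ms)))
    return fits


def fit_power_law(S_values: np.ndarray, D_values: np.ndarray) -> PowerLawFit:
    """Exponent of D ~ S^-alpha by log-log regression; alpha is reported
    positive when D decreases with S (the convention for crowding of larger
    complexes).  Nonpositive values are excluded with a warning."""
    import warnings

    S = np.asarray(S_values, dtype=float)
    D = np.asarray(D_values, dtype=float)
    keep = (S > 0) & (D > 0)
    if keep.sum() < len(S):
        warnings.warn(f"excluding {len(S) - int(keep.sum())} nonpositive "
                      "values from the power-law fit", stacklevel=2)
    S, D = S[keep], D[keep]
    if len(S) < 5:
        raise ValueError("need >= 5 positive (S, D) pairs")
    res = stats.linregress(np.log(S), np.log(D))
    alpha = -res.slope
    half = 1.96 * res.stderr
    return PowerLawFit(alpha=float(alpha), alpha_stderr=float(res.stderr),
                       ci95=(float(alpha - half), float(alpha + half)))


# ---------------------------------------------------------------------------
# frictional drag


def drag_coefficient(a_nm: float, model: MembraneDragModel) -> float:
    """Lateral drag gamma (N s / m) of a membrane cylinder of radius a."""
    if a_nm <= 0:
        raise ValueError("radius must be positive")
    eps = model.epsilon(a_nm)
    if eps >= 1:
        raise ValueError(
            f"epsilon = {eps:.3f} >= 1: outside the small-epsilon validity "
            "range of the drag approximation")
    C = 1.0 / (eps * np.log(2.0 / eps))
    eta1 = eta2 = model.eta_cytoplasm_cP * 1e-3   # cP -> Pa s
    a_m = a_nm * 1e-9
    return float(4.0 * np.pi * (eta1 + eta2) * a_m * C)


def drag_D(a_nm: float, model: MembraneDragModel) -> float:
    """Diffusion coefficient (um^2/s) from the Stokes-Einstein relation
    D = k_B T / gamma."""
    gamma = drag_coefficient(a_nm, model)
    return float(K_BOLTZMANN * model.temperature_K / gamma * 1e12)


def invert_D(D_um2_s: float, model: MembraneDragModel,
             a_range_nm: tuple[float, float] = (0.1, 1000.0)) -> float:
    """Cylinder radius a whose drag reproduces an observed D (bisection on
    the strictly decreasing forward map, log-spaced bracket)."""
    lo, hi = a_range_nm
    # clip the bracket to where the approximation holds (eps < 1)
    eps_hi = model.epsilon(hi)
    if eps_hi >= 1:
        hi = 0.999 * model.bilayer_thickness_nm * model.eta_membrane_cP \
            / (2 * model.eta_cytoplasm_cP)
    D_lo, D_hi = drag_D(hi, model), drag_D(lo, model)
    if not (D_lo <= D_um2_s <= D_hi):
        raise ValueError(
            f"D = {D_um2_s:g} um^2/s outside the attainable range "
            f"[{D_lo:.3g}, {D_hi:.3g}] um^2/s for radii {lo}-{hi:.3g} nm")
    f = lambda loga: drag_D(float(np.exp(loga)), model) - D_um2_s
    root = optimize.brentq(f, np.log(lo), np.log(hi), xtol=1e-12, rtol=1e-14)
    return float(np.exp(root))


def lookup_table(model: MembraneDragModel, a_nm: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """(a, D) look-up table over a log-spaced radius grid."""
    if a_nm is None:
        a_nm = np.geomspace(1.0, 200.0, 200)
    D = np.array([drag_D(a, model) for a in a_nm])
    return np.asarray(a_nm), D


def helix_packing_radius(n_helices: int, helix_diameter_nm: float = 1.2
                         ) -> float:
    """Radius of a close-packed circular bundle of transmembrane helices,
    by area equivalence: R = (d/2) sqrt(n).  Forty 1.2 nm helices (a
    tetramer of a 10-TM protein) give ~3.8 nm, i.e. the ~4 nm scale of the
    bare complex."""
    if n_helices < 1:
        raise ValueError("need at least one helix")
    if helix_diameter_nm <= 0:
        raise ValueError("helix diameter must be positive")
    return float(helix_diameter_nm / 2.0 * np.sqrt(n_helices))
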