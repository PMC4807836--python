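"""Marcus-theory rate and reorganization-energy estimation from two-state
potential-energy sampling.

The potential energy of the receptor in a given redox state i is assumed
Gaussian,

    p(E_i) = 1 / (w_i sqrt(pi/2)) exp(-2 (E_i - <E_i>)^2 / w_i^2),

a convention in which the distribution width w equals twice the standard
deviation (variance = w^2/4).  The free-energy profile follows as
G_i(E) = -RT ln p(E_i): an exact parabola with minimum at <E_i> and
curvature 4RT/w^2.  Two such profiles for the states before and after
electron transfer give an order-of-magnitude reorganization-energy
estimate — descriptively from the minima separation, and quantitatively
through the linear-response identity variance = 2 lambda RT, i.e.
lambda_w = w^2 / (8RT).

The nonadiabatic Marcus rate is

    k = (2 pi / hbar) |H_DA|^2 (4 pi lambda k_B T)^(-1/2)
        exp(-(lambda + dG)^2 / (4 lambda k_B T)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .molecular_io import EnergyTrace
from .units import (CM1_J, HBAR_JS, J_PER_KCALMOL, KB_J, R_KCALMOL_K)

GAS_CONSTANT = R_KCALMOL_K  # kcal/(mol K), the paper-units R = 0.001987


@dataclass
class GaussianFit:
    """Fitted energy density: mean <E> and width w (kcal/mol; SD = w/2)."""

    mean: float
    width: float
    bin_width: float
    rss: float  # residual sum of squares of the density fit
    state: str = "donor"
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")

    def density(self, e) -> np.ndarray:
        return gaussian_density(np.asarray(e, dtype=float), self.mean, self.width)

    @property
    def variance(self) -> float:
        return self.width**2 / 4.0


def gaussian_density(e, mean, width):
    """The two-parameter density p(E); integrates to one analytically."""
    return np.exp(-2.0 * (e - mean) ** 2 / width**2) / (
        width * math.sqrt(math.pi / 2.0))


@dataclass
class FreeEnergyProfile:
    """G(E) = -RT ln p(E) on a grid: an exact parabola."""

    grid: np.ndarray  # kcal/mol
    g: np.ndarray  # kcal/mol
    minimum_location: float
    minimum_value: float
    curvature: float  # d2G/dE2 = 4RT/w^2
    temperature: float
    state: str = "donor"
    fit: Optional[GaussianFit] = None


@dataclass
class MarcusParams:
    """Inputs of the Marcus rate: coupling H_DA, reorganization energy
    lambda, driving force dG (all kcal/mol per molecule), temperature (K)."""

    h_da: float
    lam: float
    delta_g: float
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("reorganization energy must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @classmethod
    def from_spectroscopic(cls, h_da_cm1: float, lam_ev: float, dg_ev: float,
                           temperature: float = 310.0) -> "MarcusParams":
        """Build from H_DA in cm^-1 and lambda/dG in eV."""
        from .units import E_CHARGE
        kcal = 1.0 / J_PER_KCALMOL  # kcal/mol per J(molecule)
        return cls(h_da_cm1 * CM1_J * kcal, lam_ev * E_CHARGE * kcal,
                   dg_ev * E_CHARGE * kcal, temperature)


# ---------------------------------------------------------------------------
# fitting and profiles
# ---------------------------------------------------------------------------

def fit_energy_gaussian(trace: EnergyTrace, bin_width: float = 5.0,
                        method: str = "lsq") -> GaussianFit:
    """Fit the Gaussian density to a binned potential-energy trace.

    The histogram is normalized to a density with bins of ``bin_width``
    kcal/mol and the two-parameter density is least-squares fitted to the
    bin heights (initial guesses: sample mean, 2 x sample SD).
    ``method='mle'`` bypasses the histogram and uses the closed-form
    maximum-likelihood estimates instead.
    """
    import logging

    e = trace.energies
    if len(e) < 100:
        logging.getLogger(__name__).warning(
            "only %d samples; >= 100 recommended for a stable density fit",
            len(e))
    sd = e.std(ddof=1) if len(e) > 1 else 0.0
    if sd == 0:
        raise ValueError("degenerate (constant) energy trace; no density to fit")
    if method == "mle":
        return GaussianFit(float(e.mean()), float(2.0 * sd), bin_width, 0.0,
                           state=trace.state, n_samples=len(e))
    lo = math.floor(e.min() / bin_width) * bin_width
    hi = math.ceil(e.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    dens, edges = np.histogram(e, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = dens > 0
    if occupied.sum() < 3:
        raise ValueError(
            f"only {int(occupied.sum())} nonempty bins with bin_width="
            f"{bin_width}; histogram too coarse to fit")
    p0 = (e.mean(), 2.0 * sd)
    try:
        popt, _ = curve_fit(gaussian_density, centers, dens, p0=p0)
    except RuntimeError as err:
        raise RuntimeError(f"Gaussian density fit did not converge: {err}") from err
    resid = dens - gaussian_density(centers, *popt)
    return GaussianFit(float(popt[0]), float(abs(popt[1])), bin_width,
                       float(resid @ resid), state=trace.state,
                       n_samples=len(e))


def free_energy_profile(fit: GaussianFit, temperature: float = 310.0,
                        grid: Optional[np.ndarray] = None) -> FreeEnergyProfile:
    """Free-energy parabola G(E) = -RT ln p(E) from a fitted density."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rt = GAS_CONSTANT * temperature
    if grid is None:
        grid = np.linspace(fit.mean - 3 * fit.width, fit.mean + 3 * fit.width, 601)
    grid = np.asarray(grid, dtype=float)
    g = -rt * np.log(fit.density(grid))
    g_min = -rt * math.log(1.0 / (fit.width * math.sqrt(math.pi / 2.0)))
    return FreeEnergyProfile(grid, g, fit.mean, g_min,
                             4.0 * rt / fit.width**2, temperature,
                             state=fit.state, fit=fit)


@dataclass
class ReorganizationReport:
    """Descriptive and width-based reorganization-energy estimates."""

    minima_separation: float  # |<E_D> - <E_A>|, kcal/mol
    curvature_ratio: float  # donor / acceptor
    lambda_width_donor: float  # w_D^2 / 8RT, kcal/mol
    lambda_width_acceptor: float
    indistinguishable: bool  # separation below one sampling bin
    temperature: float
    details: dict = field(default_factory=dict)


def estimate_reorganization(profile_d: FreeEnergyProfile,
                            profile_a: FreeEnergyProfile) -> ReorganizationReport:
    """Compare donor and acceptor free-energy parabolas.

    Reports the separation of the minima, the curvature ratio, and the
    width-based estimates lambda_w,i = w_i^2/(8RT) (a linear-response
    extension of the paper-style descriptive comparison).  Profiles whose
    minima sit within one sampling bin of each other are flagged
    indistinguishable — the regime where only "lambda << bin width" can be
    concluded.
    """
    if profile_d.grid.max() < profile_a.grid.min() or \
            profile_a.grid.max() < profile_d.grid.min():
        raise ValueError("free-energy profiles are on disjoint grids")
    sep = abs(profile_d.minimum_location - profile_a.minimum_location)
    rt = GAS_CONSTANT * profile_d.temperature
    lam_d = profile_d.fit.variance / (2.0 * rt) if profile_d.fit else math.nan
    lam_a = profile_a.fit.variance / (2.0 * rt) if profile_a.fit else math.nan
    bin_w = profile_d.fit.bin_width if profile_d.fit else 0.0
    return ReorganizationReport(
        minima_separation=float(sep),
        curvature_ratio=float(profile_d.curvature / profile_a.curvature),
        lambda_width_donor=float(lam_d),
        lambda_width_acceptor=float(lam_a),
        indistinguishable=bool(sep < bin_w),
        temperature=profile_d.temperature,
        details={"bin_width": bin_w,
                 "minimum_donor": profile_d.minimum_location,
                 "minimum_acceptor": profile_a.minimum_location},
    )


# ---------------------------------------------------------------------------
# Marcus rate
# ---------------------------------------------------------------------------

def marcus_rate(params: MarcusParams, literal_exponent: bool = False) -> float:
    """Nonadiabatic electron-transfer rate in s^-1.

    Default: standard Marcus exponent denominator 4 lambda k_B T.
    ``literal_exponent`` keeps an extra factor pi in the denominator
    (4 pi lambda k_B T) for comparison with a typeset variant.
    """
    h = params.h_da * J_PER_KCALMOL  # J per molecule
    lam = params.lam * J_PER_KCALMOL
    dg = params.delta_g * J_PER_KCALMOL
    kbt = KB_J * params.temperature
    denom = 4.0 * lam * kbt * (math.pi if literal_exponent else 1.0)
    prefactor = (2.0 * math.pi / HBAR_JS) * h**2 / math.sqrt(
        4.0 * math.pi * lam * kbt)
    return prefactor * math.exp(-((lam + dg) ** 2) / denom)
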