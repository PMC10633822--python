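"""Association thermodynamics from PMF profiles.

The bound-state configurational integral over a free-energy well,

    Q = integral_{r0}^{r1} 4 pi r^2 exp(-W(r)/kT) dr,

normalised by a reference volume V_ref, gives the association free energy
dG_assoc = -kT ln(Q / V_ref) and the dissociation free energy
dG_d = -dG_assoc.  Two standard-state conventions are supported:
``molar_1M`` (V_ref = 1/(c0 N_A), the volume per molecule at 1 mol/L) and
``solvent_mole_fraction`` (V_ref = v_s, the solvent molecular volume).
The dissociation constant follows as K_d = c0 exp(-dG_d/RT), and its
temperature dependence is fitted with the integrated Van't Hoff equation
ln K(T) = ln K0 - (dH/R)(1/T - 1/T0), assuming a temperature-independent
dissociation enthalpy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .units import N_AVOGADRO, R_J, kT, reference_volume_molar
from .wham import PMFProfile

__all__ = [
    "AssociationResult",
    "VantHoffFit",
    "find_minima",
    "well_integral",
    "integrate_association",
    "kd_from_dG",
    "dG_from_kd",
    "vant_hoff_fit",
    "open_closed_decomposition",
    "secondary_minimum_contribution",
    "solvent_molar_volume",
    "DEFAULT_R0",
    "DEFAULT_R1",
]

#: Default acid-acid well limits (A): lower and upper bounds of the dimer well.
DEFAULT_R0 = 3.9
DEFAULT_R1 = 5.3


@dataclass(frozen=True)
class AssociationResult:
    """Association thermodynamics of one reaction at one temperature."""

    temperature: float  # K
    dG_dissociation: float  # kJ/mol
    K_d: float  # mM
    r0: float  # A
    r1: float  # A
    standard_state: str  # 'molar_1M' | 'solvent_mole_fraction'
    v_s: float | None = None  # A^3/molecule, used for solvent_mole_fraction


@dataclass(frozen=True)
class VantHoffFit:
    """Integrated Van't Hoff description of K_d(T)."""

    K_d0: float  # mM at T0
    T0: float  # K
    dH: float  # kJ/mol, dissociation enthalpy
    fit_method: str
    K_d0_method: str
    residuals: np.ndarray  # ln-space residuals per input point

    def predict(self, T) -> np.ndarray | float:
        """K_d(T) in mM from the fitted parameters."""
        T = np.asarray(T, float)
        k = self.K_d0 * np.exp(-(self.dH * 1000.0 / R_J) * (1.0 / T - 1.0 / self.T0))
        return float(k) if k.ndim == 0 else k


def find_minima(pmf: PMFProfile, depth_threshold: float = 0.5):
    """Local minima of a binned PMF with 3-point quadratic refinement.

    Minima shallower than ``depth_threshold`` (kJ/mol) relative to the
    neighbouring maxima (peak prominence) are suppressed; when the profile
    carries per-bin errors, the threshold is raised to 3x the local error so
    statistical dips in thinly sampled bins are not reported.  Returns a
    list of (r, W) sorted by r; raises if none are found.
    """
    mask = pmf.finite_mask
    if mask.sum() < 3:
        raise ValueError("need at least 3 finite bins")
    r = pmf.bin_centers[mask]
    w = pmf.W[mask]
    idx, props = find_peaks(-w, prominence=depth_threshold)
    if pmf.W_error is not None:
        err = np.nan_to_num(pmf.W_error[mask], nan=0.0)
        keep = props["prominences"] > np.maximum(depth_threshold, 3.0 * err[idx])
        idx = idx[keep]
    if idx.size == 0:
        raise ValueError("no minima found in the PMF")
    out = []
    for i in idx:
        # vertex of the parabola through the three bins around the minimum
        y0, y1, y2 = w[i - 1], w[i], w[i + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom > 0 else 0.0
        dr = r[i + 1] - r[i]
        out.append((float(r[i] + delta * dr), float(y1 - 0.25 * (y0 - y2) * delta)))
    return sorted(out)


def _well_grid(pmf: PMFProfile, r0: float, r1: float):
    """Quadrature nodes: the exact limits plus every bin center inside them."""
    if not r0 < r1:
        raise ValueError("need r0 < r1")
    m = pmf.finite_mask
    r_fin = pmf.bin_centers[m]
    if r0 < r_fin.min() - pmf.bin_width or r1 > r_fin.max() + pmf.bin_width:
        raise ValueError("integration limits outside the finite support of the PMF")
    inner = (pmf.bin_centers > r0) & (pmf.bin_centers < r1)
    if np.any(inner & ~m):
        raise ValueError("integration window overlaps unsampled (+inf) bins")
    r = np.concatenate(([r0], pmf.bin_centers[inner & m], [r1]))
    w = np.interp(r, r_fin, pmf.W[m])
    return r, w


def well_integral(pmf: PMFProfile, r0: float, r1: float, temperature: float) -> float:
    """Q = int_{r0}^{r1} 4 pi r^2 exp(-W/kT) dr (A^3), trapezoid on the bin grid."""
    r, w = _well_grid(pmf, r0, r1)
    integrand = 4.0 * np.pi * r**2 * np.exp(-w / kT(temperature))
    return float(np.trapezoid(integrand, r))


def integrate_association(
    pmf: PMFProfile,
    r0: float = DEFAULT_R0,
    r1: float = DEFAULT_R1,
    temperature: float | None = None,
    standard_state: str = "molar_1M",
    v_s: float | None = None,
    c0_molar: float = 1.0,
) -> AssociationResult:
    """Integrate a PMF well into an association/dissociation free energy.

    ``temperature`` defaults to the profile's own temperature and must match
    it when given.  See the module docstring for the conventions.
    """
    if temperature is None:
        temperature = pmf.temperature
    elif not math.isclose(temperature, pmf.temperature, rel_tol=1e-9):
        raise ValueError(
            f"temperature {temperature} K does not match PMF temperature {pmf.temperature} K"
        )
    q = well_integral(pmf, r0, r1, temperature)
    if standard_state == "molar_1M":
        v_ref = reference_volume_molar(c0_molar)
    elif standard_state == "solvent_mole_fraction":
        if v_s is None or v_s <= 0:
            raise ValueError("solvent_mole_fraction convention needs v_s > 0")
        v_ref = v_s
    else:
        raise ValueError(f"unknown standard state {standard_state!r}")
    dG_a = -kT(temperature) * math.log(q / v_ref)
    dG_d = -dG_a
    return AssociationResult(
        temperature=temperature,
        dG_dissociation=dG_d,
        K_d=kd_from_dG(dG_d, temperature, c0_molar),
        r0=r0,
        r1=r1,
        standard_state=standard_state,
        v_s=v_s,
    )


def kd_from_dG(dG_d: float, temperature: float, c0_molar: float = 1.0) -> float:
    """K_d (mM) from a dissociation free energy (kJ/mol): K_d = c0 exp(-dG/RT)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return 1000.0 * c0_molar * math.exp(-dG_d * 1000.0 / (R_J * temperature))


def dG_from_kd(K_d_mM: float, temperature: float, c0_molar: float = 1.0) -> float:
    """Inverse of :func:`kd_from_dG`; K_d in mM, result in kJ/mol."""
    if K_d_mM <= 0:
        raise ValueError("K_d must be positive")
    return -R_J * temperature * math.log(K_d_mM / (1000.0 * c0_molar)) / 1000.0


def vant_hoff_fit(
    points,
    T0: float = 298.0,
    fit_method: str = "lnK_regression",
    K_d0_method: str = "extrapolate_from_nearest_T",
) -> VantHoffFit:
    """Fit the integrated Van't Hoff equation to (T [K], K_d [mM]) pairs.

    ``lnK_regression`` least-squares ln K_d against 1/T; dH = -R * slope.
    ``K_d0_method='extrapolate_from_nearest_T'`` carries the data point
    nearest T0 to T0 along the fitted enthalpy; ``'regression_intercept'``
    evaluates the regression line at 1/T0 instead.
    """
    pts = [(float(t), float(k)) for t, k in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 (T, K_d) points")
    T = np.array([p[0] for p in pts])
    K = np.array([p[1] for p in pts])
    if len(np.unique(T)) != len(T):
        raise ValueError("duplicate temperatures")
    if np.any(K <= 0):
        raise ValueError("K_d values must be positive")
    if fit_method != "lnK_regression":
        raise ValueError(f"unknown fit method {fit_method!r}")
    x = 1.0 / T
    y = np.log(K)
    slope, intercept = np.polyfit(x, y, 1)
    dH = -R_J * slope / 1000.0  # kJ/mol
    residuals = y - (slope * x + intercept)
    if K_d0_method == "extrapolate_from_nearest_T":
        i = int(np.argmin(np.abs(T - T0)))
        K0 = K[i] * math.exp(-(dH * 1000.0 / R_J) * (1.0 / T0 - 1.0 / T[i]))
    elif K_d0_method == "regression_intercept":
        K0 = math.exp(slope / T0 + intercept)
    else:
        raise ValueError(f"unknown K_d0 method {K_d0_method!r}")
    return VantHoffFit(
        K_d0=float(K0),
        T0=T0,
        dH=float(dH),
        fit_method=fit_method,
        K_d0_method=K_d0_method,
        residuals=residuals,
    )


def open_closed_decomposition(
    pmf: PMFProfile,
    boundary: float,
    r0: float = DEFAULT_R0,
    r1: float = DEFAULT_R1,
    temperature: float | None = None,
) -> tuple[float, float]:
    """Population split of the bound well at ``boundary`` (A).

    Returns (fraction_open, fraction_closed): the shares of the bound-state
    integral Q carried by [boundary, r1] (open dimer, single hydrogen bond)
    and [r0, boundary] (closed dimer, two hydrogen bonds).  They sum to 1.
    """
    if not r0 < boundary < r1:
        raise ValueError("boundary must lie strictly inside (r0, r1)")
    if temperature is None:
        temperature = pmf.temperature
    q_closed = well_integral(pmf, r0, boundary, temperature)
    q_open = well_integral(pmf, boundary, r1, temperature)
    total = q_open + q_closed
    return q_open / total, q_closed / total


def secondary_minimum_contribution(
    pmf: PMFProfile,
    primary_range: tuple[float, float],
    secondary_range: tuple[float, float],
    temperature: float | None = None,
    c0_molar: float = 1.0,
) -> float:
    """Relative increase (%) of dG_d when a secondary minimum joins the well.

    100 * (dG_d[primary + secondary] - dG_d[primary]) / dG_d[primary], with
    both free energies from the bound-state integral under the 1 M standard
    state.  Ranges must be disjoint and ordered.
    """
    p0, p1 = primary_range
    s0, s1 = secondary_range
    if not (p0 < p1 and s0 < s1):
        raise ValueError("ranges must be ordered (lo < hi)")
    if not (p1 <= s0 or s1 <= p0):
        raise ValueError("primary and secondary ranges overlap")
    if temperature is None:
        temperature = pmf.temperature
    kt = kT(temperature)
    v_ref = reference_volume_molar(c0_molar)
    q_p = well_integral(pmf, p0, p1, temperature)
    q_s = well_integral(pmf, s0, s1, temperature)
    dG_p = kt * math.log(q_p / v_ref)
    dG_ps = kt * math.log((q_p + q_s) / v_ref)
    return 100.0 * (dG_ps - dG_p) / dG_p


def solvent_molar_volume(density_g_per_L: float, molar_mass_g_per_mol: float) -> float:
    """Solvent molecular volume v_s in A^3 from bulk density and molar mass."""
    if density_g_per_L <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("density and molar mass must be positive")
    # m^3 per molecule -> A^3: 1 m^3 = 1e30 A^3; density g/L = kg/m^3
    return molar_mass_g_per_mol / (density_g_per_L * N_AVOGADRO) * 1e27
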