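"""Monomer/dimer/hydrate speciation equilibria.

A carboxylic acid in a nonpolar solvent partitions between monomer M and
dimer D with dissociation constant K_d = M^2/D; dissolved water can bind a
monomer into a 1:1 hydrate MW with heterodissociation constant
K_h = M * W_free / MW.  Two acid mass-balance conventions are supported:
``paper_C_eq_M_plus_D`` counts the dimer once (C = M + D + MW), while
``monomer_units_C_eq_M_plus_2D`` counts it in monomer units
(C = M + 2D + MW).  The water balance is always W_total = W_free + MW.
All concentrations are mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import R_J

__all__ = [
    "EquilibriumConstants",
    "SpeciationState",
    "SpeciationError",
    "monomer_concentration",
    "solve_speciation",
    "temperature_adjust",
    "CONVENTIONS",
]

CONVENTIONS = ("paper_C_eq_M_plus_D", "monomer_units_C_eq_M_plus_2D")


class SpeciationError(RuntimeError):
    """Coupled equilibrium solve failed; carries the final residuals."""


@dataclass(frozen=True)
class EquilibriumConstants:
    """Dissociation constants at one temperature (mM)."""

    K_d: float  # dimer dissociation
    K_h: float = math.inf  # hydrate heterodissociation; inf = no hydration
    temperature: float = 298.0  # K

    def __post_init__(self) -> None:
        if self.K_d <= 0 or self.K_h <= 0:
            raise ValueError("equilibrium constants must be positive")


@dataclass(frozen=True)
class SpeciationState:
    """Self-consistent species concentrations (mM)."""

    M: float  # monomer
    D: float  # dimer
    MW: float  # acid-water hydrate
    W_free: float  # free water
    C_total: float
    W_total: float
    balance_convention: str

    def acid_balance_residual(self) -> float:
        dimer_units = 1.0 if self.balance_convention == "paper_C_eq_M_plus_D" else 2.0
        return self.M + dimer_units * self.D + self.MW - self.C_total

    def water_balance_residual(self) -> float:
        return self.W_free + self.MW - self.W_total


def _check_convention(convention: str) -> float:
    """Return the dimer stoichiometric weight for the acid balance."""
    if convention == "paper_C_eq_M_plus_D":
        return 1.0
    if convention == "monomer_units_C_eq_M_plus_2D":
        return 2.0
    raise ValueError(f"unknown balance convention {convention!r}")


def monomer_concentration(
    C: float, K_d: float, convention: str = "paper_C_eq_M_plus_D"
) -> float:
    """Water-free monomer concentration (mM) from the total acid C (mM).

    Positive root of s*M^2/K_d + M - C = 0 with s the dimer weight in the
    acid balance; for the single-count convention this is
    M = K_d (sqrt(1 + 4C/K_d) - 1) / 2.
    """
    if C < 0 or K_d <= 0:
        raise ValueError("need C >= 0 and K_d > 0")
    s = _check_convention(convention)
    if C == 0:
        return 0.0
    # expm1-style stable form of (-K + sqrt(K^2 + 4sKC)) / (2s)
    return 2.0 * C / (1.0 + math.sqrt(1.0 + 4.0 * s * C / K_d))


def solve_speciation(
    C_total: float,
    W_total: float,
    constants: EquilibriumConstants,
    convention: str = "paper_C_eq_M_plus_D",
    tol: float = 1e-12,
    max_iterations: int = 200,
) -> SpeciationState:
    """Solve the coupled monomer/dimer/hydrate equilibria.

    Damped Newton iteration on (M, W_free) with residuals given by the acid
    and water balances; D = M^2/K_d and MW = M W_free/K_h hold identically.
    The initial guess is the water-free closed form.  Steps that would drive
    a concentration negative are halved.
    """
    if C_total < 0 or W_total < 0:
        raise ValueError("total concentrations must be non-negative")
    s = _check_convention(convention)
    K_d, K_h = constants.K_d, constants.K_h

    def state(M: float, Wf: float) -> SpeciationState:
        return SpeciationState(
            M=M,
            D=M * M / K_d,
            MW=(M * Wf / K_h) if math.isfinite(K_h) else 0.0,
            W_free=Wf,
            C_total=C_total,
            W_total=W_total,
            balance_convention=convention,
        )

    if C_total == 0:
        return state(0.0, W_total)
    if W_total == 0 or not math.isfinite(K_h):
        return state(monomer_concentration(C_total, K_d, convention), W_total)

    M = monomer_concentration(C_total, K_d, convention)
    Wf = W_total / (1.0 + M / K_h)
    scale = max(C_total, W_total, K_d)
    for _ in range(max_iterations):
        F1 = M + s * M * M / K_d + M * Wf / K_h - C_total
        F2 = Wf + M * Wf / K_h - W_total
        if max(abs(F1), abs(F2)) < tol * scale:
            return state(M, Wf)
        # Jacobian of (F1, F2) wrt (M, Wf)
        j11 = 1.0 + 2.0 * s * M / K_d + Wf / K_h
        j12 = M / K_h
        j21 = Wf / K_h
        j22 = 1.0 + M / K_h
        det = j11 * j22 - j12 * j21
        dM = -(F1 * j22 - F2 * j12) / det
        dWf = -(F2 * j11 - F1 * j21) / det
        while M + dM < 0 or Wf + dWf < 0:  # damp on negativity violations
            dM *= 0.5
            dWf *= 0.5
        M += dM
        Wf += dWf
    raise SpeciationError(
        f"no convergence in {max_iterations} iterations; residuals ({F1:.3e}, {F2:.3e}) mM"
    )


def temperature_adjust(K0: float, T0: float, dH: float, T: float) -> float:
    """Integrated Van't Hoff shift: K(T) = K0 exp(-(dH/R)(1/T - 1/T0)).

    ``K0`` in mM at reference temperature ``T0`` (K); ``dH`` in kJ/mol.
    """
    if K0 <= 0 or T0 <= 0 or T <= 0:
        raise ValueError("K0, T0 and T must be positive")
    return K0 * math.exp(-(dH * 1000.0 / R_J) * (1.0 / T - 1.0 / T0))


def speciation_curve(
    C_values,
    W_total: float,
    constants: EquilibriumConstants,
    convention: str = "paper_C_eq_M_plus_D",
):
    """Species concentrations across a schedule of total acid concentrations.

    Returns a dict of numpy arrays keyed C, M, D, MW, W_free, monomer_fraction.
    """
    C_values = np.asarray(C_values, float)
    states = [solve_speciation(c, W_total, constants, convention) for c in C_values]
    out = {
        "C": C_values,
        "M": np.array([s.M for s in states]),
        "D": np.array([s.D for s in states]),
        "MW": np.array([s.MW for s in states]),
        "W_free": np.array([s.W_free for s in states]),
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        out["monomer_fraction"] = np.where(C_values > 0, out["M"] / C_values, 1.0)
    return out
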