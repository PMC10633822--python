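"""Ground-truth model PMFs and synthetic umbrella-sampling data.

The model free-energy landscape W(r) along the head-group separation r is a
sum of negative Gaussian wells plus an exponential repulsive wall, flat (zero)
in the bulk.  The default acid-acid landscape has the closed-dimer minimum
(two hydrogen bonds) near 3.8 A and the shallower open-dimer minimum (one
hydrogen bond) near 4.6 A; acid-water landscapes have their bound minimum at
2.7 A.  Umbrella windows are drawn from the biased Boltzmann density
exp(-[W(r) + k/2 (r-c)^2] / kT) by Metropolis Monte Carlo on the scalar
coordinate.  The coordinate carries no r^2 Jacobian weight here: W(r) is by
definition the PMF that WHAM reconstructs, and the 4 pi r^2 volume element
enters only when a well is integrated into an association free energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .units import kT, spring_kcal_to_kj

__all__ = [
    "GaussianWell",
    "ModelPMF",
    "UmbrellaWindow",
    "UmbrellaDataset",
    "SamplerConfig",
    "make_default_pmf",
    "make_water_pmf",
    "evaluate_pmf",
    "sample_window",
    "run_schedule",
    "DEFAULT_SPRING_KCAL",
    "DEFAULT_SPACING",
    "DEFAULT_N_SAMPLES",
]

#: Harmonic bias used for the umbrella ladder, kcal/(mol A^2).
DEFAULT_SPRING_KCAL = 6.0
#: Window spacing, A.
DEFAULT_SPACING = 0.5
#: Stored samples per window (2 ns at a 0.1 ps storage stride).
DEFAULT_N_SAMPLES = 20_000


@dataclass(frozen=True)
class GaussianWell:
    """One attractive well: ``-depth * exp(-(r-center)^2 / (2 width^2))``."""

    center: float  # A
    depth: float  # kJ/mol, > 0
    width: float  # A (Gaussian sigma)

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.width <= 0 or self.center <= 0:
            raise ValueError("well center, depth and width must be positive")


@dataclass(frozen=True)
class ModelPMF:
    """Parametric free-energy curve W(r), kJ/mol vs A.

    W(r) = wall_height * exp(-wall_steepness * (r - wall_position))
           - sum_i depth_i * exp(-(r - center_i)^2 / (2 width_i^2))

    The plateau value is identically zero: every term decays to zero at
    large r, so the bulk reference is built in.
    """

    wells: tuple[GaussianWell, ...] = ()
    wall_position: float = 3.5  # A
    wall_height: float = 20.0  # kJ/mol at the wall position
    wall_steepness: float = 20.0  # per A
    plateau_value: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if self.wall_position < 0 or self.wall_height < 0 or self.wall_steepness <= 0:
            raise ValueError("invalid wall parameters")

    def __call__(self, r):
        return evaluate_pmf(self, r)


def make_default_pmf(
    closed_depth: float = 25.0, open_depth: float = 20.0, width: float = 0.28
) -> ModelPMF:
    """Canonical two-well acid-acid landscape.

    Closed-dimer minimum at 3.8 A (depth ``closed_depth``), open-dimer
    minimum at 4.6 A (``open_depth`` < ``closed_depth``), repulsive wall
    below ~3.5 A, zero plateau beyond 10 A.  Default depths give a
    dissociation free energy of the order of 15-20 kJ/mol at 300 K.
    """
    if not closed_depth > open_depth > 0:
        raise ValueError("need closed_depth > open_depth > 0")
    return ModelPMF(
        wells=(
            GaussianWell(center=3.8, depth=closed_depth, width=width),
            GaussianWell(center=4.6, depth=open_depth, width=width),
        ),
        wall_position=3.5,
        wall_height=20.0,
        wall_steepness=20.0,
    )


def make_water_pmf(variant: str) -> ModelPMF:
    """Acid-water landscape along the O-O separation.

    ``variant='COH'``: water oxygen bound to the acid O-H proton; a deep
    minimum at 2.7 A plus a shallow secondary minimum at 5.0 A (water
    hydrogen reaching the carbonyl oxygen at large separation).
    ``variant='CO'``: water hydrogen bound to the carbonyl oxygen; a single
    minimum at 2.7 A.  Both are flat (zero) beyond 6 A.
    """
    variant = variant.upper()
    if variant == "COH":
        wells = (
            GaussianWell(center=2.7, depth=30.0, width=0.20),
            GaussianWell(center=5.0, depth=2.0, width=0.30),
        )
    elif variant == "CO":
        wells = (GaussianWell(center=2.7, depth=28.0, width=0.20),)
    else:
        raise ValueError(f"unknown acid-water variant {variant!r}; use 'COH' or 'CO'")
    return ModelPMF(wells=wells, wall_position=2.4, wall_height=20.0, wall_steepness=25.0)


def evaluate_pmf(model: ModelPMF, r):
    """Evaluate W(r) in kJ/mol; ``r`` may be a scalar or array of A > 0."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("separation r must be positive")
    w = model.wall_height * np.exp(-model.wall_steepness * (r_arr - model.wall_position))
    for well in model.wells:
        w = w - well.depth * np.exp(-((r_arr - well.center) ** 2) / (2.0 * well.width**2))
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(w)
    return w


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased window: harmonic restraint k/2 (r - center)^2 on top of W."""

    center: float  # A
    spring_constant: float  # kcal/(mol A^2), the conventional input unit
    temperature: float  # K
    samples: np.ndarray  # stored coordinate values, A
    sample_interval: float = 0.1  # ps between stored samples

    def __post_init__(self) -> None:
        # zero spring = unbiased window (WHAM degenerates to Boltzmann inversion)
        if self.spring_constant < 0:
            raise ValueError("spring constant must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.size == 0:
            raise ValueError("window has no samples")

    @property
    def spring_kj(self) -> float:
        """Spring constant in kJ/(mol A^2)."""
        return spring_kcal_to_kj(self.spring_constant)

    def bias_energy(self, r):
        """Harmonic bias u(r) in kJ/mol."""
        return 0.5 * self.spring_kj * (np.asarray(r, dtype=float) - self.center) ** 2


@dataclass(frozen=True)
class UmbrellaDataset:
    """A ladder of umbrella windows at one temperature."""

    windows: tuple[UmbrellaWindow, ...]
    temperature: float  # K
    coordinate_label: str = "head-group separation (A)"

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("dataset has no windows")
        for w in self.windows:
            if w.temperature != self.temperature:
                raise ValueError(
                    "all windows must share the dataset temperature "
                    f"({w.temperature} K != {self.temperature} K)"
                )
        object.__setattr__(self, "windows", tuple(self.windows))

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])

    def sorted_by_center(self) -> "UmbrellaDataset":
        order = np.argsort(self.centers)
        return replace(self, windows=tuple(self.windows[i] for i in order))


@dataclass(frozen=True)
class SamplerConfig:
    """Controls for the Metropolis sampler.

    ``steps_per_sample`` Metropolis moves are taken between stored samples so
    that the stored stream is effectively decorrelated, mirroring a sparse
    storage stride in a molecular simulation.
    """

    n_samples: int = DEFAULT_N_SAMPLES
    n_equilibration: int = 2_000
    proposal_step: float = 0.3  # A
    seed: int = 0
    steps_per_sample: int = 10

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_equilibration < 0:
            raise ValueError("n_equilibration must be >= 0")
        if self.proposal_step <= 0:
            raise ValueError("proposal_step must be positive")
        if self.steps_per_sample <= 0:
            raise ValueError("steps_per_sample must be positive")


def _log_density_fn(model: ModelPMF, center: float, spring_kj: float, beta: float):
    """Scalar log of the biased Boltzmann density (unnormalised)."""
    wall_h = model.wall_height
    wall_s = model.wall_steepness
    wall_p = model.wall_position
    wells = [(w.center, w.depth, 2.0 * w.width**2) for w in model.wells]

    def logp(r: float) -> float:
        w = wall_h * math.exp(-wall_s * (r - wall_p))
        for c, d, tw2 in wells:
            w -= d * math.exp(-((r - c) ** 2) / tw2)
        w += 0.5 * spring_kj * (r - center) ** 2
        return -beta * w

    return logp


def sample_window(
    model: ModelPMF,
    center: float,
    spring: float,
    temperature: float,
    config: SamplerConfig,
) -> UmbrellaWindow:
    """Draw one umbrella window by Metropolis Monte Carlo.

    ``spring`` is in kcal/(mol A^2).  Samples are distributed proportionally
    to exp(-[W(r) + k/2 (r-center)^2]/kT); the first ``n_equilibration``
    moves are discarded and ``steps_per_sample`` moves separate stored
    samples.  Identical inputs and seed give an identical sample stream.
    """
    if spring <= 0:
        raise ValueError("spring must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    spring_kj = spring_kcal_to_kj(spring)
    beta = 1.0 / kT(temperature)
    logp = _log_density_fn(model, center, spring_kj, beta)

    rng = np.random.default_rng(config.seed)
    n_steps = config.n_equilibration + config.n_samples * config.steps_per_sample
    proposals = rng.normal(0.0, config.proposal_step, n_steps)
    log_u = np.log(rng.random(n_steps))

    x = center
    lp = logp(x)
    out = np.empty(config.n_samples)
    stored = 0
    since_store = 0
    for i in range(n_steps):
        y = x + proposals[i]
        if y > 0:  # proposals at or below r=0 are rejected (domain escape)
            lq = logp(y)
            if log_u[i] < lq - lp:
                x = y
                lp = lq
        if i >= config.n_equilibration:
            since_store += 1
            if since_store == config.steps_per_sample:
                out[stored] = x
                stored += 1
                since_store = 0
    return UmbrellaWindow(
        center=center,
        spring_constant=spring,
        temperature=temperature,
        samples=out,
    )


def run_schedule(
    model: ModelPMF,
    r_start: float = 15.0,
    r_end: float = 3.5,
    spacing: float = DEFAULT_SPACING,
    spring: float = DEFAULT_SPRING_KCAL,
    temperature: float = 300.0,
    config: SamplerConfig | None = None,
) -> UmbrellaDataset:
    """Pull the pair together: windows at r_start, r_start - spacing, ... >= r_end.

    Each window is sampled independently with a per-window seed
    ``config.seed + index`` so the ladder is deterministic yet decorrelated
    across windows.
    """
    if not r_start > r_end > 0:
        raise ValueError("need r_start > r_end > 0")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if config is None:
        config = SamplerConfig()
    n_windows = int(math.floor((r_start - r_end) / spacing + 1e-9)) + 1
    if n_windows < 1:
        raise ValueError("schedule is empty")
    windows = []
    for i in range(n_windows):
        c = r_start - i * spacing
        win_cfg = replace(config, seed=config.seed + i)
        windows.append(sample_window(model, c, spring, temperature, win_cfg))
    return UmbrellaDataset(windows=tuple(windows), temperature=temperature)
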