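"""Weighted histogram analysis method (WHAM) for umbrella windows.

Window samples are binned on a common uniform grid and the standard WHAM
pair of self-consistent equations is iterated directly:

    p_b  =  ( sum_i n_ib )  /  ( sum_i N_i exp(f_i) c_ib )
    exp(-f_i)  =  sum_b p_b c_ib,        c_ib = exp(-u_i(r_b)/kT)

until the largest change in any window shift f_i (kT units) falls below the
tolerance.  The PMF is W_b = -kT ln p_b referenced so that its mean over the
bulk plateau (default r >= 10 A) is zero.  Statistical uncertainty comes from
a parametric Monte Carlo bootstrap: window histogram counts are redrawn
multinomially and WHAM is re-solved per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .synthetic_umbrella import UmbrellaDataset
from .units import kT

__all__ = [
    "PMFProfile",
    "WhamConfig",
    "WhamConvergenceError",
    "solve_wham",
    "overlap_matrix",
    "bootstrap_error",
    "convergence_check",
]


class WhamConvergenceError(RuntimeError):
    """WHAM iteration did not reach the tolerance; carries the residual."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"WHAM did not converge in {iterations} iterations "
            f"(final max |df| = {residual:.3e} kT)"
        )


@dataclass(frozen=True)
class PMFProfile:
    """Binned PMF estimate W(r) with optional per-bin uncertainty.

    Bins never sampled carry ``W = +inf`` (flagged, not interpolated).
    After referencing, the mean of W over the finite bins inside
    ``zero_region`` is zero.
    """

    bin_centers: np.ndarray  # A, strictly increasing, uniform width
    W: np.ndarray  # kJ/mol
    temperature: float  # K
    zero_region: tuple[float, float]
    W_error: np.ndarray | None = None  # kJ/mol
    counts: np.ndarray | None = None  # aggregate samples per bin

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, float))
        object.__setattr__(self, "W", np.asarray(self.W, float))
        if self.bin_centers.shape != self.W.shape:
            raise ValueError("bin_centers and W must have the same shape")
        d = np.diff(self.bin_centers)
        if self.bin_centers.size > 1 and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValueError("bin centers must be strictly increasing and uniform")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.W)

    def zero_referenced(self) -> "PMFProfile":
        """Shift W so its mean over the finite bins of ``zero_region`` is zero."""
        lo, hi = self.zero_region
        mask = (self.bin_centers >= lo) & (self.bin_centers <= hi) & self.finite_mask
        if not mask.any():
            raise ValueError("no finite bins inside the zero region")
        return replace(self, W=self.W - self.W[mask].mean())

    def interp_W(self, r):
        """Linear interpolation of W over the finite bins."""
        m = self.finite_mask
        return np.interp(np.asarray(r, float), self.bin_centers[m], self.W[m])


@dataclass(frozen=True)
class WhamConfig:
    bin_width: float = 0.05  # A; resolves the 0.8 A-separated dimer minima
    tolerance: float = 1e-7  # max |df_i| in kT units
    max_iterations: int = 100_000
    bootstrap_replicates: int = 200
    seed: int = 0
    zero_region_start: float = 10.0  # A; bulk plateau onset

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.tolerance <= 0:
            raise ValueError("bin_width and tolerance must be positive")
        if self.bootstrap_replicates < 0:
            raise ValueError("bootstrap_replicates must be >= 0")


def _bin_grid(dataset: UmbrellaDataset, bin_width: float) -> np.ndarray:
    """Uniform bin edges covering every sample in the dataset."""
    lo = min(w.samples.min() for w in dataset.windows)
    hi = max(w.samples.max() for w in dataset.windows)
    lo = np.floor(lo / bin_width) * bin_width
    n_bins = int(np.ceil((hi - lo) / bin_width)) + 1
    return lo + bin_width * np.arange(n_bins + 1)


def _histogram_counts(dataset: UmbrellaDataset, edges: np.ndarray) -> np.ndarray:
    """(n_windows, n_bins) integer histogram counts."""
    return np.stack([np.histogram(w.samples, bins=edges)[0] for w in dataset.windows])


def _bias_factors(dataset: UmbrellaDataset, centers: np.ndarray) -> np.ndarray:
    """c_ib = exp(-u_i(r_b)/kT); underflow to 0 is intended for far bins."""
    beta = 1.0 / kT(dataset.temperature)
    u = np.stack([w.bias_energy(centers) for w in dataset.windows])
    with np.errstate(under="ignore"):
        return np.exp(-beta * u)


def _iterate_wham(
    counts: np.ndarray,
    c_ib: np.ndarray,
    tolerance: float,
    max_iterations: int,
    f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct iteration of the WHAM equations on histogram counts.

    Returns (p_b, f_i); p_b is zero on bins with no counts, f in kT units.
    """
    n_i = counts.sum(axis=1).astype(float)  # samples per window
    m_b = counts.sum(axis=0).astype(float)  # aggregate counts per bin
    f = np.zeros(len(n_i)) if f_init is None else f_init.copy()
    with np.errstate(divide="ignore", invalid="ignore", under="ignore"):
        for it in range(max_iterations):
            denom = (n_i * np.exp(f)) @ c_ib  # sum_i N_i e^{f_i} c_ib
            p = np.where(m_b > 0, m_b / denom, 0.0)
            z = c_ib @ p  # exp(-f_i_new)
            f_new = -np.log(z)
            f_new -= f_new[0]
            resid = np.abs(f_new - f).max()
            f = f_new
            if resid < tolerance:
                return p / p.sum(), f
    raise WhamConvergenceError(resid, max_iterations)


def solve_wham(dataset: UmbrellaDataset, config: WhamConfig | None = None) -> PMFProfile:
    """Reconstruct the unbiased PMF from a dataset of biased windows."""
    if config is None:
        config = WhamConfig()
    edges = _bin_grid(dataset, config.bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = _histogram_counts(dataset, edges)
    c_ib = _bias_factors(dataset, centers)
    p, _ = _iterate_wham(counts, c_ib, config.tolerance, config.max_iterations)

    m_b = counts.sum(axis=0)
    interior = (m_b == 0) & (centers > centers[m_b > 0].min()) & (centers < centers[m_b > 0].max())
    if interior.any():
        warnings.warn(
            f"{int(interior.sum())} empty bins inside the sampled range; "
            "flagged as +inf, not interpolated",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        W = np.where(p > 0, -kT(dataset.temperature) * np.log(np.where(p > 0, p, 1.0)), np.inf)
    profile = PMFProfile(
        bin_centers=centers,
        W=W,
        temperature=dataset.temperature,
        zero_region=(config.zero_region_start, float(centers[-1])),
        counts=m_b,
    )
    return profile.zero_referenced()


def overlap_matrix(dataset: UmbrellaDataset, config: WhamConfig | None = None) -> np.ndarray:
    """Histogram overlap of adjacent windows (sorted by center).

    Entry j is the summed bin-wise minimum of the normalized histograms of
    windows j and j+1; 1 for identical sampling, 0 for disjoint ranges.
    """
    if config is None:
        config = WhamConfig()
    ds = dataset.sorted_by_center()
    if len(ds.windows) < 2:
        raise ValueError("need at least two windows for overlap")
    edges = _bin_grid(ds, config.bin_width)
    hists = _histogram_counts(ds, edges).astype(float)
    hists /= hists.sum(axis=1, keepdims=True)
    return np.minimum(hists[:-1], hists[1:]).sum(axis=1)


def bootstrap_error(dataset: UmbrellaDataset, config: WhamConfig | None = None) -> PMFProfile:
    """Monte Carlo bootstrap uncertainty of the WHAM PMF.

    Each replicate redraws every window's histogram counts from a
    multinomial with that window's sample size and empirical bin
    probabilities, then re-solves WHAM (warm-started from the full-data
    shifts).  ``W_error`` is the per-bin standard deviation across
    replicates; bins finite in fewer than two replicates get NaN error.
    Deterministic for a fixed ``config.seed``.
    """
    if config is None:
        config = WhamConfig()
    if config.bootstrap_replicates < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    edges = _bin_grid(dataset, config.bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = _histogram_counts(dataset, edges)
    c_ib = _bias_factors(dataset, centers)
    p0, f0 = _iterate_wham(counts, c_ib, config.tolerance, config.max_iterations)
    kt = kT(dataset.temperature)

    rng = np.random.default_rng(config.seed)
    n_i = counts.sum(axis=1)
    probs = counts / n_i[:, None]
    reps = np.full((config.bootstrap_replicates, len(centers)), np.nan)
    failed = 0
    for r in range(config.bootstrap_replicates):
        rc = np.stack([rng.multinomial(n_i[i], probs[i]) for i in range(len(n_i))])
        try:
            p, _ = _iterate_wham(rc, c_ib, config.tolerance, config.max_iterations, f_init=f0)
        except WhamConvergenceError:
            failed += 1
            continue
        with np.errstate(divide="ignore"):
            w = np.where(p > 0, -kt * np.log(np.where(p > 0, p, 1.0)), np.nan)
        lo, hi = config.zero_region_start, centers[-1]
        zmask = (centers >= lo) & (centers <= hi) & np.isfinite(w)
        reps[r] = w - w[zmask].mean()
    if failed:
        warnings.warn(f"{failed} bootstrap replicates failed to converge and were dropped",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        err = np.nanstd(reps, axis=0, ddof=1)
    n_finite = np.sum(np.isfinite(reps), axis=0)
    err[n_finite < 2] = np.nan

    with np.errstate(divide="ignore"):
        W = np.where(p0 > 0, -kt * np.log(np.where(p0 > 0, p0, 1.0)), np.inf)
    profile = PMFProfile(
        bin_centers=centers,
        W=W,
        temperature=dataset.temperature,
        zero_region=(config.zero_region_start, float(centers[-1])),
        W_error=err,
        counts=counts.sum(axis=0),
    )
    return profile.zero_referenced()


def convergence_check(
    dataset: UmbrellaDataset,
    fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0),
    config: WhamConfig | None = None,
    min_counts: int = 10,
):
    """Drift of the PMF when only the leading fraction of each window is used.

    Returns a list of (fraction, max |W_frac - W_full|) over bins finite in
    both solutions and holding at least ``min_counts`` aggregate samples in
    the full data (near-empty edge bins carry O(kT) shot noise that says
    nothing about convergence of the profile).  Fractions must be ascending
    and end at 1.0.
    """
    if config is None:
        config = WhamConfig()
    if list(fractions) != sorted(fractions) or fractions[-1] != 1.0:
        raise ValueError("fractions must be ascending and end at 1.0")
    full = solve_wham(dataset, config)
    rows = []
    for frac in fractions:
        if frac <= 0 or frac > 1:
            raise ValueError("fractions must lie in (0, 1]")
        if frac == 1.0:
            rows.append((1.0, 0.0))
            continue
        trimmed = []
        for w in dataset.windows:
            n = int(len(w.samples) * frac)
            if n == 0:
                raise ValueError(f"fraction {frac} empties a window")
            trimmed.append(replace(w, samples=w.samples[:n]))
        part = solve_wham(
            UmbrellaDataset(windows=tuple(trimmed), temperature=dataset.temperature), config
        )
        w_part = part.interp_W(full.bin_centers)
        mask = full.finite_mask & (full.counts >= min_counts) \
            & (full.bin_centers >= part.bin_centers[part.finite_mask].min()) \
            & (full.bin_centers <= part.bin_centers[part.finite_mask].max())
        rows.append((frac, float(np.abs(w_part[mask] - full.W[mask]).max())))
    return rows
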