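"""PMFs, rescaling, free energies, entropy plateau and block errors.

The full adsorption PMF is estimated from a converged biased run as

    W(s) = -kT ln rho(s) - U_bias(s) + C,

with rho(s) the sampled CV distribution and C an anchor chosen so the
bulk region (far from the surface) averages to zero.  The crystal-growth
PMF replaces rho by rho_r, the distribution of *aligned* states
normalized to the total number of frames, and inherits the same anchor;
its bulk plateau is the orientational entropy penalty -T dS_r.  Free
energies integrate exp(-W/kT) over the contiguous below-zero region
around the global minimum by the trapezoidal rule, with the free-layer
thickness Z_free set equal to the bound-layer thickness (excess
adsorption free energy convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConvergenceError, CrystalignError
from .trajio import KB, BiasGrid, CVSeries

__all__ = [
    "PMFProfile",
    "StateDensity",
    "FreeEnergyResult",
    "pmf_from_bias",
    "aligned_density",
    "state_density",
    "rescale_pmf",
    "free_energy_change",
    "entropy_plateau",
    "block_standard_error",
    "bridge_curve",
    "sampling_diagnostics",
]


@dataclass
class PMFProfile:
    """A binned free-energy profile W(s) with per-bin errors.

    Bins with zero sampled density are undefined and carried as NaN (never
    +-inf); ``anchor`` records the bulk-zero shift that was applied.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    anchor: float = 0.0

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.errors is None:
            self.errors = np.full_like(self.values, np.nan)
        else:
            self.errors = np.asarray(self.errors, dtype=float)
        widths = np.diff(self.bin_centers)
        if len(widths) and not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("PMF bins must be uniform")
        finite = self.values[np.isfinite(self.values)]
        if np.any(np.isinf(finite)):
            raise ValueError("defined PMF values must be finite")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class StateDensity:
    """Per-bin state probability rho(s) = counts / total trajectory frames.

    For the aligned subset the probabilities sum to at most 1; for the
    full state set they sum to 1 (up to frames falling outside the grid).
    """

    bin_centers: np.ndarray
    rho: np.ndarray
    counts: np.ndarray
    total_frames: int

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.total_frames <= 0:
            raise ValueError("total_frames must be positive")
        if not np.allclose(self.rho, self.counts / self.total_frames):
            raise ValueError("rho must equal counts / total_frames")
        if self.rho.sum() > 1.0 + 1e-9:
            raise ValueError("state density cannot exceed unit total mass")


@dataclass
class FreeEnergyResult:
    """Outcome of integrating a PMF: dG, the bound interval and its width."""

    dG: float
    bound_range: tuple[float, float] | None
    z_bound: float

    @property
    def has_bound_state(self) -> bool:
        return self.bound_range is not None


def _bin_edges(bin_centers: np.ndarray) -> np.ndarray:
    w = bin_centers[1] - bin_centers[0]
    return np.concatenate(
        [bin_centers - w / 2.0, [bin_centers[-1] + w / 2.0]]
    )


def state_density(
    s: np.ndarray,
    edges: np.ndarray,
    total_frames: int | None = None,
) -> StateDensity:
    """Histogram CV samples into a StateDensity on the given bin edges."""
    counts, _ = np.histogram(s, bins=edges)
    total = int(total_frames) if total_frames is not None else int(len(s))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return StateDensity(
        bin_centers=centers,
        rho=counts / total,
        counts=counts,
        total_frames=total,
    )


def default_anchor_window(
    edges: np.ndarray, fraction: float = 0.2, upper_limit: float | None = None
) -> tuple[float, float]:
    """Bulk window: the outermost ``fraction`` of the CV range, optionally
    capped at the upper wall onset."""
    hi = float(edges[-1]) if upper_limit is None else min(float(edges[-1]), upper_limit)
    lo = hi - fraction * (hi - float(edges[0]))
    return lo, hi


def pmf_from_bias(
    cv: CVSeries,
    bias: BiasGrid,
    bins: int | np.ndarray,
    temperature: float,
    anchor_window: tuple[float, float] | None = None,
    max_empty_fraction: float = 0.5,
) -> PMFProfile:
    """Full adsorption PMF from a biased CV series and its bias grid.

    ``bins`` is either a bin count (spread over the sampled CV range) or
    an explicit edge array.  Empty bins are undefined (NaN); if more than
    ``max_empty_fraction`` of the bins are empty the run is deemed
    unconverged.  The profile is anchored so the mean over
    ``anchor_window`` (default: the outermost 20 % of the range) is zero.
    """
    if np.isscalar(bins):
        edges = np.linspace(cv.s.min(), cv.s.max(), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    dens = state_density(cv.s, edges)
    kT = KB * temperature
    with np.errstate(divide="ignore"):
        w = np.where(dens.counts > 0, -kT * np.log(np.where(dens.counts > 0, dens.rho, 1.0)), np.nan)
    w = w - bias.evaluate(dens.bin_centers)
    empty = np.mean(dens.counts == 0)
    if empty > max_empty_fraction:
        raise ConvergenceError(
            f"{empty:.0%} of PMF bins are empty; sampling has not covered the CV range"
        )
    if anchor_window is None:
        anchor_window = default_anchor_window(edges)
    lo, hi = anchor_window
    in_win = (dens.bin_centers >= lo) & (dens.bin_centers <= hi)
    if not np.any(in_win & np.isfinite(w)):
        raise ConvergenceError("no defined bins inside the anchoring window")
    anchor = -float(np.nanmean(w[in_win]))
    return PMFProfile(
        bin_centers=dens.bin_centers,
        values=w + anchor,
        anchor=anchor,
    )


def aligned_density(
    records: pd.DataFrame,
    cv: CVSeries,
    n_bins: int = 100,
    edges: np.ndarray | None = None,
) -> StateDensity:
    """Density of crystal-growth (aligned) states over the CV.

    ``records`` must cover both bound and unbound frames (one row per
    frame with an ``aligned`` flag); the density is normalized to the
    total number of frames in the trajectory, not to the aligned count.
    """
    if edges is None:
        edges = np.linspace(cv.s.min(), cv.s.max(), n_bins + 1)
    idx = records["frame_index"].to_numpy()
    aligned = records["aligned"].to_numpy(dtype=bool)
    s_aligned = cv.s[idx[aligned]]
    return state_density(s_aligned, edges, total_frames=len(cv))


def rescale_pmf(
    density_r: StateDensity,
    bias: BiasGrid,
    full: PMFProfile,
    temperature: float,
    form: str = "approx",
    density_all: StateDensity | None = None,
) -> PMFProfile:
    """Crystal-growth PMF from the aligned-state density.

    ``form="approx"`` assumes the biased CV distribution is uniform (a
    converged flat-sampling run) and computes
    W_r = -kT ln rho_r - U_bias + C with the anchor C inherited from the
    full PMF.  ``form="exact"`` keeps the sampled rho explicitly:
    W_r = W - kT ln(rho_r / rho).  Bins with no aligned states are
    undefined.  Wherever both are defined, W_r >= W because
    rho_r <= rho by construction.
    """
    if not np.allclose(density_r.bin_centers, full.bin_centers):
        raise ValueError("rescaled density must share the full PMF binning")
    kT = KB * temperature
    pos = density_r.counts > 0
    with np.errstate(divide="ignore"):
        if form == "approx":
            w_r = np.where(
                pos, -kT * np.log(np.where(pos, density_r.rho, 1.0)), np.nan
            )
            w_r = w_r - bias.evaluate(density_r.bin_centers) + full.anchor
        elif form == "exact":
            if density_all is None:
                raise ValueError("exact form requires the full state density")
            both = pos & (density_all.counts > 0)
            ratio = np.where(
                both, density_r.rho / np.where(both, density_all.rho, 1.0), 1.0
            )
            w_r = np.where(both, full.values - kT * np.log(ratio), np.nan)
        else:
            raise ValueError(f"unknown rescaling form {form!r}")
    return PMFProfile(
        bin_centers=full.bin_centers, values=w_r, anchor=full.anchor
    )


def free_energy_change(
    profile: PMFProfile,
    temperature: float,
) -> FreeEnergyResult:
    """Free energy change from a bulk-anchored PMF.

    The bound region is the contiguous interval around the global minimum
    where the curve is below zero.  I_b = int_bound exp(-W/kT) ds by the
    trapezoidal rule over the defined bin centres in that interval, the
    free-layer thickness equals the bound-layer thickness, and
    dG = -kT ln(I_b / Z_free).  A profile that never drops below zero has
    no bound state (dG = NaN).
    """
    vals = profile.values
    centers = profile.bin_centers
    finite = np.isfinite(vals)
    below = finite & (vals < 0.0)
    if not below.any():
        warnings.warn("PMF never below zero: no bound state")
        return FreeEnergyResult(dG=float("nan"), bound_range=None, z_bound=0.0)
    kT = KB * temperature
    imin = int(np.nanargmin(np.where(finite, vals, np.inf)))
    lo = imin
    while lo - 1 >= 0 and below[lo - 1]:
        lo -= 1
    hi = imin
    while hi + 1 < len(vals) and below[hi + 1]:
        hi += 1
    sel = slice(lo, hi + 1)
    s_sel = centers[sel]
    w_sel = vals[sel]
    defined = np.isfinite(w_sel)
    if not defined.all():
        warnings.warn(
            "undefined bins inside the bound region were skipped in the "
            "free-energy integral"
        )
        s_sel, w_sel = s_sel[defined], w_sel[defined]
    if len(s_sel) < 2:
        warnings.warn("bound region narrower than two bins; dG undefined")
        return FreeEnergyResult(dG=float("nan"), bound_range=None, z_bound=0.0)
    integrand = np.exp(-w_sel / kT)
    i_b = np.trapezoid(integrand, s_sel)
    z_bound = float(s_sel[-1] - s_sel[0])
    dG = -kT * np.log(i_b / z_bound)
    return FreeEnergyResult(
        dG=float(dG),
        bound_range=(float(s_sel[0]), float(s_sel[-1])),
        z_bound=z_bound,
    )


def entropy_plateau(
    rescaled: PMFProfile,
    bulk_window: tuple[float, float],
    min_bins: int = 5,
) -> float:
    """-T dS_r: mean of the rescaled PMF over its long-distance plateau.

    Far from the surface the rescaled PMF fluctuates around a constant —
    the free-energy cost of confining a randomly oriented solute to
    lattice-compatible orientations.  Undefined bins inside the window are
    skipped; fewer than ``min_bins`` defined bins is an error.
    """
    lo, hi = bulk_window
    sel = (rescaled.bin_centers >= lo) & (rescaled.bin_centers <= hi)
    vals = rescaled.values[sel]
    n_def = int(np.isfinite(vals).sum())
    if n_def < min_bins:
        raise CrystalignError(
            f"only {n_def} defined bins in the entropy window; need >= {min_bins}"
        )
    return float(np.nanmean(vals))


def block_standard_error(
    n_frames: int,
    block_frames: int,
    estimator: Callable[[slice], float | np.ndarray],
    min_blocks: int = 5,
) -> tuple[np.ndarray | float, np.ndarray | float, int]:
    """Block-averaged standard error of a correlated-series estimate.

    The frame range is cut into ``B = n_frames // block_frames``
    contiguous blocks, ``estimator`` is re-run on each block (it may
    return a scalar or a per-bin array, NaN where undefined), and the
    standard error of the mean across blocks is reported per component.

    Returns ``(mean, se, n_blocks)``.
    """
    n_blocks = int(n_frames) // int(block_frames)
    if n_blocks < min_blocks:
        raise CrystalignError(
            f"{n_blocks} blocks of {block_frames} frames from {n_frames} "
            f"frames; need >= {min_blocks}"
        )
    vals = [
        np.asarray(estimator(slice(b * block_frames, (b + 1) * block_frames)))
        for b in range(n_blocks)
    ]
    arr = np.array(vals, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_def = np.sum(np.isfinite(arr), axis=0)
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
    se = np.where(n_def > 1, sd / np.sqrt(np.maximum(n_def, 1)), np.nan)
    if np.ndim(mean) == 0:
        return float(mean), float(se), n_blocks
    return mean, se, n_blocks


def bridge_curve(
    rescaled: PMFProfile,
    bound_range: tuple[float, float],
    plateau: float,
    plateau_start: float,
) -> PMFProfile:
    """Logarithmic display-only interpolation between well and plateau.

    Between the outer edge of the bound region and the start of the bulk
    plateau the rescaled PMF mixes orientational populations and is not
    quantitatively meaningful; for plotting it is replaced by
    a + b ln(s - s0) matching the curve value at the bound edge and the
    plateau value at the plateau start.  The bridge is returned as its own
    profile (NaN outside the bridged interval) and must never enter any
    free-energy or entropy evaluation.
    """
    centers = rescaled.bin_centers
    s_edge = bound_range[1]
    i_edge = int(np.argmin(np.abs(centers - s_edge)))
    # walk inward to the nearest defined bin
    while i_edge > 0 and not np.isfinite(rescaled.values[i_edge]):
        i_edge -= 1
    w_edge = rescaled.values[i_edge]
    s_edge = centers[i_edge]
    if not np.isfinite(w_edge):
        raise CrystalignError("no defined rescaled value at the bound edge")
    finite_min = np.nanmin(rescaled.values)
    s0 = bound_range[0] - rescaled.bin_width
    denom = np.log((plateau_start - s0) / (s_edge - s0))
    if abs(denom) < 1e-12 or abs(plateau - w_edge) < 1e-12:
        b = 0.0
    else:
        b = (plateau - w_edge) / denom
    a = w_edge - b * np.log(s_edge - s0)
    mask = (centers >= s_edge) & (centers <= plateau_start)
    vals = np.full_like(centers, np.nan)
    vals[mask] = a + b * np.log(centers[mask] - s0)
    return PMFProfile(bin_centers=centers, values=vals, anchor=rescaled.anchor)


def sampling_diagnostics(
    positions: np.ndarray,
    cv: CVSeries,
    box_lateral: np.ndarray,
    z_range: tuple[float, float],
    voxel: float = 0.1,
    n_bins: int = 100,
    s_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Volume-coverage and CV-flatness convergence diagnostics.

    ``positions``: solute COM per frame (n, 3).  The aqueous region
    (lateral cell x ``z_range``) is voxelized at ``voxel`` nm and the
    fraction of voxels ever visited is reported, together with the
    flatness max |rho(s) n_bins - 1| of the CV histogram over
    ``s_range`` (default: the full sampled range), rho renormalized over
    that range.  A converged flat-sampling run should give coverage near 1
    and flatness well below 1.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 1000:
        warnings.warn("fewer than 1000 frames: diagnostics are unreliable")
    lx = float(box_lateral[0, 0])
    ly = float(box_lateral[1, 1])
    z_lo, z_hi = z_range
    nx = max(int(np.ceil(lx / voxel)), 1)
    ny = max(int(np.ceil(ly / voxel)), 1)
    nz = max(int(np.ceil((z_hi - z_lo) / voxel)), 1)
    ix = np.floor(positions[:, 0] % lx / lx * nx).astype(int).clip(0, nx - 1)
    iy = np.floor(positions[:, 1] % ly / ly * ny).astype(int).clip(0, ny - 1)
    zsel = (positions[:, 2] >= z_lo) & (positions[:, 2] < z_hi)
    iz = np.floor(
        (positions[zsel, 2] - z_lo) / (z_hi - z_lo) * nz
    ).astype(int).clip(0, nz - 1)
    flat_idx = (ix[zsel] * ny + iy[zsel]) * nz + iz
    covered = len(np.unique(flat_idx)) / (nx * ny * nz)

    if s_range is None:
        s_range = (float(cv.s.min()), float(cv.s.max()))
    sel = (cv.s >= s_range[0]) & (cv.s <= s_range[1])
    counts, _ = np.histogram(cv.s[sel], bins=n_bins, range=s_range)
    nonzero = counts > 0
    rho = counts / max(counts.sum(), 1)
    flatness = float(np.abs(rho[nonzero] * n_bins - 1.0).max())
    return float(covered), flatness
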