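"""End-to-end orchestration: trajectory + CV + bias -> thermodynamics.

The stages, in order: full PMF from the biased CV distribution; bound /
unbound split at the -0.9 kJ/mol contour of the PMF minimum; alignment
tests (angles against the reference-layer molecule for bound frames, the
selection ellipse fitted to the angle-passing bound states, any-surface
matching for unbound frames); aligned-state density; rescaled PMF; free
energies, entropy plateau and block-averaged errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alignment as al
from . import thermo as th
from .colvar_geometry import SlabModel, WallSpec, compute_com
from .config import RunConfig
from .errors import CrystalignError
from .trajio import KB, BiasGrid, CVSeries, ThermoResult, TrajectoryBundle

__all__ = ["FrameGeometry", "AnalysisResult", "solute_geometry", "analyze"]


@dataclass
class FrameGeometry:
    """Per-frame solute geometry the alignment stage consumes."""

    ring_coms: np.ndarray     # (n, 2, 3)
    ring_normals: np.ndarray  # (n, 2, 3)
    coms: np.ndarray          # (n, 3) solute COM
    u: np.ndarray             # (n, 3) ring-axis vector
    w: np.ndarray             # (n, 3) amide vector

    @property
    def n_frames(self) -> int:
        return len(self.coms)


def solute_geometry(
    sol_xyz: np.ndarray,
    rings: al.RingTopology,
    masses: np.ndarray,
    com_mode: str = "mass",
) -> FrameGeometry:
    """Ring frames, COM and intramolecular vectors from solute coordinates.

    ``sol_xyz``: (n_frames, n_solute_atoms, 3); ``rings`` uses indices
    relative to the solute's own atom ordering; ``masses`` matches that
    ordering.
    """
    coms = compute_com(sol_xyz, np.arange(sol_xyz.shape[1]), masses, com_mode)
    ring_coms, ring_normals = al.rings_geometry_series(sol_xyz, rings)
    u = ring_coms[:, 1] - ring_coms[:, 0]
    w = sol_xyz[:, rings.amide[1]] - sol_xyz[:, rings.amide[0]]
    return FrameGeometry(ring_coms, ring_normals, coms, u, w)


def geometry_from_bundle(
    bundle: TrajectoryBundle,
    rings_template: al.RingTopology,
    com_mode: str = "mass",
    chunk: int = 20000,
) -> FrameGeometry:
    """Stream a TrajectoryBundle into per-frame solute geometry."""
    parts = []
    sol = bundle.solute_atoms
    sol_masses = bundle.masses[sol]
    for _, xyz in bundle.iter_chunks(chunk):
        parts.append(
            solute_geometry(xyz[:, sol], rings_template, sol_masses, com_mode)
        )
    return FrameGeometry(
        ring_coms=np.concatenate([p.ring_coms for p in parts]),
        ring_normals=np.concatenate([p.ring_normals for p in parts]),
        coms=np.concatenate([p.coms for p in parts]),
        u=np.concatenate([p.u for p in parts]),
        w=np.concatenate([p.w for p in parts]),
    )


@dataclass
class AnalysisResult:
    full: th.PMFProfile
    rescaled: th.PMFProfile
    bridge: th.PMFProfile | None
    density_all: th.StateDensity
    density_r: th.StateDensity
    records: pd.DataFrame
    ellipse: al.SelectionEllipse | None
    thermo: ThermoResult
    diagnostics: dict
    bound_range: tuple[float, float] | None


def _dg_over_range(
    centers: np.ndarray,
    vals: np.ndarray,
    s_range: tuple[float, float],
    kT: float,
) -> float:
    sel = (centers >= s_range[0]) & (centers <= s_range[1]) & np.isfinite(vals)
    if sel.sum() < 2:
        return float("nan")
    s, w = centers[sel], vals[sel]
    i_b = np.trapezoid(np.exp(-w / kT), s)
    z = s[-1] - s[0]
    if z <= 0 or i_b <= 0:
        return float("nan")
    return float(-kT * np.log(i_b / z))


def analyze(
    geom: FrameGeometry,
    cv: CVSeries,
    bias: BiasGrid,
    slab: SlabModel,
    slab_geom: dict,
    config: RunConfig | None = None,
) -> AnalysisResult:
    """Run the full rescaling analysis.

    ``slab_geom`` is the precomputed reference-slab ring geometry from
    :func:`crystalign.alignment.slab_molecule_geometry`.
    """
    cfg = config or RunConfig()
    if geom.n_frames != len(cv):
        raise CrystalignError(
            f"geometry has {geom.n_frames} frames but CV series {len(cv)}"
        )
    kT = KB * cfg.temperature
    edges = np.linspace(cv.s.min(), cv.s.max(), cfg.n_bins_density + 1)
    anchor_window = cfg.anchor_window
    if anchor_window is None:
        hi = min(float(edges[-1]), cfg.wall_upper_a)
        lo_lim = max(float(edges[0]), cfg.wall_lower_a)
        anchor_window = (hi - cfg.anchor_fraction * (hi - lo_lim), hi)
    entropy_window = cfg.entropy_window or anchor_window

    full = th.pmf_from_bias(cv, bias, edges, cfg.temperature, anchor_window)
    bound_mask, unbound_mask, bound_range = al.split_bound_unbound(
        cv, full, cfg.bound_threshold
    )
    bound_idx = np.nonzero(bound_mask)[0]
    unbound_idx = np.nonzero(unbound_mask)[0]

    # --- bound-state alignment: angles first, then the ellipse ---------
    ellipse = None
    extra = [
        al.SelectionEllipse.from_dict(d) for d in (cfg.extra_aligned_regions or [])
    ]
    if len(bound_idx):
        rec_b = al.select_aligned(
            geom.ring_coms[bound_idx],
            geom.ring_normals[bound_idx],
            geom.coms[bound_idx],
            bound_idx,
            slab,
            slab_geom,
            "bound",
            angle_window=cfg.angle_window_deg,
            ellipse=None,
        )
        d_pass = rec_b.loc[rec_b["angle_pass"], ["d1", "d3"]].to_numpy()
        if len(d_pass):
            ellipse = al.fit_selection_ellipse(
                d_pass, cfg.ellipse_fraction, cfg.ellipse_bins
            )
            rec_b = al.select_aligned(
                geom.ring_coms[bound_idx],
                geom.ring_normals[bound_idx],
                geom.coms[bound_idx],
                bound_idx,
                slab,
                slab_geom,
                "bound",
                angle_window=cfg.angle_window_deg,
                ellipse=ellipse,
                extra_regions=extra or None,
            )
        else:
            warnings.warn("no angle-passing bound states; ellipse not fitted")
    else:
        rec_b = al.select_aligned(
            geom.ring_coms[:0], geom.ring_normals[:0], geom.coms[:0],
            np.empty(0, dtype=int), slab, slab_geom, "bound",
        )

    rec_u = al.select_aligned(
        geom.ring_coms[unbound_idx],
        geom.ring_normals[unbound_idx],
        geom.coms[unbound_idx],
        unbound_idx,
        slab,
        slab_geom,
        "unbound",
        angle_window=cfg.angle_window_deg,
        ellipse=ellipse,
        extra_regions=extra or None,
    )
    records = (
        pd.concat([rec_b, rec_u], ignore_index=True)
        .sort_values("frame_index")
        .reset_index(drop=True)
    )
    # orientation modes of aligned frames
    aligned_mask = records["aligned"].to_numpy(dtype=bool)
    modes = np.full(len(records), "none", dtype=object)
    if aligned_mask.any():
        fi = records.loc[aligned_mask, "frame_index"].to_numpy()
        partner = records.loc[aligned_mask, "partner"].to_numpy()
        modes[aligned_mask] = al.classify_orientation_mode(
            geom.u[fi], geom.w[fi],
            slab_geom["u"][partner], slab_geom["w"][partner],
        )
    records["mode"] = modes

    # --- densities and rescaled PMF ------------------------------------
    density_all = th.state_density(cv.s, edges)
    density_r = th.aligned_density(records, cv, edges=edges)
    rescaled = th.rescale_pmf(
        density_r, bias, full, cfg.temperature,
        form=cfg.rescale_form, density_all=density_all,
    )

    # --- scalars --------------------------------------------------------
    fe_full = th.free_energy_change(full, cfg.temperature)
    fe_r = th.free_energy_change(rescaled, cfg.temperature)
    try:
        plateau = th.entropy_plateau(rescaled, entropy_window)
    except CrystalignError as exc:
        warnings.warn(f"entropy plateau unavailable: {exc}")
        plateau = float("nan")

    # --- block errors ---------------------------------------------------
    centers = full.bin_centers
    bias_c = bias.evaluate(centers)
    aligned_by_frame = np.zeros(geom.n_frames, dtype=bool)
    aligned_by_frame[records.loc[aligned_mask, "frame_index"].to_numpy()] = True
    in_anchor = (centers >= anchor_window[0]) & (centers <= anchor_window[1])
    n_total = geom.n_frames

    def _block_w(frames: np.ndarray) -> np.ndarray:
        counts, _ = np.histogram(cv.s[frames], bins=edges)
        with np.errstate(divide="ignore"):
            w = np.where(counts > 0, -kT * np.log(counts / len(frames)), np.nan)
        w = w - bias_c
        if not np.any(np.isfinite(w[in_anchor])):
            return np.full_like(w, np.nan)
        return w - np.nanmean(w[in_anchor])

    def _block_wr(frames: np.ndarray, norm: float) -> np.ndarray:
        sel = frames[aligned_by_frame[frames]]
        counts, _ = np.histogram(cv.s[sel], bins=edges)
        rho = counts / max(len(frames), 1) * norm
        with np.errstate(divide="ignore"):
            w = np.where(counts > 0, -kT * np.log(rho), np.nan)
        return w - bias_c + full.anchor

    all_frames = np.arange(n_total)
    full_err = np.full_like(centers, np.nan)
    dg_ads_err = dg_r_err = plateau_err = float("nan")
    try:
        w_blocks, full_err, _ = th.block_standard_error(
            n_total, cfg.block_frames_bound,
            lambda sl: _block_w(all_frames[sl]),
        )
        if fe_full.has_bound_state:
            _, dg_ads_err, _ = th.block_standard_error(
                n_total, cfg.block_frames_bound,
                lambda sl: _dg_over_range(
                    centers, _block_w(all_frames[sl]), fe_full.bound_range, kT
                ),
            )
    except CrystalignError as exc:
        warnings.warn(f"full-PMF block errors unavailable: {exc}")
    full.errors = full_err

    wr_err = np.full_like(centers, np.nan)
    if len(bound_idx) and fe_r.has_bound_state:
        try:
            norm_b = len(bound_idx) / n_total
            _, err_b, _ = th.block_standard_error(
                len(bound_idx), cfg.block_frames_bound,
                lambda sl: _block_wr(bound_idx[sl], norm_b),
            )
            _, dg_r_err, _ = th.block_standard_error(
                len(bound_idx), cfg.block_frames_bound,
                lambda sl: _dg_over_range(
                    centers, _block_wr(bound_idx[sl], norm_b),
                    fe_r.bound_range, kT,
                ),
            )
            in_bound = (centers >= bound_range[0]) & (centers <= bound_range[1])
            wr_err[in_bound] = err_b[in_bound]
        except CrystalignError as exc:
            warnings.warn(f"bound-state block errors unavailable: {exc}")
    if len(unbound_idx):
        try:
            norm_u = len(unbound_idx) / n_total
            in_win = (centers >= entropy_window[0]) & (centers <= entropy_window[1])
            _, err_u, _ = th.block_standard_error(
                len(unbound_idx), cfg.block_frames_unbound,
                lambda sl: _block_wr(unbound_idx[sl], norm_u),
            )
            _, plateau_err, _ = th.block_standard_error(
                len(unbound_idx), cfg.block_frames_unbound,
                lambda sl: _nanmean_or_nan(
                    _block_wr(unbound_idx[sl], norm_u)[in_win]
                ),
            )
            outside = ~(
                (centers >= (bound_range[0] if bound_range else np.inf))
                & (centers <= (bound_range[1] if bound_range else -np.inf))
            )
            wr_err[outside] = err_u[outside]
        except CrystalignError as exc:
            warnings.warn(f"unbound-state block errors unavailable: {exc}")
    rescaled.errors = wr_err

    # --- display bridge and diagnostics --------------------------------
    bridge = None
    if fe_r.has_bound_state and np.isfinite(plateau):
        try:
            bridge = th.bridge_curve(
                rescaled, fe_r.bound_range, plateau, entropy_window[0]
            )
        except CrystalignError:
            bridge = None
    z_lo = slab.surface_z
    z_hi = slab.surface_z + cfg.wall_upper_a
    covered, flatness = th.sampling_diagnostics(
        geom.coms, cv, slab.box_lateral, (z_lo, z_hi),
        s_range=(
            max(float(cv.s.min()), cfg.wall_lower_a),
            min(float(cv.s.max()), cfg.wall_upper_a),
        ),
    )
    n_bound_aligned = int((records["aligned"] & records["bound"]).sum())
    diagnostics = {
        "covered_volume_fraction": covered,
        "cv_flatness": flatness,
        "n_frames": int(n_total),
        "n_bound": int(len(bound_idx)),
        "n_aligned": int(aligned_mask.sum()),
        "n_bound_aligned": n_bound_aligned,
        "bound_aligned_percent": (
            100.0 * n_bound_aligned / len(bound_idx) if len(bound_idx) else 0.0
        ),
    }
    thermo_res = ThermoResult(
        dG_ads=fe_full.dG,
        dG_ads_err=dg_ads_err,
        dG_r=fe_r.dG,
        dG_r_err=dg_r_err,
        minus_T_dS=plateau,
        minus_T_dS_err=plateau_err,
        temperature=cfg.temperature,
        bound_range=bound_range,
    )
    return AnalysisResult(
        full=full,
        rescaled=rescaled,
        bridge=bridge,
        density_all=density_all,
        density_r=density_r,
        records=records,
        ellipse=ellipse,
        thermo=thermo_res,
        diagnostics=diagnostics,
        bound_range=bound_range,
    )


def _nanmean_or_nan(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    return float(x.mean()) if len(x) else float("nan")
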