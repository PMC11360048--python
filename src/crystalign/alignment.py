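"""Frame-by-frame decision whether the solute is aligned with the lattice.

A solute orientation counts as a crystal-growth state when the planes of
its two six-membered rings lie within a window (default 30 deg, i.e.
0-30 or 150-180 because the ring system can flip) of the planes of the
matching rings of a slab molecule, and when the paired ring
centre-of-mass distances fall inside an ellipse fitted to the maximum of
their joint distribution.  Ring correspondence is not fixed a priori: the
two possible ring pairings are scored by the summed length of the
COM-connecting vectors v1 and v2 and the shorter assignment wins.

Bound states (inside the PMF minimum) are tested against the single
reference-layer molecule the solute projects onto; unbound states are
tested against every molecule of the surface layer and pass if any
matches.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .colvar_geometry import SlabModel, compute_com, lateral_min_image
from .errors import CrystalignError, DegenerateGeometryError
from .trajio import CVSeries

__all__ = [
    "RingTopology",
    "AlignmentRecord",
    "SelectionEllipse",
    "ring_frame",
    "reference_layer_molecule",
    "pair_rings",
    "ring_alignment_angles",
    "passes_angle_window",
    "ring_com_distances",
    "fit_selection_ellipse",
    "split_bound_unbound",
    "select_aligned",
    "classify_orientation_mode",
]

ORIENTATION_MODES = ("full", "amide_rotated", "ring_flipped")


@dataclass
class RingTopology:
    """Atom bookkeeping of one two-ring molecule.

    Indices are relative to the molecule's own atom ordering; use
    :meth:`for_atoms` to translate to absolute indices of a particular
    molecule.  ``amide`` holds the two atoms whose difference defines the
    amide vector; ``axis`` the two atoms spanning the ring-axis vector.
    """

    ring_a: np.ndarray
    ring_b: np.ndarray
    amide: np.ndarray
    axis: np.ndarray

    def __post_init__(self) -> None:
        self.ring_a = np.asarray(self.ring_a, dtype=int)
        self.ring_b = np.asarray(self.ring_b, dtype=int)
        self.amide = np.asarray(self.amide, dtype=int)
        self.axis = np.asarray(self.axis, dtype=int)
        if self.ring_a.size != 6 or self.ring_b.size != 6:
            raise ValueError("each ring must contain exactly 6 atoms")
        if set(self.ring_a) & set(self.ring_b):
            raise ValueError("rings must be disjoint")
        if self.amide.size != 2 or self.axis.size != 2:
            raise ValueError("amide and axis are defined by 2 atoms each")

    def for_atoms(self, atom_indices: np.ndarray) -> "RingTopology":
        """Map relative indices onto a molecule's absolute atom indices."""
        atom_indices = np.asarray(atom_indices)
        return RingTopology(
            ring_a=atom_indices[self.ring_a],
            ring_b=atom_indices[self.ring_b],
            amide=atom_indices[self.amide],
            axis=atom_indices[self.axis],
        )


@dataclass
class AlignmentRecord:
    """Per-frame outcome of the alignment test."""

    frame_index: int
    partner: int
    pairing: tuple[tuple[int, int], tuple[int, int]]
    theta1: float
    theta3: float
    d1: float
    d3: float
    angle_pass: bool
    ellipse_pass: bool
    aligned: bool
    mode: str = "none"
    bound: bool = True

    def __post_init__(self) -> None:
        if self.aligned and not (self.angle_pass and self.ellipse_pass):
            raise ValueError("aligned implies angle_pass and ellipse_pass")
        for th in (self.theta1, self.theta3):
            if np.isfinite(th) and not 0.0 <= th <= 180.0:
                raise ValueError("angles must lie in [0, 180]")
        for d in (self.d1, self.d3):
            if np.isfinite(d) and d < 0:
                raise ValueError("distances must be non-negative")


def records_to_frame(records: list[AlignmentRecord]) -> pd.DataFrame:
    """Tabulate AlignmentRecords (CSV-exportable)."""
    return pd.DataFrame(
        {
            "frame_index": [r.frame_index for r in records],
            "partner": [r.partner for r in records],
            "crossed_pairing": [r.pairing[0][1] == 1 for r in records],
            "theta1": [r.theta1 for r in records],
            "theta3": [r.theta3 for r in records],
            "d1": [r.d1 for r in records],
            "d3": [r.d3 for r in records],
            "angle_pass": [r.angle_pass for r in records],
            "ellipse_pass": [r.ellipse_pass for r in records],
            "aligned": [r.aligned for r in records],
            "mode": [r.mode for r in records],
            "bound": [r.bound for r in records],
        }
    )


# ---------------------------------------------------------------------------
# ring geometry
# ---------------------------------------------------------------------------

def _ring_normals_batch(pos: np.ndarray) -> np.ndarray:
    """Unit normals of least-squares ring planes for a batch.

    ``pos``: (..., 6, 3) ring atom positions in topology order.  The sign
    is fixed by the right-hand rule over that ordering (sum of consecutive
    edge cross products).
    """
    com = pos.mean(axis=-2, keepdims=True)
    centered = pos - com
    # smallest right-singular vector = least-squares plane normal
    _, sv, vh = np.linalg.svd(centered)
    if np.any(sv[..., 1] < 1e-10):
        raise DegenerateGeometryError("collinear ring atoms: plane undefined")
    normal = vh[..., 2, :]
    rolled = np.roll(centered, -1, axis=-2)
    rh = np.cross(centered, rolled).sum(axis=-2)
    sign = np.sign(np.einsum("...i,...i->...", rh, normal))
    sign = np.where(sign == 0, 1.0, sign)
    return normal * sign[..., None]


def ring_frame(
    xyz: np.ndarray, rings: RingTopology
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """(COM, unit normal) for both rings of one molecule in one frame.

    COM is the plain mean of the six ring atoms; the normal is the unit
    normal of the least-squares plane with its sign fixed by the
    right-hand rule over the topology's atom ordering (counter-clockwise
    ordering in the xy-plane gives +z).
    """
    out = []
    for ring in (rings.ring_a, rings.ring_b):
        pos = xyz[ring]
        com = pos.mean(axis=0)
        normal = _ring_normals_batch(pos[None])[0]
        out.append((com, normal))
    return out[0], out[1]


def rings_geometry_series(
    xyz: np.ndarray, rings: RingTopology
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ring COMs and normals over frames.

    ``xyz``: (n_frames, n_atoms, 3).  Returns ``coms`` (n, 2, 3) and
    ``normals`` (n, 2, 3), index 0 = ring A, 1 = ring B.
    """
    pos = np.stack(
        [xyz[:, rings.ring_a, :], xyz[:, rings.ring_b, :]], axis=1
    )  # (n, 2, 6, 3)
    coms = pos.mean(axis=-2)
    normals = _ring_normals_batch(pos)
    return coms, normals


# ---------------------------------------------------------------------------
# partner selection and ring pairing
# ---------------------------------------------------------------------------

def reference_layer_molecule(
    solute_com: np.ndarray,
    slab: SlabModel,
    slab_mol_coms: np.ndarray,
    candidates: list[int] | None = None,
) -> int | np.ndarray:
    """Reference-layer molecule laterally closest to the solute's z-projection.

    ``solute_com``: (3,) or (n, 3); ``slab_mol_coms``: (n_mol, 3) COMs of
    all slab molecules (reference coordinates).  Distances are
    minimum-imaged in the lateral cell.  Exact ties resolve to the lowest
    molecule id.
    """
    if candidates is None:
        candidates = slab.reference_layer
    if not candidates:
        raise CrystalignError("reference layer is empty")
    cand = sorted(candidates)
    ref = slab_mol_coms[cand]  # (m, 3)
    d = solute_com[..., None, :] - ref  # (..., m, 3)
    d = lateral_min_image(d, slab.box_lateral)
    lat2 = np.einsum("...i,...i->...", d[..., :2], d[..., :2])
    best = np.argmin(lat2, axis=-1)  # argmin returns first (lowest id) on ties
    out = np.asarray(cand)[best]
    return int(out) if np.ndim(out) == 0 else out


def pair_rings(
    solute_coms: np.ndarray,
    slab_coms: np.ndarray,
    box_lateral: np.ndarray | None = None,
) -> tuple[tuple[tuple[int, int], tuple[int, int]], np.ndarray, np.ndarray]:
    """Assign solute rings to slab rings by minimizing |v1| + |v2|.

    Both bijections between the two ring pairs are evaluated; the one with
    the smaller summed COM-vector length wins, the identity pairing being
    preferred on an exact tie.  Returns ``(pairing, v1, v2)`` where
    ``pairing`` maps (solute ring -> slab ring) and ``v_k`` is the
    (minimum-imaged) vector from slab ring to its paired solute ring.
    """
    def vec(i: int, j: int) -> np.ndarray:
        d = solute_coms[i] - slab_coms[j]
        if box_lateral is not None:
            d = lateral_min_image(d, box_lateral)
        return d

    v_id = (vec(0, 0), vec(1, 1))
    v_cr = (vec(0, 1), vec(1, 0))
    cost_id = np.linalg.norm(v_id[0]) + np.linalg.norm(v_id[1])
    cost_cr = np.linalg.norm(v_cr[0]) + np.linalg.norm(v_cr[1])
    if cost_cr < cost_id:
        return ((0, 1), (1, 0)), v_cr[0], v_cr[1]
    return ((0, 0), (1, 1)), v_id[0], v_id[1]


def ring_alignment_angles(
    solute_normals: np.ndarray,
    slab_normals: np.ndarray,
    pairing: tuple[tuple[int, int], tuple[int, int]],
) -> tuple[float, float]:
    """Angles (deg, in [0, 180]) between paired ring-plane normals."""
    out = []
    for si, bi in pairing:
        ns, nb = solute_normals[si], slab_normals[bi]
        for n in (ns, nb):
            if abs(np.linalg.norm(n) - 1.0) > 1e-6:
                raise ValueError("ring normals must be unit vectors")
        out.append(float(np.degrees(np.arccos(np.clip(np.dot(ns, nb), -1, 1)))))
    return out[0], out[1]


def passes_angle_window(
    theta1: float | np.ndarray,
    theta3: float | np.ndarray,
    window: float = 30.0,
) -> bool | np.ndarray:
    """True iff BOTH angles lie in [0, window] or [180 - window, 180].

    The two-sided window accounts for the flip symmetry of the ring
    system and makes the result independent of the normal sign convention.
    """
    t1 = np.asarray(theta1, dtype=float)
    t3 = np.asarray(theta3, dtype=float)
    if np.any(t1 < 0) or np.any(t1 > 180) or np.any(t3 < 0) or np.any(t3 > 180):
        raise ValueError("angles must lie in [0, 180]")

    def ok(t):
        return (t <= window) | (t >= 180.0 - window)

    out = ok(t1) & ok(t3)
    return bool(out) if np.ndim(out) == 0 else out


def ring_com_distances(
    solute_coms: np.ndarray,
    slab_coms: np.ndarray,
    pairing: tuple[tuple[int, int], tuple[int, int]],
    box_lateral: np.ndarray | None = None,
) -> tuple[float, float]:
    """Euclidean distances of paired ring COMs (laterally minimum-imaged)."""
    out = []
    for si, bi in pairing:
        d = solute_coms[si] - slab_coms[bi]
        if box_lateral is not None:
            d = lateral_min_image(d, box_lateral)
        out.append(float(np.linalg.norm(d)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# selection ellipse
# ---------------------------------------------------------------------------

@dataclass
class SelectionEllipse:
    """Quadratic-form membership region fitted to a (d1, d3) distribution."""

    center: np.ndarray
    axes: np.ndarray       # semi-axis lengths, descending
    rotation: float        # radians, orientation of the major axis
    matrix: np.ndarray     # (x-c)^T M (x-c) <= 1 defines membership

    def contains(self, pts: np.ndarray) -> np.ndarray | bool:
        pts = np.asarray(pts, dtype=float)
        d = pts - self.center
        q = np.einsum("...i,ij,...j->...", d, self.matrix, d)
        out = q <= 1.0 + 1e-9
        return bool(out) if np.ndim(out) == 0 else out

    def to_dict(self) -> dict:
        return {
            "center": [float(x) for x in self.center],
            "axes": [float(x) for x in self.axes],
            "rotation": float(self.rotation),
            "matrix": [[float(x) for x in row] for row in self.matrix],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionEllipse":
        return cls(
            center=np.array(d["center"], dtype=float),
            axes=np.array(d["axes"], dtype=float),
            rotation=float(d["rotation"]),
            matrix=np.array(d["matrix"], dtype=float),
        )


def fit_selection_ellipse(
    d_samples: np.ndarray,
    fraction: float = 0.06,
    n_bins: int = 32,
) -> SelectionEllipse:
    """Fit the state-selection ellipse to the peak of a (d1, d3) cloud.

    A 2D histogram is built, the connected superlevel set of bins with
    count >= ``fraction`` x the maximum count containing the global
    maximum is extracted (8-connectivity, so satellite peaks stay
    excluded), and the smallest ellipse with the shape of the selected bin
    centres' second moments that covers all those centres is returned.

    ``fraction`` defaults to 0.06, the midpoint of the 5-7 % band used to
    delimit the peak.
    """
    d_samples = np.asarray(d_samples, dtype=float)
    if d_samples.size == 0:
        raise CrystalignError("cannot fit a selection ellipse to no samples")
    d_samples = d_samples.reshape(-1, 2)
    if d_samples.shape[0] < 100:
        warnings.warn(
            f"only {d_samples.shape[0]} samples for the selection ellipse; "
            "the peak estimate may be unstable"
        )
    lo = d_samples.min(axis=0)
    hi = d_samples.max(axis=0)
    degenerate = hi - lo < 1e-6  # floor guards all-identical samples
    span = np.maximum(hi - lo, 1e-6)
    lo = lo - 1e-9 * span - np.where(degenerate, span / 2, 0.0)
    hi = hi + 1e-9 * span + np.where(degenerate, span / 2, 0.0)
    counts, xe, ye = np.histogram2d(
        d_samples[:, 0], d_samples[:, 1], bins=n_bins, range=[(lo[0], hi[0]), (lo[1], hi[1])]
    )
    binw = np.array([xe[1] - xe[0], ye[1] - ye[0]])
    mask = counts >= fraction * counts.max()
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    peak = np.unravel_index(np.argmax(counts), counts.shape)
    comp = labels == labels[peak]
    ii, jj = np.nonzero(comp)
    centers = np.column_stack(
        [xe[:-1][ii] + binw[0] / 2, ye[:-1][jj] + binw[1] / 2]
    )
    center = centers.mean(axis=0)
    dev = centers - center
    cov = (dev.T @ dev) / max(len(centers), 1)
    # floor the shape at one bin so a single-bin peak still yields a region
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, binw.max() ** 2)  # minimum axis: one bin width
    cov = (evecs * evals) @ evecs.T
    cov_inv = np.linalg.inv(cov)
    scale2 = np.einsum("ni,ij,nj->n", dev, cov_inv, dev).max()
    scale2 = max(scale2, 1.0)
    matrix = cov_inv / scale2
    evals_m, evecs_m = np.linalg.eigh(matrix)
    axes = 1.0 / np.sqrt(evals_m[::-1])  # descending semi-axes
    major = evecs_m[:, np.argmin(evals_m)]
    rotation = float(np.arctan2(major[1], major[0]))
    return SelectionEllipse(
        center=center, axes=axes, rotation=rotation, matrix=matrix
    )


# ---------------------------------------------------------------------------
# bound / unbound split
# ---------------------------------------------------------------------------

def split_bound_unbound(
    cv: CVSeries,
    full_pmf,
    threshold: float = -0.9,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float] | None]:
    """Partition frames into bound / unbound sets around the PMF minimum.

    Bound frames have s inside the contiguous CV interval around the
    global PMF minimum where W < ``threshold`` (default -0.9 kJ/mol, which
    keeps bulk fluctuations out).  The interval is closed: frames exactly
    at its edges count as bound.  Returns boolean masks
    ``(bound, unbound)`` and the interval, or ``None`` if the PMF never
    dips below the threshold (then a warning is issued and no frame is
    bound).
    """
    vals = np.asarray(full_pmf.values, dtype=float)
    centers = np.asarray(full_pmf.bin_centers, dtype=float)
    below = np.isfinite(vals) & (vals < threshold)
    if not below.any():
        warnings.warn(
            f"PMF never drops below {threshold} kJ/mol: bound set is empty"
        )
        bound = np.zeros(len(cv), dtype=bool)
        return bound, ~bound, None
    imin = int(np.nanargmin(np.where(np.isfinite(vals), vals, np.inf)))
    lo = imin
    while lo - 1 >= 0 and below[lo - 1]:
        lo -= 1
    hi = imin
    while hi + 1 < len(vals) and below[hi + 1]:
        hi += 1
    half = (centers[1] - centers[0]) / 2.0
    s_lo, s_hi = float(centers[lo] - half), float(centers[hi] + half)
    bound = (cv.s >= s_lo) & (cv.s <= s_hi)
    return bound, ~bound, (s_lo, s_hi)


# ---------------------------------------------------------------------------
# full selection drivers
# ---------------------------------------------------------------------------

def slab_molecule_geometry(
    ref_xyz: np.ndarray,
    slab: SlabModel,
    rings_template: RingTopology,
    masses: np.ndarray,
    com_mode: str = "mass",
) -> dict:
    """Precompute per-molecule ring geometry of the restrained slab.

    Returns a dict with molecule COMs, ring COMs/normals and the
    intramolecular u (ring axis) and w (amide) vectors, all from the
    reference coordinates: the slab does not move.
    """
    n = len(slab.molecules)
    mol_coms = np.empty((n, 3))
    ring_coms = np.empty((n, 2, 3))
    ring_normals = np.empty((n, 2, 3))
    u = np.empty((n, 3))
    w = np.empty((n, 3))
    for m, atoms in enumerate(slab.molecules):
        mol_coms[m] = compute_com(ref_xyz, atoms, masses, com_mode)
        top = rings_template.for_atoms(atoms)
        (com_a, n_a), (com_b, n_b) = ring_frame(ref_xyz, top)
        ring_coms[m] = [com_a, com_b]
        ring_normals[m] = [n_a, n_b]
        u[m] = com_b - com_a
        w[m] = ref_xyz[top.amide[1]] - ref_xyz[top.amide[0]]
    return {
        "mol_coms": mol_coms,
        "ring_coms": ring_coms,
        "ring_normals": ring_normals,
        "u": u,
        "w": w,
    }


def _pair_and_measure(
    sol_coms: np.ndarray,
    sol_normals: np.ndarray,
    slab_coms: np.ndarray,
    slab_normals: np.ndarray,
    box_lateral: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ring pairing + angles + distances.

    All inputs broadcast over leading dimensions; ring axis is -2
    (length 2).  Returns (crossed, theta1, theta3, d1, d3) where
    ``crossed`` flags the crossed bijection, and lateral components
    (l1, l3) of the paired displacements are also returned via the last
    two entries of the tuple... kept separate for clarity below.
    """
    # displacement of each solute ring to each slab ring: (..., 2s, 2b, 3)
    d = sol_coms[..., :, None, :] - slab_coms[..., None, :, :]
    d = lateral_min_image(d, box_lateral)
    norms = np.linalg.norm(d, axis=-1)  # (..., 2, 2)
    cost_id = norms[..., 0, 0] + norms[..., 1, 1]
    cost_cr = norms[..., 0, 1] + norms[..., 1, 0]
    crossed = cost_cr < cost_id
    d1 = np.where(crossed, norms[..., 0, 1], norms[..., 0, 0])
    d3 = np.where(crossed, norms[..., 1, 0], norms[..., 1, 1])
    # lateral magnitudes of the paired displacements
    lat = np.linalg.norm(d[..., :2], axis=-1)  # (..., 2, 2)
    l1 = np.where(crossed, lat[..., 0, 1], lat[..., 0, 0])
    l3 = np.where(crossed, lat[..., 1, 0], lat[..., 1, 1])
    cosang = np.einsum(
        "...si,...bi->...sb", sol_normals, slab_normals
    ).clip(-1, 1)
    ang = np.degrees(np.arccos(cosang))  # (..., 2, 2)
    theta1 = np.where(crossed, ang[..., 0, 1], ang[..., 0, 0])
    theta3 = np.where(crossed, ang[..., 1, 0], ang[..., 1, 1])
    return crossed, theta1, theta3, d1, d3, l1, l3


def select_aligned(
    sol_ring_coms: np.ndarray,
    sol_ring_normals: np.ndarray,
    solute_coms: np.ndarray,
    frame_indices: np.ndarray,
    slab: SlabModel,
    slab_geom: dict,
    mode: str,
    angle_window: float = 30.0,
    ellipse: SelectionEllipse | None = None,
    extra_regions: list[SelectionEllipse] | None = None,
) -> pd.DataFrame:
    """Run the alignment criteria over a set of frames.

    ``mode="bound"`` tests each frame against the single reference-layer
    molecule under the solute; ``mode="unbound"`` tests against every
    surface-layer molecule (any match passes) with the distance criterion
    applied in lateral-register form: the paired displacement's lateral
    component l_k is mapped to an effective distance
    sqrt(d_z^2 + l_k^2) and tested against the bound-state ellipse.
    ``extra_regions`` whitelists additional (d1, d3) regions (used when
    alternate in-plane rotations are confirmed as growth states).

    When ``ellipse`` is None only the angle criterion is evaluated and
    ``ellipse_pass``/``aligned`` are left False (two-stage workflow: the
    ellipse is fitted to the angle-passing bound states first).
    """
    if mode not in ("bound", "unbound"):
        raise ValueError("mode must be 'bound' or 'unbound'")
    box = slab.box_lateral
    n = len(frame_indices)
    if mode == "bound":
        partner = reference_layer_molecule(
            solute_coms, slab, slab_geom["mol_coms"]
        )
        partner = np.atleast_1d(partner)
        b_coms = slab_geom["ring_coms"][partner]
        b_normals = slab_geom["ring_normals"][partner]
        crossed, t1, t3, d1, d3, l1, l3 = _pair_and_measure(
            sol_ring_coms, sol_ring_normals, b_coms, b_normals, box
        )
        angle_pass = passes_angle_window(t1, t3, angle_window)
        if ellipse is not None:
            pts = np.column_stack([d1, d3])
            ell = ellipse.contains(pts)
            if extra_regions:
                for reg in extra_regions:
                    ell |= reg.contains(pts)
            ellipse_pass = np.asarray(ell, dtype=bool)
            aligned = angle_pass & ellipse_pass
        else:
            ellipse_pass = np.zeros(n, dtype=bool)
            aligned = np.zeros(n, dtype=bool)
    else:
        surf = sorted(slab.surface_layer)
        b_coms = slab_geom["ring_coms"][surf]      # (m, 2, 3)
        b_normals = slab_geom["ring_normals"][surf]
        crossed_m, t1_m, t3_m, d1_m, d3_m, l1_m, l3_m = _pair_and_measure(
            sol_ring_coms[:, None], sol_ring_normals[:, None],
            b_coms[None], b_normals[None], box,
        )  # (n, m)
        ap_m = passes_angle_window(t1_m, t3_m, angle_window)
        if ellipse is not None:
            deff1 = np.hypot(slab.d_z, l1_m)
            deff3 = np.hypot(slab.d_z, l3_m)
            pts = np.stack([deff1, deff3], axis=-1)
            ep_m = np.asarray(ellipse.contains(pts), dtype=bool)
            if extra_regions:
                for reg in extra_regions:
                    ep_m |= np.asarray(reg.contains(pts), dtype=bool)
        else:
            ep_m = np.zeros_like(ap_m, dtype=bool)
        pass_m = ap_m & ep_m
        # report the best-matching partner: an (any-)passing one if present,
        # otherwise the laterally nearest by summed ring distance
        score = np.where(pass_m, -1.0, d1_m + d3_m)
        best = np.argmin(score, axis=1)
        rows = np.arange(n)
        partner = np.asarray(surf)[best]
        crossed = crossed_m[rows, best]
        t1, t3 = t1_m[rows, best], t3_m[rows, best]
        d1, d3 = d1_m[rows, best], d3_m[rows, best]
        angle_pass = ap_m.any(axis=1)
        ellipse_pass = ep_m.any(axis=1)
        aligned = pass_m.any(axis=1)
    return pd.DataFrame(
        {
            "frame_index": np.asarray(frame_indices, dtype=int),
            "partner": partner,
            "crossed_pairing": np.asarray(crossed, dtype=bool),
            "theta1": t1,
            "theta3": t3,
            "d1": d1,
            "d3": d3,
            "angle_pass": np.asarray(angle_pass, dtype=bool),
            "ellipse_pass": np.asarray(ellipse_pass, dtype=bool),
            "aligned": np.asarray(aligned, dtype=bool),
            "bound": mode == "bound",
        }
    )


# ---------------------------------------------------------------------------
# orientation mode
# ---------------------------------------------------------------------------

def classify_orientation_mode(
    u_solute: np.ndarray,
    w_solute: np.ndarray,
    u_partner: np.ndarray,
    w_partner: np.ndarray,
    aligned: bool | np.ndarray = True,
) -> str | np.ndarray:
    """Classify an aligned attachment into one of three orientation modes.

    With u the ring-axis vector (ring A COM -> ring B COM) and w the amide
    vector, compared against the partner molecule's primed vectors:

    - ``full``          u.u' > 0 and w.w' > 0 (all atoms aligned)
    - ``amide_rotated`` u.u' > 0 and w.w' < 0 (amide flipped 180 deg)
    - ``ring_flipped``  u.u' < 0 (symmetric ring system flipped; w ignored)
    """
    scalar = np.ndim(u_solute) == 1
    uu = np.einsum("...i,...i->...", u_solute, u_partner)
    ww = np.einsum("...i,...i->...", w_solute, w_partner)
    aligned_arr = np.broadcast_to(np.asarray(aligned, dtype=bool), np.shape(uu))
    if not np.all(aligned_arr):
        raise CrystalignError(
            "orientation mode is only defined for aligned records"
        )
    out = np.where(
        uu < 0,
        "ring_flipped",
        np.where(ww > 0, "full", "amide_rotated"),
    )
    return str(out) if scalar else out
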