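"""Collective variables and wall energies for a solute over a 2D-periodic slab.

The primary CV is the surface separation distance (SSD): the z-distance
between the solute's centre of mass and the slab's centre of mass, shifted
by half the slab depth so that s = 0 sits at the surface plane.  For slabs
whose relevant face is tilted in the simulation cell a minimum-distance
variant is provided: the minimum distance from the solute COM to any atom
of the first (surface) layer, minimum-imaged laterally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CrystalignError

__all__ = [
    "SlabModel",
    "WallSpec",
    "compute_com",
    "compute_ssd",
    "ssd_series",
    "compute_min_atom_cv",
    "wall_energy",
    "lateral_min_image",
]


@dataclass
class WallSpec:
    """One-sided polynomial wall ``k ((s - a)/s_i)^e`` beyond its onset ``a``.

    ``side="upper"`` acts for s > a, ``side="lower"`` mirrors it for s < a.
    """

    a: float
    k: float = 400_000.0
    e: float = 4.0
    s_i: float = 1.0
    side: str = "upper"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("wall energy constant k must be >= 0")
        if self.e < 1:
            raise ValueError("wall exponent must be >= 1")
        if self.s_i <= 0:
            raise ValueError("wall rescaling factor s_i must be > 0")
        if self.side not in ("upper", "lower"):
            raise ValueError("wall side must be 'upper' or 'lower'")


def wall_energy(s: np.ndarray | float, wall: WallSpec) -> np.ndarray | float:
    """Wall energy in kJ/mol; zero on the allowed side of the onset."""
    s = np.asarray(s, dtype=float)
    if wall.side == "upper":
        x = np.clip(s - wall.a, 0.0, None)
    else:
        x = np.clip(wall.a - s, 0.0, None)
    out = wall.k * (x / wall.s_i) ** wall.e
    return out if out.ndim else float(out)


def wall_force(s: float, wall: WallSpec) -> float:
    """-dU/ds of the wall at a scalar s (used by the toy integrator)."""
    if wall.side == "upper":
        x = s - wall.a
        if x <= 0.0:
            return 0.0
        return -wall.k * wall.e * (x / wall.s_i) ** (wall.e - 1.0) / wall.s_i
    x = wall.a - s
    if x <= 0.0:
        return 0.0
    return wall.k * wall.e * (x / wall.s_i) ** (wall.e - 1.0) / wall.s_i


@dataclass
class SlabModel:
    """Restrained crystal slab with layer and molecule bookkeeping.

    The slab COM and half-depth are computed once from the restrained
    reference coordinates (the slab is position-restrained, so per-frame
    recomputation would only add noise).  ``d_z`` is the repeat distance of
    the periodically repeating layer perpendicular to the surface — one
    layer spacing when successive layers share an orientation, two when
    they alternate.
    """

    molecules: list[np.ndarray]
    layer_of: np.ndarray
    reference_layer: list[int]
    surface_layer: list[int]
    slab_com_z: float
    half_depth: float
    d_z: float
    box_lateral: np.ndarray

    def __post_init__(self) -> None:
        self.layer_of = np.asarray(self.layer_of, dtype=int)
        self.box_lateral = np.asarray(self.box_lateral, dtype=float)
        if self.half_depth <= 0:
            raise ValueError("half_depth must be > 0")
        if self.d_z <= 0:
            raise ValueError("d_z must be > 0")
        if not self.reference_layer:
            raise ValueError("reference_layer must be non-empty")
        if len(self.layer_of) != len(self.molecules):
            raise ValueError("one layer assignment per molecule required")
        if self.box_lateral.shape != (2, 2):
            raise ValueError("box_lateral must be a 2x2 matrix")
        if np.linalg.det(self.box_lateral) <= 0:
            raise ValueError("lateral box must have positive area")

    @property
    def surface_z(self) -> float:
        """z of the nominal surface plane (slab COM + half depth)."""
        return self.slab_com_z + self.half_depth

    @classmethod
    def from_reference(
        cls,
        xyz: np.ndarray,
        masses: np.ndarray,
        molecules: list[np.ndarray],
        box_lateral: np.ndarray,
        layer_spacing: float,
        pattern: str = "stacked",
    ) -> "SlabModel":
        """Build a SlabModel from a reference frame.

        Molecules are assigned to layers by rounding their COM z to the
        nearest multiple of ``layer_spacing``.  ``pattern`` states which
        layer periodically repeats at a growing surface: ``"stacked"`` makes
        the first (top) layer the reference with repeat ``layer_spacing``;
        ``"alternating"`` makes it the second layer with repeat
        ``2 * layer_spacing``.
        """
        if pattern not in ("stacked", "alternating"):
            raise ValueError(f"unknown stacking pattern {pattern!r}")
        com_z = np.array(
            [compute_com(xyz, idx, masses)[2] for idx in molecules]
        )
        z0 = com_z.min()
        layer_raw = np.rint((com_z - z0) / layer_spacing).astype(int)
        # relabel so that layer 0 is the top (surface) layer
        layer_of = layer_raw.max() - layer_raw
        surface = [i for i, l in enumerate(layer_of) if l == 0]
        if pattern == "stacked":
            reference = surface
            d_z = layer_spacing
        else:
            reference = [i for i, l in enumerate(layer_of) if l == 1]
            d_z = 2.0 * layer_spacing
        slab_atoms = np.concatenate(molecules)
        w = masses[slab_atoms]
        slab_com_z = float(np.average(xyz[slab_atoms, 2], weights=w))
        zspan = xyz[slab_atoms, 2]
        half_depth = float((zspan.max() - zspan.min()) / 2.0)
        return cls(
            molecules=molecules,
            layer_of=layer_of,
            reference_layer=reference,
            surface_layer=surface,
            slab_com_z=slab_com_z,
            half_depth=half_depth,
            d_z=d_z,
            box_lateral=np.asarray(box_lateral, dtype=float),
        )


def compute_com(
    xyz: np.ndarray,
    atom_indices: np.ndarray,
    masses: np.ndarray,
    mode: str = "mass",
) -> np.ndarray:
    """Centre of mass of a selection; mass-weighted by default.

    ``xyz`` may be a single frame ``(n_atoms, 3)`` or a stack
    ``(n_frames, n_atoms, 3)``.
    """
    pos = xyz[..., atom_indices, :]
    if mode == "geometric":
        return pos.mean(axis=-2)
    w = masses[atom_indices]
    total = w.sum()
    if total <= 0:
        raise CrystalignError("zero total mass in COM selection")
    return np.tensordot(pos, w, axes=([-2], [0])) / total


def compute_ssd(
    xyz: np.ndarray,
    slab: SlabModel,
    solute_atoms: np.ndarray,
    masses: np.ndarray,
    com_mode: str = "mass",
) -> float | np.ndarray:
    """Surface separation distance of the solute for one frame (or a stack).

    s = z_com(solute) - z_com(slab) - half_depth, with the slab COM taken
    from the frame itself so the CV is invariant under whole-frame
    translations.  The half-depth stays fixed at its reference value (the
    slab is position-restrained; its extent does not evolve).  s may be
    negative for sub-surface excursions down to the lower wall.
    """
    z_sol = compute_com(xyz, solute_atoms, masses, com_mode)[..., 2]
    slab_atoms = np.concatenate(slab.molecules)
    z_slab = compute_com(xyz, slab_atoms, masses, com_mode)[..., 2]
    out = z_sol - z_slab - slab.half_depth
    return float(out) if np.ndim(out) == 0 else out


def ssd_series(bundle, slab: SlabModel, com_mode: str = "mass") -> np.ndarray:
    """SSD for every frame of a TrajectoryBundle (vectorized)."""
    return compute_ssd(
        bundle.xyz, slab, bundle.solute_atoms, bundle.masses, com_mode
    )


def lateral_min_image(dvec: np.ndarray, box_lateral: np.ndarray) -> np.ndarray:
    """Minimum-image the xy components of displacement vectors.

    Handles (possibly triclinic) lateral cells by explicit search over the
    nine nearest lattice shifts; z components are untouched (the slab
    region is not periodic in z).

    ``dvec``: (..., 3) displacement(s); returns the same shape.
    """
    dvec = np.array(dvec, dtype=float, copy=True)
    lat = dvec[..., :2]
    shifts = np.array(
        [
            i * box_lateral[0] + j * box_lateral[1]
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
        ]
    )  # (9, 2)
    cand = lat[..., None, :] - shifts  # (..., 9, 2)
    norms = np.einsum("...ki,...ki->...k", cand, cand)
    best = np.argmin(norms, axis=-1)
    dvec[..., :2] = np.take_along_axis(
        cand, best[..., None, None], axis=-2
    )[..., 0, :]
    return dvec


def compute_min_atom_cv(
    xyz: np.ndarray,
    slab: SlabModel,
    solute_atoms: np.ndarray,
    masses: np.ndarray,
    com_mode: str = "mass",
) -> float | np.ndarray:
    """Minimum-distance CV variant (used when the surface is tilted).

    Minimum over all first-layer (surface) atoms of the distance between
    the atom and the solute COM, minimum-imaged in the lateral directions.
    """
    if not slab.surface_layer:
        raise CrystalignError("slab has an empty surface layer")
    surf_atoms = np.concatenate(
        [slab.molecules[m] for m in slab.surface_layer]
    )
    com = compute_com(xyz, solute_atoms, masses, com_mode)  # (..., 3)
    pos = xyz[..., surf_atoms, :]  # (..., n_surf, 3)
    d = lateral_min_image(pos - com[..., None, :], slab.box_lateral)
    dist = np.sqrt(np.einsum("...i,...i->...", d, d)).min(axis=-1)
    return float(dist) if np.ndim(dist) == 0 else dist
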