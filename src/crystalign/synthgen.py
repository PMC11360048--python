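"""Ground-truth test systems: toy slab, biased 1D walker, orientation model.

The generator emulates the statistical structure of a converged biased
(metadynamics) simulation of one mobile solute over a restrained crystal
slab, at desk scale and with exact ground truth:

* a rigid planar two-ring molecule (two disjoint six-membered rings plus
  two amide-marker atoms) stacked on a rectangular lattice,
* an overdamped Langevin walker in the surface-separation CV ``s`` moving
  on a known adsorption well ``W_true(s)`` plus the accumulated Gaussian
  bias and the production-parameter wall potentials, with lateral free
  diffusion in the periodic cell,
* a z-dependent aligned-orientation probability: near the surface the
  solute adopts the lattice orientation (with small-angle noise and
  lateral registry), far from it orientations are uniform,
* a "prefilled" mode that initializes the bias to ``-W_true`` with
  deposition off — the stationary flat-sampling state a long deposition
  run converges to — so large samples are available cheaply.

Everything is emitted in the standard formats the pipeline reads (GRO +
XTC, COLVAR table, PLUMED grid file) plus a ground-truth JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import mdtraj as md
import numpy as np
from scipy.spatial.transform import Rotation

from .alignment import RingTopology, SelectionEllipse, select_aligned, rings_geometry_series
from .colvar_geometry import SlabModel, WallSpec, wall_energy, wall_force
from .errors import ConvergenceError
from .trajio import KB, BiasGrid, CVSeries, TrajectoryBundle, write_bias_grid, write_colvar

__all__ = [
    "SynthParams",
    "GroundTruth",
    "ToySystem",
    "SynthRun",
    "build_toy_slab",
    "run_biased_walker",
    "sample_orientation",
    "sample_orientations",
    "alignment_probability_oracle",
]


@dataclass
class SynthParams:
    """Study conditions of a synthetic run.

    Metadynamics deposition (stride 200 steps, sigma 0.05 nm, height
    0.01 kJ/mol), the wall potentials (onsets 1.5 / -0.5 nm, k = 400000
    kJ/mol, exponent 4, rescale 1 nm), the 1000-bin bias grid and the
    300 K temperature follow the production setup this generator
    emulates.  The frame spacing is dt = 0.002 ps with every step saved,
    so 1000 frames span 2 ps.
    """

    # lattice
    nx: int = 3
    ny: int = 3
    nz: int = 2
    a_x: float = 0.7
    a_y: float = 0.7
    layer_spacing: float = 0.5
    pattern: str = "stacked"          # or "alternating"
    # adsorption well: truncated Gaussian of the given depth and width,
    # shifted to reach exactly zero at center +- well_cut * width, flanked
    # by small positive barriers (the desolvation shoulder typical of
    # adsorption PMFs, and sub-surface repulsion) so the PMF crosses zero
    # with finite slope on both sides
    well_depth: float = 12.0
    well_center: float = 0.5
    well_width: float = 0.12
    well_cut: float = 2.5
    barrier_out: float = 2.0          # kJ/mol, shoulder on the solution side
    barrier_sub: float = 3.0          # kJ/mol, sub-surface repulsion
    barrier_offset: float = 0.35      # nm from the well centre
    barrier_width: float = 0.1        # nm
    # orientation model
    p_surf: float = 0.2
    p_bulk: float = 0.05
    kappa: float = 300.0              # noise concentration; angle std = kappa**-0.5
    registry_sigma: float = 0.04      # nm, lateral registry noise of aligned bound states
    mode_probs: tuple[float, float, float] = (0.6, 0.25, 0.15)
    switch_width: float = 0.1         # nm, sigmoid width of the well-edge switch
    bound_threshold: float = -0.9     # kJ/mol, defines the switch location
    # dynamics
    n_steps: int = 4_000_000
    dt: float = 0.00025               # ps
    save_stride: int = 8              # frame spacing 2 fs: 1000 frames = 2 ps
    friction: float = 5.0             # kJ ps mol^-1 nm^-2; D = kT / friction
    temperature: float = 300.0
    s_start: float = 1.0
    seed: int = 0
    # metadynamics
    meta_stride: int = 200
    meta_sigma: float = 0.05
    meta_height: float = 0.01
    prefill: bool = False             # sample the converged stationary state:
                                      # bias = -W_true, deposition frozen
    # walls and grid
    wall_upper: WallSpec = field(default_factory=lambda: WallSpec(a=1.5, side="upper"))
    wall_lower: WallSpec = field(default_factory=lambda: WallSpec(a=-0.5, side="lower"))
    grid_min: float = -0.5
    grid_max: float = 1.5
    grid_bins: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bulk <= self.p_surf <= 1.0:
            raise ValueError("require 0 <= p_bulk <= p_surf <= 1")
        if self.well_depth <= 0 or self.layer_spacing <= 0:
            raise ValueError("well depth and layer spacing must be positive")
        if self.pattern not in ("stacked", "alternating"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if abs(sum(self.mode_probs) - 1.0) > 1e-9:
            raise ValueError("mode_probs must sum to 1")

    # -- ground-truth functions ------------------------------------------
    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def diffusion(self) -> float:
        return self.kT / self.friction

    @property
    def _well_floor(self) -> float:
        return math.exp(-self.well_cut**2 / 2.0)

    @property
    def _well_amp(self) -> float:
        return self.well_depth / (1.0 - self._well_floor)

    @property
    def well_range(self) -> tuple[float, float]:
        """Interval where the true well is (strictly inside) below zero."""
        half = self.well_cut * self.well_width
        return self.well_center - half, self.well_center + half

    @property
    def well_edge(self) -> float:
        """Outer s where the well crosses the bound threshold (the well
        centre itself for wells shallower than the threshold)."""
        target = self._well_floor + abs(self.bound_threshold) / self._well_amp
        if target >= 1.0:
            return self.well_center
        return self.well_center + self.well_width * math.sqrt(
            -2.0 * math.log(target)
        )

    def w_true(self, s):
        """True adsorption profile: truncated-Gaussian well plus barriers."""
        s = np.asarray(s, dtype=float)
        u2 = ((s - self.well_center) / self.well_width) ** 2
        out = np.where(
            u2 < self.well_cut**2,
            -self._well_amp * (np.exp(-u2 / 2.0) - self._well_floor),
            0.0,
        )
        for height, center in (
            (self.barrier_out, self.well_center + self.barrier_offset),
            (self.barrier_sub, self.well_center - self.barrier_offset),
        ):
            out = out + height * np.exp(
                -((s - center) ** 2) / (2.0 * self.barrier_width**2)
            )
        return float(out) if out.ndim == 0 else out

    def w_true_force(self, s: float) -> float:
        """-dW_true/ds at scalar s."""
        u = (s - self.well_center) / self.well_width
        f = 0.0
        if abs(u) < self.well_cut:
            f = -self._well_amp * u * math.exp(-u * u / 2.0) / self.well_width
        for height, center in (
            (self.barrier_out, self.well_center + self.barrier_offset),
            (self.barrier_sub, self.well_center - self.barrier_offset),
        ):
            x = s - center
            f += height * x / self.barrier_width**2 * math.exp(
                -x * x / (2.0 * self.barrier_width**2)
            )
        return f

    def switch(self, s):
        """Smooth surface switch: 1 in the well, 0 in the bulk."""
        return 1.0 / (1.0 + np.exp((np.asarray(s, dtype=float) - self.well_edge) / self.switch_width))

    def p_align(self, s):
        return self.p_bulk + (self.p_surf - self.p_bulk) * self.switch(s)


# ---------------------------------------------------------------------------
# toy molecule and slab
# ---------------------------------------------------------------------------

def molecule_template() -> tuple[np.ndarray, list[str], RingTopology]:
    """Rigid two-ring template, COM-centred, lying in the xy-plane.

    Atoms 0-5: ring A (counter-clockwise, so the topology-order normal is
    +z); atoms 6-11: ring B; atoms 12-13: amide markers (N, O) slightly
    out of plane, their difference defining the amide vector w (+y-ish).
    The ring-axis vector u runs ring A -> ring B (+x).
    """
    r = 0.1
    coords = []
    for cx in (-0.25, 0.25):
        for k in range(6):
            ang = math.radians(60 * k)
            coords.append([cx + r * math.cos(ang), r * math.sin(ang), 0.0])
    coords.append([0.0, 0.18, 0.04])   # amide N
    coords.append([0.0, 0.28, 0.10])   # amide O
    coords = np.array(coords)
    elements = ["C"] * 12 + ["N", "O"]
    masses = np.array(
        [md.element.carbon.mass] * 12
        + [md.element.nitrogen.mass, md.element.oxygen.mass]
    )
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    coords = coords - com
    rings = RingTopology(
        ring_a=np.arange(6),
        ring_b=np.arange(6, 12),
        amide=np.array([12, 13]),
        axis=np.array([3, 6]),
    )
    return coords, elements, rings


@dataclass
class ToySystem:
    """A built toy slab + solute: topology, reference coordinates, lattice."""

    params: SynthParams
    topology: md.Topology
    ref_xyz: np.ndarray
    slab: SlabModel
    rings_template: RingTopology
    solute_atoms: np.ndarray
    masses: np.ndarray
    template: np.ndarray
    lattice_sites: np.ndarray          # (n_sites, 2) lateral positions, surface layer
    box: np.ndarray                    # (3, 3) box vectors
    base_rotation: np.ndarray          # lattice orientation of a new growth molecule

    @property
    def surface_plane_z(self) -> float:
        return self.slab.surface_z

    def solute_coords(self, rotations: np.ndarray, centers: np.ndarray) -> np.ndarray:
        """Place the rigid solute: (n, 3, 3) rotations, (n, 3) COM centres."""
        return np.einsum("nij,aj->nai", rotations, self.template) + centers[:, None, :]

    def nearest_site(self, xy: np.ndarray) -> np.ndarray:
        """Nearest lattice site (minimum-image) for (n, 2) lateral positions."""
        p = self.params
        lx, ly = p.nx * p.a_x, p.ny * p.a_y
        d = xy[:, None, :] - self.lattice_sites[None, :, :]
        d[..., 0] -= lx * np.round(d[..., 0] / lx)
        d[..., 1] -= ly * np.round(d[..., 1] / ly)
        best = np.argmin((d**2).sum(axis=-1), axis=1)
        return self.lattice_sites[best]


def build_toy_slab(params: SynthParams) -> ToySystem:
    """Build the rigid toy crystal slab plus one solute molecule.

    Layers stack along z at ``layer_spacing``; with the ``alternating``
    pattern every other layer is rotated 180 deg about z, the reference
    layer is the second from the top and the periodic repeat is two
    layers.  The solute is an identical molecule, initially in the bulk.
    """
    p = params
    if p.nx * p.ny * p.nz < 1:
        raise ValueError("lattice must contain at least one molecule")
    template, elements, rings = molecule_template()
    z_base = 0.5
    flip = Rotation.from_euler("z", 180, degrees=True).as_matrix()
    coords = []
    mol_meta = []  # (layer_from_top, site_xy)
    sites = []
    for l in range(p.nz):             # l = 0 bottom ... nz-1 top
        dl = (p.nz - 1) - l           # distance from top
        rot = np.eye(3)
        if p.pattern == "alternating" and dl % 2 == 1:
            rot = flip
        z = z_base + l * p.layer_spacing
        for i in range(p.nx):
            for j in range(p.ny):
                cx, cy = (i + 0.5) * p.a_x, (j + 0.5) * p.a_y
                coords.append(template @ rot.T + np.array([cx, cy, z]))
                mol_meta.append(dl)
                if dl == 0:
                    sites.append([cx, cy])
    n_slab = len(coords)
    # solute starts in the bulk above the surface
    z_top = z_base + (p.nz - 1) * p.layer_spacing
    coords.append(template + np.array([0.5 * p.nx * p.a_x, 0.5 * p.ny * p.a_y,
                                       z_top + p.s_start]))
    xyz = np.concatenate(coords, axis=0)

    top = md.Topology()
    chain = top.add_chain()
    elem = {"C": md.element.carbon, "N": md.element.nitrogen, "O": md.element.oxygen}
    for m in range(n_slab + 1):
        resname = "SLB" if m < n_slab else "MOL"
        res = top.add_residue(resname, chain)
        for a, e in enumerate(elements):
            top.add_atom(f"{e}{a + 1}", elem[e], res)

    n_at = template.shape[0]
    molecules = [np.arange(m * n_at, (m + 1) * n_at) for m in range(n_slab)]
    solute_atoms = np.arange(n_slab * n_at, (n_slab + 1) * n_at)
    masses = np.array([a.element.mass for a in top.atoms])
    box = np.diag(
        [p.nx * p.a_x, p.ny * p.a_y,
         z_top + p.wall_upper.a + 1.0]
    )
    slab = SlabModel.from_reference(
        xyz, masses, molecules, box[:2, :2], p.layer_spacing, p.pattern
    )
    # orientation a new growth molecule would adopt: continues the pattern,
    # i.e. matches the reference layer
    base_rot = flip if p.pattern == "alternating" else np.eye(3)
    return ToySystem(
        params=p,
        topology=top,
        ref_xyz=xyz,
        slab=slab,
        rings_template=rings,
        solute_atoms=solute_atoms,
        masses=masses,
        template=template,
        lattice_sites=np.array(sites),
        box=box,
        base_rotation=base_rot,
    )


# ---------------------------------------------------------------------------
# orientation sampling
# ---------------------------------------------------------------------------

def _uniform_rotations(n: int, rng: np.random.Generator) -> Rotation:
    """Uniform random rotations from normalized 4D Gaussians."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q)


_MODE_FLIPS = {
    "full": np.eye(3),
    # 180 deg about the ring axis (x): u kept, amide vector flipped
    "amide_rotated": Rotation.from_euler("x", 180, degrees=True).as_matrix(),
    # 180 deg about the plane normal (z): ring system flipped
    "ring_flipped": Rotation.from_euler("z", 180, degrees=True).as_matrix(),
}
_MODES = ("full", "amide_rotated", "ring_flipped")


def sample_orientations(
    s: np.ndarray,
    params: SynthParams,
    rng: np.random.Generator,
    base_rotation: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-frame solute orientations for CV values ``s``.

    With probability ``p_align(s)`` the orientation is the lattice
    orientation composed with one of the three attachment modes and
    small-angle noise of concentration ``kappa``; otherwise it is a
    uniform random rotation.  Returns ``(rotations (n,3,3), aligned,
    registry, mode_index)`` where ``registry`` marks aligned draws that
    additionally snap into lateral lattice register (probability =
    surface switch) and ``mode_index`` is -1 for non-aligned frames.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    n = len(s)
    base = np.eye(3) if base_rotation is None else base_rotation
    aligned = rng.random(n) < params.p_align(s)
    registry = aligned & (rng.random(n) < params.switch(s))
    mode_idx = np.where(
        aligned, rng.choice(3, size=n, p=list(params.mode_probs)), -1
    )
    rots = _uniform_rotations(n, rng).as_matrix()
    # small-angle noise: random axis, normal angle with std kappa**-1/2
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.normal(scale=params.kappa**-0.5, size=n)
    noise = Rotation.from_rotvec(axes * angles[:, None]).as_matrix()
    for k, name in enumerate(_MODES):
        sel = mode_idx == k
        if sel.any():
            rots[sel] = noise[sel] @ (base @ _MODE_FLIPS[name])[None]
    return rots, aligned, registry, mode_idx


def sample_orientation(
    s: float, params: SynthParams, rng: np.random.Generator,
    base_rotation: np.ndarray | None = None,
) -> np.ndarray:
    """Single-frame convenience wrapper around :func:`sample_orientations`."""
    return sample_orientations(np.array([s]), params, rng, base_rotation)[0][0]


# ---------------------------------------------------------------------------
# biased walker
# ---------------------------------------------------------------------------

def _run_walker_1d(
    params: SynthParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Overdamped Langevin in s with Gaussian deposition; returns
    (saved s values, bias grid values, bias value at s per saved frame)."""
    p = params
    nodes = np.linspace(p.grid_min, p.grid_max, p.grid_bins + 1)
    ds_grid = nodes[1] - nodes[0]
    if p.prefill:
        bias = -p.w_true(nodes)
        # bias force = -dU_bias/ds = +dW_true/ds = -w_true_force
        bias_f = np.array([-p.w_true_force(x) for x in nodes])
    else:
        bias = np.zeros_like(nodes)
        bias_f = np.zeros_like(nodes)
    mobility_dt = p.diffusion / p.kT * p.dt
    noise_scale = math.sqrt(2.0 * p.diffusion * p.dt)
    noise = rng.normal(size=p.n_steps)
    n_saved = p.n_steps // p.save_stride
    s_saved = np.empty(n_saved)
    b_saved = np.empty(n_saved)
    s = p.s_start
    smin, smax = p.grid_min, p.grid_max
    nbins = p.grid_bins
    w_up, w_lo = p.wall_upper, p.wall_lower
    # prefill emulates the converged stationary state: bias held fixed
    h = 0.0 if p.prefill else p.meta_height
    sig2 = p.meta_sigma**2
    limit = 5.0 * p.meta_sigma
    k = 0
    for step in range(p.n_steps):
        if h > 0.0 and step % p.meta_stride == 0 and step > 0:
            g = h * np.exp(-((nodes - s) ** 2) / (2.0 * sig2))
            bias += g
            bias_f += (nodes - s) / sig2 * g
        # linear interpolation of the bias force (clamped to the grid)
        x = (s - smin) / ds_grid
        if x <= 0.0:
            fb = bias_f[0]
            bv = bias[0]
        elif x >= nbins:
            fb = bias_f[-1]
            bv = bias[-1]
        else:
            i0 = int(x)
            frac = x - i0
            fb = bias_f[i0] * (1.0 - frac) + bias_f[i0 + 1] * frac
            bv = bias[i0] * (1.0 - frac) + bias[i0 + 1] * frac
        f = p.w_true_force(s) + fb + wall_force(s, w_up) + wall_force(s, w_lo)
        delta = mobility_dt * f + noise_scale * noise[step]
        if abs(delta) > limit:
            raise ConvergenceError(
                f"step displacement {delta:.3f} nm exceeds {limit:.2f} nm at "
                f"step {step}; use a smaller dt"
            )
        s += delta
        if (step + 1) % p.save_stride == 0:
            s_saved[k] = s
            b_saved[k] = bv
            k += 1
    return s_saved, bias, b_saved


@dataclass
class GroundTruth:
    """What the generator knows exactly about its own run."""

    params: SynthParams
    dG_ads_true: float
    q_uniform: float | None = None
    q_uniform_se: float | None = None

    def w_true(self, s):
        return self.params.w_true(s)

    def pmf_total(self, s):
        """True PMF of the sampled system: well plus wall potentials."""
        return (
            self.params.w_true(s)
            + wall_energy(s, self.params.wall_upper)
            + wall_energy(s, self.params.wall_lower)
        )

    def p_align(self, s):
        return self.params.p_align(s)

    def to_dict(self) -> dict:
        d = {
            "dG_ads_true": self.dG_ads_true,
            "q_uniform": self.q_uniform,
            "q_uniform_se": self.q_uniform_se,
            "well_depth": self.params.well_depth,
            "well_center": self.params.well_center,
            "well_width": self.params.well_width,
            "p_surf": self.params.p_surf,
            "p_bulk": self.params.p_bulk,
            "temperature": self.params.temperature,
            "seed": self.params.seed,
        }
        return d


def _true_free_energy(params: SynthParams, n_quad: int = 20001) -> float:
    """Closed-form (high-resolution quadrature) dG of the true well.

    Same convention as the pipeline: Boltzmann integral of exp(-W/kT)
    over the contiguous below-zero region, free-layer thickness equal to
    the bound-layer thickness.
    """
    p = params
    s = np.linspace(p.grid_min, p.grid_max, n_quad)
    w = p.w_true(s)
    imin = int(np.argmin(w))
    below = w < 0
    lo = imin
    while lo - 1 >= 0 and below[lo - 1]:
        lo -= 1
    hi = imin
    while hi + 1 < len(s) and below[hi + 1]:
        hi += 1
    sel = slice(lo, hi + 1)
    i_b = np.trapezoid(np.exp(-w[sel] / p.kT), s[sel])
    z = s[hi] - s[lo]
    return float(-p.kT * math.log(i_b / z))


@dataclass
class SynthRun:
    """Output bundle of one synthetic biased run (plus exact truth)."""

    system: ToySystem
    cv: CVSeries
    bias: BiasGrid
    truth: GroundTruth
    positions: np.ndarray         # (n, 3) solute COM per saved frame
    rotations: np.ndarray         # (n, 3, 3)
    aligned_truth: np.ndarray
    registry_truth: np.ndarray
    mode_truth: np.ndarray

    def iter_coords(self, chunk: int = 20000):
        """Yield synthesized full-system coordinate chunks (n, n_atoms, 3)."""
        sys = self.system
        n = len(self.positions)
        n_at = sys.ref_xyz.shape[0]
        for start in range(0, n, chunk):
            end = min(start + chunk, n)
            sol = sys.solute_coords(
                self.rotations[start:end], self.positions[start:end]
            )
            xyz = np.empty((end - start, n_at, 3), dtype=np.float32)
            xyz[:] = sys.ref_xyz[None]
            xyz[:, sys.solute_atoms, :] = sol
            yield start, xyz

    def bundle(self) -> TrajectoryBundle:
        """In-memory TrajectoryBundle of the synthesized trajectory."""
        sys = self.system
        xyz = np.concatenate([c for _, c in self.iter_coords()], axis=0)
        traj = md.Trajectory(
            xyz,
            sys.topology,
            unitcell_lengths=np.tile(np.diag(sys.box), (len(xyz), 1)),
            unitcell_angles=np.full((len(xyz), 3), 90.0),
        )
        return TrajectoryBundle(traj)

    def emit(self, outdir: str | Path) -> dict[str, Path]:
        """Write GRO + XTC + COLVAR + bias grid + ground-truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sys = self.system
        paths = {
            "top": outdir / "system.gro",
            "traj": outdir / "traj.xtc",
            "colvar": outdir / "COLVAR",
            "bias": outdir / "bias.grid",
            "truth": outdir / "truth.json",
        }
        ref = md.Trajectory(
            sys.ref_xyz[None].astype(np.float32),
            sys.topology,
            unitcell_lengths=np.diag(sys.box)[None],
            unitcell_angles=np.full((1, 3), 90.0),
        )
        ref.save_gro(str(paths["top"]))
        lengths = np.diag(sys.box).astype(np.float32)
        boxmat = np.diag(lengths)
        with md.formats.XTCTrajectoryFile(str(paths["traj"]), "w") as xtc:
            for start, xyz in self.iter_coords():
                n = len(xyz)
                xtc.write(
                    xyz,
                    time=self.cv.time[start : start + n].astype(np.float32),
                    box=np.tile(boxmat, (n, 1, 1)),
                )
        write_colvar(self.cv, paths["colvar"])
        write_bias_grid(self.bias, paths["bias"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth.to_dict(), fh, indent=2)
            fh.write("\n")
        return paths


def run_biased_walker(
    params: SynthParams,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> SynthRun:
    """Run the toy biased simulation and synthesize the trajectory.

    One integer seed drives every random stream (walker noise, lateral
    diffusion, orientation draws); rerunning with the same seed is
    bit-identical.  If ``outdir`` is given the standard-format artifacts
    are written there as well.
    """
    p = params if seed is None else SynthParams(**{**asdict(params), "seed": seed,
        "wall_upper": params.wall_upper, "wall_lower": params.wall_lower})
    rng = np.random.default_rng(p.seed)
    system = build_toy_slab(p)
    s_saved, bias_vals, b_saved = _run_walker_1d(p, rng)
    n = len(s_saved)
    times = (np.arange(n) + 1) * p.dt * p.save_stride
    cv = CVSeries(time=times, s=s_saved, bias_at_s=b_saved)
    bias = BiasGrid(
        s_min=p.grid_min, s_max=p.grid_max, n_bins=p.grid_bins,
        values=bias_vals, periodic=False,
    )
    # lateral free diffusion over the full step sequence, sampled at saves
    lx, ly = p.nx * p.a_x, p.ny * p.a_y
    step_scale = math.sqrt(2.0 * p.diffusion * p.dt * p.save_stride)
    xy = np.cumsum(rng.normal(scale=step_scale, size=(n, 2)), axis=0)
    xy += np.array([lx / 2, ly / 2])
    xy[:, 0] %= lx
    xy[:, 1] %= ly
    rots, aligned, registry, mode_idx = sample_orientations(
        s_saved, p, rng, system.base_rotation
    )
    if registry.any():
        sites = system.nearest_site(xy[registry])
        xy[registry] = (
            sites + rng.normal(scale=p.registry_sigma, size=sites.shape)
        )
        xy[registry, 0] %= lx
        xy[registry, 1] %= ly
    positions = np.column_stack(
        [xy, system.surface_plane_z + s_saved]
    )
    truth = GroundTruth(params=p, dG_ads_true=_true_free_energy(p))
    run = SynthRun(
        system=system, cv=cv, bias=bias, truth=truth,
        positions=positions, rotations=rots,
        aligned_truth=aligned, registry_truth=registry, mode_truth=mode_idx,
    )
    if outdir is not None:
        run.emit(outdir)
    return run


# ---------------------------------------------------------------------------
# Monte-Carlo oracles
# ---------------------------------------------------------------------------

def alignment_probability_oracle(
    n_samples: int,
    window: float = 30.0,
    seed: int = 0,
    system: ToySystem | None = None,
) -> tuple[float, float]:
    """Acceptance of the angle window under uniform random orientations.

    Draws uniform rotations of the solute template, runs the full angle
    pipeline (ring geometry -> ring pairing -> plane angles -> window)
    against a reference molecule, and returns the acceptance fraction
    with its binomial standard error.
    """
    if n_samples < 10_000:
        raise ValueError("oracle requires at least 1e4 samples")
    if system is None:
        system = build_toy_slab(SynthParams())
    rng = np.random.default_rng(seed)
    ref = system.slab.reference_layer[0]
    ref_atoms = system.slab.molecules[ref]
    n_hits = 0
    chunk = 100_000
    for start in range(0, n_samples, chunk):
        m = min(chunk, n_samples - start)
        rots = _uniform_rotations(m, rng).as_matrix()
        site = system.ref_xyz[ref_atoms].mean(axis=0) + np.array(
            [0.0, 0.0, system.slab.d_z]
        )
        sol = np.einsum("nij,aj->nai", rots, system.template) + site
        df = select_aligned(
            *rings_geometry_series(sol, system.rings_template),
            solute_coms=np.tile(site, (m, 1)),
            frame_indices=np.arange(m),
            slab=system.slab,
            slab_geom=_slab_geom(system),
            mode="bound",
            angle_window=window,
            ellipse=None,
        )
        n_hits += int(df["angle_pass"].sum())
    q = n_hits / n_samples
    se = math.sqrt(max(q * (1 - q), 1e-12) / n_samples)
    return q, se


def _slab_geom(system: ToySystem) -> dict:
    from .alignment import slab_molecule_geometry

    return slab_molecule_geometry(
        system.ref_xyz, system.slab, system.rings_template, system.masses
    )


def bulk_aligned_fraction_oracle(
    system: ToySystem,
    ellipse: SelectionEllipse,
    s_window: tuple[float, float],
    n_samples: int = 200_000,
    seed: int = 0,
    angle_window: float = 30.0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the bulk aligned-state fraction.

    Independently of any trajectory, draws bulk frames — s uniform over
    the entropy window, lateral position uniform over the cell,
    orientation from the generator's bulk mixture (aligned with
    probability p_align(s), else uniform rotation) — and measures the
    fraction passing the unbound selection.  The plateau of the rescaled
    PMF should equal -kT ln(fraction).
    """
    p = system.params
    rng = np.random.default_rng(seed)
    geom = _slab_geom(system)
    lx, ly = p.nx * p.a_x, p.ny * p.a_y
    n_hits = 0
    chunk = 100_000
    for start in range(0, n_samples, chunk):
        m = min(chunk, n_samples - start)
        s = rng.uniform(s_window[0], s_window[1], size=m)
        rots, _, _, _ = sample_orientations(s, p, rng, system.base_rotation)
        centers = np.column_stack(
            [
                rng.uniform(0, lx, size=m),
                rng.uniform(0, ly, size=m),
                system.surface_plane_z + s,
            ]
        )
        sol = system.solute_coords(rots, centers)
        coms, normals = rings_geometry_series(sol, system.rings_template)
        df = select_aligned(
            coms, normals, centers, np.arange(m),
            system.slab, geom, "unbound",
            angle_window=angle_window, ellipse=ellipse,
        )
        n_hits += int(df["aligned"].sum())
    f = n_hits / n_samples
    se = math.sqrt(max(f * (1 - f), 1e-12) / n_samples)
    return f, se
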