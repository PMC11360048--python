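"""Readers and writers for every external artifact the pipeline touches.

Covers PLUMED-style COLVAR tables and 1D bias-grid files, GRO/XTC (and
multi-model PDB) trajectories via mdtraj, and the CSV/JSON result reports.

Unit conventions throughout the package: lengths in nm, energies in kJ/mol,
times in ps, temperatures in K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Mapping, Sequence

import mdtraj as md
import numpy as np
import pandas as pd

from .errors import FormatError

if TYPE_CHECKING:  # pragma: no cover
    from .thermo import PMFProfile

#: Boltzmann constant in kJ mol^-1 K^-1 (GROMACS value).
KB = 0.0083144621


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CVSeries:
    """Per-frame collective-variable record of a biased trajectory.

    Parameters
    ----------
    time : ndarray
        Simulation time per frame (ps), strictly increasing.
    s : ndarray
        CV value per frame (nm, the surface separation distance or its
        minimum-distance variant).
    bias_at_s : ndarray, optional
        Instantaneous bias energy at ``s`` (kJ/mol), if the table carried it.
    frame_index : ndarray
        Ordinal frame index; both time and index are kept because block
        sizes may be quoted in either convention.
    """

    time: np.ndarray
    s: np.ndarray
    bias_at_s: np.ndarray | None = None
    frame_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.time.size == 0:
            raise FormatError("no frames in CV series")
        if self.time.shape != self.s.shape:
            raise FormatError("time and s must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise FormatError("time must be strictly increasing")
        if not np.all(np.isfinite(self.s)):
            raise FormatError("CV values must be finite")
        if self.bias_at_s is not None:
            self.bias_at_s = np.asarray(self.bias_at_s, dtype=float)
        if self.frame_index is None:
            self.frame_index = np.arange(self.time.size)
        else:
            self.frame_index = np.asarray(self.frame_index, dtype=int)

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_frames(self) -> int:
        return self.time.size


@dataclass
class BiasGrid:
    """Accumulated 1D metadynamics bias :math:`U_{bias}(s)` on a uniform grid.

    PLUMED writes non-periodic grids on ``n_bins + 1`` edge nodes spanning
    ``[s_min, s_max]`` and periodic grids on ``n_bins`` nodes; both dialects
    are accepted and the convention that was read is recorded in
    ``periodic``.  Between nodes the bias is evaluated by linear
    interpolation (grids are dense, typically 1000 bins over ~2 nm).
    """

    s_min: float
    s_max: float
    n_bins: int
    values: np.ndarray
    periodic: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.s_min < self.s_max:
            raise FormatError("bias grid requires s_min < s_max")
        if self.n_bins < 2:
            raise FormatError("bias grid requires n_bins >= 2")
        if self.values.shape != (self.n_nodes,):
            raise FormatError(
                f"bias grid declares {self.n_bins} bins "
                f"({self.n_nodes} nodes) but has {self.values.size} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("bias values must be finite")

    @property
    def n_nodes(self) -> int:
        return self.n_bins if self.periodic else self.n_bins + 1

    @property
    def nodes(self) -> np.ndarray:
        if self.periodic:
            return self.s_min + np.arange(self.n_bins) * (
                (self.s_max - self.s_min) / self.n_bins
            )
        return np.linspace(self.s_min, self.s_max, self.n_bins + 1)

    def evaluate(self, s: np.ndarray | float) -> np.ndarray | float:
        """Bias at arbitrary CV values (clamped beyond the grid range)."""
        return np.interp(s, self.nodes, self.values)


@dataclass
class ThermoResult:
    """Headline thermodynamic quantities of one analysis run.

    ``dG_ads`` integrates the full adsorption PMF, ``dG_r`` the rescaled
    (crystal-growth) PMF — over different curves and ranges, so no ordering
    between the two is implied.  ``minus_T_dS`` is the bulk plateau of the
    rescaled PMF, the orientational entropy penalty of aligning a freely
    rotating solute with the lattice; it is non-negative by construction.
    """

    dG_ads: float
    dG_ads_err: float
    dG_r: float
    dG_r_err: float
    minus_T_dS: float
    minus_T_dS_err: float
    temperature: float
    bound_range: tuple[float, float] | None

    def __post_init__(self) -> None:
        for name in ("dG_ads_err", "dG_r_err", "minus_T_dS_err"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        def _clean(x):
            if x is None:
                return None
            x = float(x)
            return x if np.isfinite(x) else None

        return {
            "dG_ads": _clean(self.dG_ads),
            "dG_ads_err": _clean(self.dG_ads_err),
            "dG_r": _clean(self.dG_r),
            "dG_r_err": _clean(self.dG_r_err),
            "minus_T_dS": _clean(self.minus_T_dS),
            "minus_T_dS_err": _clean(self.minus_T_dS_err),
            "temperature": float(self.temperature),
            "bound_range": (
                [float(self.bound_range[0]), float(self.bound_range[1])]
                if self.bound_range is not None
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThermoResult":
        def _num(x):
            return float("nan") if x is None else float(x)

        br = d.get("bound_range")
        return cls(
            dG_ads=_num(d["dG_ads"]),
            dG_ads_err=_num(d["dG_ads_err"]),
            dG_r=_num(d["dG_r"]),
            dG_r_err=_num(d["dG_r_err"]),
            minus_T_dS=_num(d["minus_T_dS"]),
            minus_T_dS_err=_num(d["minus_T_dS_err"]),
            temperature=float(d["temperature"]),
            bound_range=None if br is None else (float(br[0]), float(br[1])),
        )


class TrajectoryBundle:
    """A trajectory plus the topology bookkeeping the analysis needs.

    Distinguishes the single mobile solute molecule from the
    position-restrained slab molecules by residue name.  Coordinates are in
    nm with periodic box vectors; the lateral (xy) box is taken from the
    first frame since the slab is restrained.
    """

    def __init__(
        self,
        traj: md.Trajectory,
        solute_resname: str = "MOL",
        slab_resname: str = "SLB",
    ) -> None:
        self.traj = traj
        top = traj.topology
        solute = [r for r in top.residues if r.name == solute_resname]
        if len(solute) != 1:
            raise FormatError(
                f"topology must contain exactly one solute residue named "
                f"{solute_resname!r}, found {len(solute)}"
            )
        slab = [r for r in top.residues if r.name == slab_resname]
        if not slab:
            raise FormatError(f"no slab residues named {slab_resname!r}")
        self.solute_atoms = np.array([a.index for a in solute[0].atoms])
        self.slab_molecules = [
            np.array([a.index for a in r.atoms]) for r in slab
        ]
        self.masses = np.array([a.element.mass for a in top.atoms])
        if traj.unitcell_vectors is None:
            raise FormatError("trajectory lacks periodic box vectors")

    @property
    def topology(self) -> md.Topology:
        return self.traj.topology

    @property
    def n_frames(self) -> int:
        return self.traj.n_frames

    @property
    def xyz(self) -> np.ndarray:
        return self.traj.xyz

    @property
    def box_lateral(self) -> np.ndarray:
        """2x2 lateral box matrix (rows = a, b vectors' xy components)."""
        return np.asarray(self.traj.unitcell_vectors[0][:2, :2], dtype=float)

    def iter_chunks(self, chunk: int = 20000) -> Iterator[tuple[int, np.ndarray]]:
        """Yield ``(frame_offset, xyz_chunk)`` pairs."""
        for start in range(0, self.n_frames, chunk):
            yield start, self.traj.xyz[start : start + chunk]


# ---------------------------------------------------------------------------
# COLVAR tables
# ---------------------------------------------------------------------------

def read_colvar(
    path: str | Path,
    cv_field: str | None = None,
    bias_field: str | None = None,
) -> CVSeries:
    """Read a PLUMED COLVAR-style whitespace table.

    The first line must be a ``#! FIELDS`` header naming at least ``time``
    and one CV column.  ``#!`` continuation lines (``SET`` records) and
    ``#`` comments are skipped.  Columns are mapped by header name; by
    default the CV is the first non-time, non-bias field.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\r\n")
        if not first.startswith("#! FIELDS"):
            raise FormatError(f"{path}: missing '#! FIELDS' header")
        fields = first.split()[2:]
        if "time" not in fields:
            raise FormatError(f"{path}: header must name a 'time' column")
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != len(fields):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(fields)} columns, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})")
    if not rows:
        raise FormatError(f"{path}: no frames")
    data = np.array(rows)
    cols = {name: data[:, i] for i, name in enumerate(fields)}
    if bias_field is None:
        bias_candidates = [f for f in fields if f == "bias" or f.endswith(".bias")]
        bias_field = bias_candidates[0] if bias_candidates else None
    if cv_field is None:
        try:
            cv_field = next(
                f for f in fields if f != "time" and f != bias_field
            )
        except StopIteration:
            raise FormatError(f"{path}: no CV column in header")
    if cv_field not in cols:
        raise FormatError(f"{path}: no column named {cv_field!r}")
    return CVSeries(
        time=cols["time"],
        s=cols[cv_field],
        bias_at_s=cols.get(bias_field) if bias_field else None,
    )


def write_colvar(cv: CVSeries, path: str | Path, cv_name: str = "ssd") -> None:
    """Write a CVSeries as a PLUMED-style COLVAR table."""
    path = Path(path)
    fields = ["time", cv_name]
    cols = [cv.time, cv.s]
    if cv.bias_at_s is not None:
        fields.append("metad.bias")
        cols.append(cv.bias_at_s)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for row in zip(*cols):
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# PLUMED grid files
# ---------------------------------------------------------------------------

def read_bias_grid(path: str | Path) -> BiasGrid:
    """Read a 1D PLUMED grid file (``#! SET min_* / max_* / nbins_*``).

    Accepts both the non-periodic edge convention (``nbins + 1`` nodes) and
    the periodic convention (``nbins`` nodes); the one found is recorded in
    :attr:`BiasGrid.periodic`.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                parts = line.split()
                if parts[1] == "SET" and len(parts) >= 4:
                    meta[parts[2]] = parts[3]
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                values.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})")

    def _meta(prefix: str) -> str:
        for key, val in meta.items():
            if key.startswith(prefix):
                return val
        raise FormatError(f"{path}: missing '#! SET {prefix}*' header")

    s_min = float(_meta("min_"))
    s_max = float(_meta("max_"))
    n_bins = int(_meta("nbins_"))
    declared_periodic = _meta("periodic_").lower() in ("true", "1", "yes") \
        if any(k.startswith("periodic_") for k in meta) else None

    if len(values) == n_bins + 1:
        periodic = False
    elif len(values) == n_bins:
        periodic = True
    else:
        raise FormatError(
            f"{path}: grid declares nbins={n_bins} but contains "
            f"{len(values)} nodes"
        )
    if declared_periodic is not None and declared_periodic != periodic:
        raise FormatError(
            f"{path}: node count inconsistent with declared periodicity"
        )
    return BiasGrid(
        s_min=s_min, s_max=s_max, n_bins=n_bins,
        values=np.array(values), periodic=periodic,
    )


def write_bias_grid(grid: BiasGrid, path: str | Path, name: str = "ssd") -> None:
    """Write a BiasGrid in the PLUMED grid-file dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS {name} metad.bias\n")
        fh.write(f"#! SET min_{name} {grid.s_min!r}\n")
        fh.write(f"#! SET max_{name} {grid.s_max!r}\n")
        fh.write(f"#! SET nbins_{name} {grid.n_bins}\n")
        fh.write(f"#! SET periodic_{name} {'true' if grid.periodic else 'false'}\n")
        for s, v in zip(grid.nodes, grid.values):
            fh.write(f"{float(s)!r} {float(v)!r}\n")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def read_trajectory(
    traj_path: str | Path,
    top_path: str | Path | None = None,
    solute_resname: str = "MOL",
    slab_resname: str = "SLB",
) -> TrajectoryBundle:
    """Load a trajectory (XTC/DCD + GRO/PDB, or a standalone multi-model PDB).

    Coordinates are returned in nm.  The topology must identify exactly one
    solute molecule and at least one slab molecule by residue name.
    """
    traj_path = Path(traj_path)
    try:
        if top_path is None:
            traj = md.load(str(traj_path))
        else:
            traj = md.load(str(traj_path), top=str(top_path))
    except (ValueError, IOError) as exc:
        raise FormatError(f"failed to load trajectory: {exc}") from exc
    return TrajectoryBundle(traj, solute_resname, slab_resname)


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------

def write_results(
    result: ThermoResult,
    profiles: Mapping[str, "PMFProfile"],
    path: str | Path,
) -> None:
    """Write the analysis report: one CSV per profile plus a JSON summary.

    Undefined (empty-density) bins are serialized as explicit ``nan`` cells
    rather than dropped, so re-reading reproduces the profile exactly.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    grids = {tuple(np.round(p.bin_centers, 12)) for p in profiles.values()}
    if len(grids) > 1:
        raise ValueError("profiles passed to write_results must share one bin grid")
    for name, prof in profiles.items():
        df = pd.DataFrame(
            {
                "bin_center": prof.bin_centers,
                "value": prof.values,
                "error": prof.errors,
            }
        )
        df.to_csv(outdir / f"{name}.csv", index=False, na_rep="nan",
                  float_format="%.17g")
    summary = {"result": result.to_dict(), "profiles": sorted(profiles)}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")


def read_results(path: str | Path) -> tuple[ThermoResult, dict[str, "PMFProfile"]]:
    """Re-read a report directory written by :func:`write_results`."""
    from .thermo import PMFProfile  # local import avoids a cycle

    outdir = Path(path)
    with open(outdir / "summary.json") as fh:
        summary = json.load(fh)
    result = ThermoResult.from_dict(summary["result"])
    profiles = {}
    for name in summary["profiles"]:
        df = pd.read_csv(outdir / f"{name}.csv", float_precision="round_trip")
        profiles[name] = PMFProfile(
            bin_centers=df["bin_center"].to_numpy(),
            values=df["value"].to_numpy(),
            errors=df["error"].to_numpy(),
        )
    return result, profiles
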