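"""Run configuration: analysis thresholds and system description.

All thresholds live in a YAML-serializable dataclass so a run is fully
described by (trajectory, COLVAR, bias grid, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Analysis parameters (defaults follow the production protocol)."""

    temperature: float = 300.0          # K
    n_bins_density: int = 100           # bins of the state density / PMF
    bound_threshold: float = -0.9       # kJ/mol, bound/unbound split contour
    angle_window_deg: float = 30.0      # ring-plane alignment window
    ellipse_fraction: float = 0.06      # superlevel fraction (5-7 % band)
    ellipse_bins: int = 32              # histogram bins of the (d1,d3) cloud
    block_frames_bound: int = 1000      # block size, bound aligned states
    block_frames_unbound: int = 2000    # block size, solution aligned states
    anchor_fraction: float = 0.2        # outer fraction of CV range -> bulk zero
    anchor_window: tuple[float, float] | None = None
    entropy_window: tuple[float, float] | None = None
    rescale_form: str = "approx"        # or "exact" (keeps sampled rho)
    com_mode: str = "mass"              # or "geometric"
    # wall potentials limiting the CV
    wall_upper_a: float = 1.5
    wall_lower_a: float = -0.5
    wall_k: float = 400_000.0
    wall_e: float = 4.0
    wall_s_i: float = 1.0
    # system description for rebuilding the SlabModel from a topology
    solute_resname: str = "MOL"
    slab_resname: str = "SLB"
    pattern: str = "stacked"            # layer stacking: stacked | alternating
    layer_spacing: float = 0.5          # nm
    # ring topology, indices relative to the molecule's atom ordering;
    # None selects the built-in toy two-ring template
    rings: dict | None = None
    # whitelisted extra (d1,d3) regions counted as aligned (serialized
    # SelectionEllipse dicts), for confirmed alternate rotations
    extra_aligned_regions: list = field(default_factory=list)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("anchor_window", "entropy_window"):
            if d[key] is not None:
                d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("anchor_window", "entropy_window"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)
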