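# crystalign

Alignment-filtered PMF rescaling for crystal-growth thermodynamics.

Biased (metadynamics-style) simulations of a single solute over a
restrained crystal slab give the potential of mean force W(s) of
*adsorption* along the surface separation distance s — adsorption in any
orientation. Secondary nucleation, however, only proceeds through states
whose orientation continues the crystal lattice. `crystalign`
post-processes such a trajectory: it decides frame by frame whether the
solute's two six-membered ring planes are aligned (within 30°, i.e.
0–30° ∪ 150–180° because the ring system can flip) with the matching
rings of the periodically repeating slab molecule and whether the paired
ring centre-of-mass distances fall inside an ellipse fitted to the peak
of their distribution, and then rescales the PMF to the aligned states:

    W(s)   = −kT ln ϱ(s)   − U_bias(s)        (full adsorption PMF)
    W_r(s) = −kT ln ϱ_r(s) − U_bias(s)        (crystal-growth PMF)

ϱ_r is the aligned-state density normalized to all frames, so
W_r ≥ W everywhere; its bulk plateau is the orientational entropy
penalty −TΔS_r of bringing a freely rotating molecule into lattice
registry. Free energies integrate exp(−W/kT) over the contiguous
below-zero region around the PMF minimum (trapezoidal rule, free-layer
thickness = bound-layer thickness):

    ΔG = −kT ln( ∫_bound e^{−W(s)/kT} ds / Z_free )

The package reads PLUMED-style COLVAR tables and 1D bias-grid files,
GRO/XTC/DCD/multi-model-PDB trajectories (via mdtraj), and writes
CSV/JSON reports. A synthetic generator provides complete ground-truth
test systems: a toy two-ring crystal slab, an overdamped-Langevin walker
over a known adsorption well with Gaussian bias deposition and wall
potentials, and a z-dependent aligned-orientation model. `docs/methods.md`
describes the model, its assumptions and its limits.

## Worked example

Generate a synthetic converged run and analyse it:

```bash
crystalign synth --seed 17 --out data/ --n-steps 2000000 --prefill
crystalign rescale --traj data/traj.xtc --top data/system.gro \
    --colvar data/COLVAR --bias data/bias.grid \
    --config data/config.yml --out results/
crystalign report --in results/ --plot results/pmf.png
```

The rescale step prints (seed 17):

```
dG_ads     =    -8.47 +- 0.32 kJ/mol
dG_r       =    -6.23 +- 0.04 kJ/mol
-T dS_r    =     4.34 +- 0.17 kJ/mol
```

`dG_ads` is the adsorption free energy of the full PMF — the
generator's exact value for this well is −9.05 kJ/mol, recovered here
within two block standard errors. `dG_r` integrates the rescaled PMF
over its own bound region: the free energy of *aligned* attachment.
`-T dS_r` is the rescaled PMF's bulk plateau; an independent
Monte-Carlo oracle over the generator's orientation model gives
−kT ln(aligned fraction) = 4.33 kJ/mol for this system, matching well
within the error bar. The output
directory holds the binned profiles (`pmf_full.csv`, `pmf_rescaled.csv`,
display-only `pmf_bridge.csv`), the per-frame alignment records, the
fitted selection ellipse and sampling diagnostics (CV flatness,
covered-volume fraction).

For real data, point `--traj/--top/--colvar/--bias` at your own files
and describe the system in the YAML config (slab residue names, layer
spacing and stacking pattern, ring atom indices, thresholds — see
`crystalign.config.RunConfig`).

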