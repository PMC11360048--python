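# Methods

## The problem

A metadynamics (or otherwise flat-sampled) simulation of one solute
molecule over a position-restrained crystal slab yields the potential of
mean force (PMF) of *adsorption* along the surface separation distance
(SSD) — but adsorption in any orientation. Crystal growth requires the
molecule to attach in registry with the lattice. `crystalign` filters the
trajectory down to lattice-compatible states and rescales the PMF to
them, separating the crystal-growth free energy from the orientational
entropy penalty of alignment.

## Collective variables

The SSD is

    s = z_com(solute) − z_com(slab) − h/2,

with h the slab depth (extremal slab atom z-range in the reference
frame) and both COMs mass-weighted (a geometric option exists;
`com_mode`). The slab COM is evaluated per frame so the CV is invariant
under whole-frame translations; for a restrained slab this is identical
to using the reference value up to restraint noise. For slabs whose
relevant face is tilted in the box, the minimum-distance variant —
minimum over first-layer atoms of the distance to the solute COM,
minimum-imaged laterally — is provided instead of correcting the SSD.

Sampling is confined by one-sided wall potentials k((s−a)/s_i)^e with
k = 400 000 kJ/mol, e = 4, s_i = 1 nm and onsets a = 1.5 / −0.5 nm.

## PMF estimation and rescaling

From a converged run with accumulated bias U_bias(s),

    W(s)   = −kT ln ϱ(s)   − U_bias(s) + C,
    W_r(s) = −kT ln ϱ_r(s) − U_bias(s) + C,

where ϱ is the sampled CV distribution on 100 uniform bins, ϱ_r the
distribution of *aligned* states normalized to the total frame count,
and C anchors the bulk window of the full PMF to zero (the outermost
20 % of the CV range below the upper wall onset by default; the same C
is applied to W_r, whose bulk plateau is then −TΔS_r). The default form
drops ϱ from the rescaled estimator, which is exact when the biased
sampling is flat; `rescale_form: exact` keeps the sampled ratio
W_r = W − kT ln(ϱ_r/ϱ) instead. Zero-count bins are carried as
undefined (NaN), never ±∞. W_r ≥ W wherever both are defined, because
ϱ_r ≤ ϱ bin by bin.

## Alignment criteria

Bound states are the frames whose s lies in the contiguous interval
around the global PMF minimum where W < −0.9 kJ/mol (the margin keeps
bulk fluctuations out of the bound set); the interval is closed at its
edges. For each bound frame:

1. **Partner**: the reference-layer molecule whose COM is laterally
   closest (minimum-image) to the solute's z-projection. The reference
   layer is the one that periodically repeats at a growing surface — the
   first layer for simple stacking, deeper for alternating packings
   (`pattern` config key).
2. **Ring pairing**: both bijections between the solute's and the
   partner's two six-membered rings are scored by the summed length of
   the COM-connecting vectors v1, v2; the shorter assignment wins
   (identity preferred on exact ties). Ring "equivalence" everywhere
   downstream follows this pairing.
3. **Angles**: each paired pair of least-squares ring-plane normals must
   lie within 30° of parallel *or* antiparallel (0–30° ∪ 150–180°; the
   ring system can flip, and the two-sided window also makes the result
   independent of the normal sign convention).
4. **Distances**: the paired ring-COM distances (d1, d3) of the
   angle-passing bound states are histogrammed; the connected superlevel
   set of bins ≥ 6 % of the maximum (midpoint of the 5–7 % band)
   containing the global maximum is extracted with 8-connectivity, so
   satellite peaks are excluded; the smallest ellipse with the shape of
   the selected bin centres' second moments covering those centres is
   the membership region. Confirmed alternate rotations can be
   whitelisted as extra regions (`extra_aligned_regions`).

A bound frame is *aligned* iff it passes both the angle window and the
ellipse. Unbound frames are tested against **every** surface-layer
molecule and pass if any matches. Because far states cannot satisfy an
absolute 3D distance criterion, the ellipse is applied there in
lateral-register form: the lateral minimum-image component l_k of each
paired displacement is mapped to an effective distance
√(d_z² + l_k²) — the distance the state *would* have at the growth
height — and tested against the same ellipse. This preserves a
register criterion at arbitrary SSD while keeping the bound-state
ellipse the single source of truth.

Aligned attachments are classified by two intramolecular vectors
(u = ring-A→ring-B COM axis, w = the amide vector) against the
partner's: full alignment (u·u′>0, w·w′>0), amide rotated (u·u′>0,
w·w′<0), ring flipped (u·u′<0, w ignored). The exact atom pairs behind
u and w are configurable; the defaults are the toy template's.

## Free energies, entropy, errors

ΔG integrates exp(−W/kT) by the trapezoidal rule over the contiguous
below-zero interval around the global minimum, with the free-layer
thickness Z_free set equal to the bound-layer thickness ("excess"
adsorption convention): ΔG = −kT ln(I_b/Z_free). A square well of depth
w therefore returns exactly −w. ΔG_ads uses the full PMF, ΔG_r the
rescaled one; they integrate different curves over different ranges, so
no ordering between them is implied. −TΔS_r is the mean of the defined
W_r bins over the bulk window (defaults to the anchor window; it is
configurable because surfaces with longer-ranged influence need a
farther window). Undefined bins inside integration ranges are skipped
with a warning.

Errors come from block averaging: the trajectory is cut into contiguous
blocks (1000 frames for the full PMF and the bound aligned states, 2000
for the solution states by default), every density/PMF/scalar is
recomputed per block — with the per-block aligned densities renormalized
to the trajectory-wide convention — and the standard error of the mean
across blocks is reported per bin and per scalar. Blocks shorter than
the slowest density relaxation underestimate the error somewhat; the
recovery tests therefore compare against ground truth at three block
standard errors.

Between the bound region and the plateau the rescaled PMF mixes
orientational populations and is not quantitatively meaningful; for
plots only, a logarithmic bridge a + b ln(s − s0) connects the bound
edge to the plateau start. It is flagged display-only and never enters
any scalar.

## Synthetic ground truth

The generator (`synthgen`) exercises every analysis stage with exact
ground truth rather than reproducing any all-atom system:

* **Toy crystal**: a rigid planar two-ring molecule (two disjoint
  six-membered rings 0.5 nm apart — comparable to the ring separation of
  a dibenzazepine — plus two out-of-plane amide-marker atoms) on a
  rectangular lattice, 3×3×2 by default, layer spacing 0.5 nm, with
  `stacked` or `alternating` layer patterns.
* **Walker**: overdamped Langevin dynamics *in the CV itself*
  (dt = 0.25 fs, D = kT/friction ≈ 0.5 nm²/ps), on a known adsorption
  profile W_true — a truncated-Gaussian well (depth 12 kJ/mol, width
  0.12 nm at s = 0.5 nm) flanked by small positive barriers (2 and
  3 kJ/mol), the desolvation shoulder and sub-surface repulsion typical
  of adsorption PMFs, which also give the profile finite slope at its
  zero crossings — plus the accumulated Gaussian bias (deposited every
  200 steps, σ = 0.05 nm, height 0.01 kJ/mol, stored on a 1000-bin
  grid) and the walls. Coordinates are synthesized around the sampled s:
  lateral free diffusion with periodic wrap, frames saved every 2 fs.
  A step displacement beyond 5σ of the deposition width aborts with
  advice to reduce dt.
* **Converged ("prefill") mode** initializes the bias to −W_true and
  freezes deposition — the stationary flat-sampling state a long
  deposition run converges to — so large, exactly characterized samples
  are cheap. Active deposition is also implemented and fills a 10 kJ/mol
  well to within 1.5 kJ/mol in 10⁶ steps.
* **Orientations**: with probability p_align(s) = p_bulk +
  (p_surf − p_bulk)·σ_w(s) (sigmoid switch of width 0.1 nm at the
  well's bound-threshold edge; p_surf = 0.2, p_bulk = 0.05) the solute
  adopts the lattice orientation composed with one of the three
  attachment modes (probabilities 0.6/0.25/0.15) and small-angle noise
  (concentration κ = 300, ≈3°); aligned draws near the surface also
  snap into lateral lattice register (σ = 0.04 nm). Otherwise the
  orientation is uniform (Marsaglia quaternions). One integer seed
  drives all streams; reruns are bit-identical.

With these conditions roughly a quarter of the bound states is selected
as aligned — somewhat above the ≤16 % seen in production systems,
because the planar toy molecule's angle window alone accepts 13.4 % of
uniform orientations (= 1 − cos 30°, both rings sharing one plane) on
top of the deliberately generated aligned population.

What the generator does *not* emulate: solvent and energetic
orientation–position coupling (orientation is drawn independently per
frame given s), intramolecular flexibility, surface reconstruction, and
force-field physics. Passing tests therefore demonstrate the
correctness of the estimators and selection logic on data with the
assumed statistical structure, not force-field accuracy on real
crystals.

## Oracles and validation

* `alignment_probability_oracle`: uniform random rotations pushed
  through the full ring-geometry pipeline give the angle-window
  acceptance q (closed form 1 − cos(window) for the planar template).
* `bulk_aligned_fraction_oracle`: independent Monte-Carlo frames
  (uniform s in the bulk window, uniform lateral position, the
  generator's orientation mixture) are run through the unbound
  selection; the rescaled-PMF plateau must equal −kT ln(fraction).
* Recovery at reference scale (5×10⁵ frames): PMF RMSE ≈ 0.1–0.2
  kJ/mol against W_true + walls, ΔG_ads within three block-SE of the
  quadrature value of W_true, plateau within 0.1 kJ/mol of the oracle.

## Problem sizes

The test suite and the acceptance script use 2×10⁵–2×10⁶ walker steps
(2.5×10⁴–2.5×10⁵ frames) for end-to-end checks and 1.5×10⁷ steps
(5×10⁵ frames over 3.75 ns of toy dynamics) for the reference-scale
recovery and diagnostics runs; Monte-Carlo oracles use 2×10⁵–10⁶
samples. These sizes give the statistical margins quoted above.

## Numerical choices and edge cases

* k_B = 0.0083144621 kJ mol⁻¹ K⁻¹; nm / kJ/mol / ps / K throughout.
* Bias grids: linear interpolation between nodes, clamped outside the
  grid; both the edge (nbins+1 nodes) and periodic (nbins) PLUMED
  dialects are accepted and the one read is recorded.
* Lateral minimum-image uses explicit search over the nine nearest
  lattice shifts, valid for triclinic cells of reasonable aspect.
* Degenerate ellipse input (all samples identical) yields a minimal
  region one histogram bin wide containing the point; collinear ring
  atoms raise a degenerate-geometry error; an everywhere-positive PMF
  reports "no bound state" rather than a number.
* Ties: ring pairing prefers the identity assignment; nearest-molecule
  searches resolve to the lowest molecule id.
* Reports serialize undefined bins as explicit `nan` cells and round
  trip bit-exactly (`%.17g` on write, round-trip float parsing on
  read).

## Known limitations

* The unbound-mode lateral-register criterion is an interpretation; the
  bound-state procedure defines the method, and far-state selection
  only enters through the plateau, where the oracle validates it.
* Block errors underestimate when block sizes are shorter than the
  slowest sampling mode (see above); the block sizes are configurable.
* The below-zero integration range inherits edge jitter from PMF noise;
  profiles that approach zero with vanishing slope make ΔG sensitive to
  it (the synthetic profile's flanking barriers reflect how real
  adsorption PMFs avoid this).
* Only 1D CVs and two-ring solutes are supported; the ring topology is
  configurable but exactly two six-membered rings are assumed.
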