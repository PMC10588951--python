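# Methods

This note documents the models and procedures implemented in `scassembly`,
their assumptions, default parameters, and the design choices made where
the design was genuinely open.

## Scientific setting

The synaptonemal complex (SC) zips homologous chromosomes together during
meiotic prophase. Its transverse filament protein SYCP1 self-assembles at
the SC midline: opposing SYCP1 dimers meet head-to-head through the
N-terminal tip of the coiled-coil (the alphaN tip, human residues
101-111, within the alphaN end 101-175). Mouse numbering runs three lower
(98-172); the core interface residue is h.L109 = m.L106 and the more
peripheral one h.V105 = m.L102. Glutamate substitutions at these
positions weaken or destroy the head-to-head interface, and the package
provides desk-scale machinery to study the consequences in three arenas:
a steered-dissociation simulation assay, trajectory metrics, and
superresolution-style image quantification with its statistics.

## Coarse-grained steered dissociation assay (`cg_simulator`)

**Model.** Four chains of 75 beads (one bead per residue of the alphaN
end) form two parallel-chain dimers. Within a chain, consecutive beads
are joined by harmonic bonds (rest length 1.5 Å, the helical rise per
residue; stiffness 4 kT/Å<sup>2</sup>) and next-nearest neighbours by a
harmonic 1-3 term (rest 3 Å, 2 kT/Å<sup>2</sup>) that supplies bending
rigidity. The two chains of a dimer are held side by side by bead-wise
harmonic restraints (rest 5 Å, 2 kT/Å<sup>2</sup>), making each dimer
rigid-ish without freezing it. The two dimers face each other head-to-head:
their 11-bead tips interdigitate, and tip bead *k* of each dimer-1 chain
binds tip bead *10-k* of each dimer-2 chain (44 contact pairs). This
lock-and-key registry emulates the structured head-to-head contact and
forbids the unphysical register sliding that an indiscriminate all-pairs
attraction permits. Each contact pair interacts through a flat-ended
quartic well V(r) = -ε(1-s²)² with s=(r-r₀)/w, minimum at the contact
distance r₀ = 4 Å, range w = 6 Å (cutoff 10 Å); the well is softly
repulsive inside r₀ and so doubles as an excluded-volume stand-in. The
initial geometry places the marker-residue (h.109) centroids of the two
dimers 9 Å apart — an intact interface by the assay's own < 10 Å
criterion.

**Dynamics.** Overdamped position-Langevin (Brownian) integration,
Δx = (F/γ)Δt + √(2kTΔt/γ)·ξ, with per-bead drag γ = 0.1 kT·ns/Å² and
timestep 4 ps. Reduced units: kT at 310 K is the energy unit, lengths
are Å, times ns. There is no inertia, no explicit solvent, and no
pressure coupling; the assay reproduces the qualitative force/stability
phenomenology of steered all-atom MD, not its timescales. Timestep
instability is detected on the deterministic drift term (a per-step drift
displacement exceeding the bond length raises an error); the Gaussian
noise increment is unbounded, so stability cannot meaningfully be judged
on the full step.

**Steering.** The per-atom forces of the assay (0.025-0.10 kJ mol⁻¹ nm⁻¹)
are applied to *every* bead, along +z for one dimer and -z for the other.
A bead stands for one residue, taken as 19 atoms (heavy + hydrogen)
for the unit conversion, so 0.05 kJ mol⁻¹ nm⁻¹ per atom ≈ 0.037 kT/Å per
bead. Whether the original assay also pulled on solvent or hydrogens is
unknowable from the outside; we force all beads and note the ambiguity.

**Genotypes and calibration.** Glutamate substitution is modelled solely
as a multiplicative weakening of the contact-well depth — charge detail
is out of scope. The wild-type depth (ε = 4 kT per pair) and the scales
(WT 1.0, L102E 0.7, L106E 0.3, L102E/L106E 0.15) were calibrated once,
before release, so that at the middle force over the default 100 ns run
the wild type and L102E survive while L106E and the double mutant
dissociate, the double mutant earlier; they are frozen in the versioned
`data/cg_defaults.yaml` and are not free parameters of the assay. With
these defaults the assay yields, at 0.05 kJ mol⁻¹ nm⁻¹: WT intact 5/5
seeds, L102E intact 5/5, L106E dissociated 5/5 (median disruption
~15-18 ns), double mutant dissociated 5/5 (median ~9-11 ns), and median
disruption times non-increasing in force. At the top force the wild type
loosens but does not dissociate.

**Closed-form diagnostics.** With the interface off and noise off, the
interdimer separation velocity equals 2F/γ exactly (each dimer drifts at
F/γ); free beads satisfy the Einstein relation MSD = 6(kT/γ)t. Both are
verified to 1% and 10% respectively.

## Trajectory metrics (`traj_analysis`)

RMSD uses the Kabsch algorithm (SVD of the weighted cross-covariance,
determinant-corrected to exclude reflections); superposition is
unweighted over the selection because CG beads are uniform. RMSF
superposes every frame onto the iteratively re-estimated mean structure
(5 fixed-point rounds) and reports per-bead fluctuation about the mean.
The interdimer distance is the Euclidean distance between the
marker-residue centroids of the two dimers, the centroid taken over all
marker particles in both chains of a dimer — the assay names a residue,
not an atom, so the residue centroid is the contract.

Dissociation classification: the interface is *intact* while the
distance stays below 10 Å; a series that crosses the 30 Å dissociation
threshold and whose smoothed tail (centered moving average, window 5
frames) never returns below 10 Å is *dissociated*, with the disruption
time at the first raw threshold crossing (frame resolution, no sub-frame
interpolation); a persistent excursion above 10 Å that never reaches
30 Å is *loosened*. The 10 Å intact criterion is the assay's own; the
30 Å threshold and 5-frame window are package defaults (well above the
intact scale, well below drift scales) and are echoed in every output.

## Synthetic imaging (`synth_imaging`)

Each stack renders two fluorescent chromosome axes as ridges offset by
±separation/2 along the normals of a midline polyline. Ridges default to
zero intrinsic width, so the in-plane cross-profile is the PSF itself:
an isotropic Gaussian of FWHM 120 nm (SIM-scale resolution). A finite
axis thickness can be added via `line_fwhm_nm` (profiles add in
quadrature); note that at ~130 nm separations the two-peak criterion
d > 2σ fails once the total profile FWHM approaches the separation, so
realism studies with thick lines should expect unresolved profiles.
Pixel size defaults to 40 nm; z-structure is a Gaussian focal envelope
(SD 1.5 slices) only — the measured quantity is in-plane. Noise is
Poisson shot noise on the expected counts plus additive Gaussian read
noise (SD 2), both seeded; the default amplitude 400 over background 20
gives peak SNR ≈ 20.

Tubule apoptosis counts come from a two-component Poisson mixture: with
probability `burst_fraction` a tubule is in meiotic-arrest "burst" state
(λ_high = 8 labelled nuclei expected), otherwise baseline (λ_low = 0.2).
The mixture's P(count ≥ 5) has the closed form f·P(Pois(λ_hi) ≥ 5) +
(1-f)·P(Pois(λ_lo) ≥ 5) used to validate the generator. Burst fractions
0.015 and 0.16 emulate a wild-type-like and a synapsis-defective-like
testis respectively.

What the generators do **not** emulate: chromatin texture, axis-width
variation, label stochasticity along the axis, multi-channel bleed,
anisotropic or depth-dependent PSFs, reconstruction artefacts, or
between-animal variance in counts. Passing tests therefore demonstrate
correctness of the measurement machinery on images whose deviations from
the model are purely shot/read noise — not robustness to every artefact
of real acquisitions.

## Image quantification (`image_quant`)

**Distance.** The focal projection takes the slice of maximal total
intensity (ties → lowest index) and projects the per-pixel maximum over
that slice ±2 (clamped). The trace is spline-interpolated, resampled at
exactly 1 px arc-length spacing (column count = floor(arc length)+1) and
the image is sampled bilinearly along trace normals over an odd band
width (default 31 px). Ten evenly spaced cross-profiles are taken at
columns (i+½)L/10 — a half-spacing margin at each end — each averaged
over 3 adjacent columns (thickness along the chromosome). Peaks are
found at a prominence of 3× the robust noise level (1.4826·median
|successive difference|/√2); with two or more candidates the two most
prominent initialize a least-squares double-Gaussian-plus-baseline fit,
and the separation is |μ₂-μ₁| × pixel size. Profiles with a single peak
are excluded — an unresolved pair is not a zero separation — as are
degenerate fits (a component amplitude below 3× noise, a width above a
third of the profile, or coincident centers). The chromosome's
separation is the mean over resolved profiles; below 250 nm it is called
synapsed (boundary → unsynapsed). The threshold is configurable and
logged; it bisects the ~150 nm synapsed and ~330-370 nm unsynapsed
regimes.

**Intensity.** ROI and background polygons are rasterized over pixel
centers with the even-odd rule; the integrated intensity is (ROI mean -
background mean) × ROI area, negative values flagged rather than
clipped. The projection operator (per-pixel maximum) is recorded in the
output; a sum projection would scale the result but not its genotype
contrasts.

## Statistics (`stats_pipeline`)

Mann-Whitney U (intensities): exact by enumeration for tie-free samples
with n₁+n₂ ≤ 12, otherwise normal approximation with tie correction; the
method is recorded. Fisher's exact test (tubules with < 5 vs ≥ 5
apoptotic nuclei; threshold inclusive on the high side): two-sided p by
the minimum-likelihood convention (sum of hypergeometric probabilities
≤ the observed table's). Unpaired t test (testis weights): Welch by
default — it is never anticonservative and reduces to the pooled test
when variances and group sizes agree — with the pooled variant available
for replication of legacy analyses. No multiple-testing correction is
applied; reports flag this. All wrappers are backed by scipy.stats; the
test suite checks them against independent enumeration /
hypergeometric-sum oracles.

## Problem sizes used in validation

The shipped validation runs use: 100 ns assay replicates (25 000 steps,
300 beads, ~4 s each), 5 seeds per genotype/force condition; 4000 free
beads over 8 ns for the Einstein-relation check (the MSD slope estimate
scatters as ~1/√n_beads, so this size puts its ~1.5% statistical error
well inside the 10% band); 20 synthetic stacks (64×160 px, 9 slices) per
separation in {132, 145, 332, 365} nm; full enumeration of all tie-free
Mann-Whitney arrangements up to n₁+n₂ = 10 and 1000 random 2×2 tables;
600-1000 replicates for the null rejection rate and 400 for power. These sizes keep a complete validation
run in a few minutes on one CPU while leaving every statistical check
with comfortable resolution.

## Known limitations

* The CG assay is calibrated to reproduce a qualitative ordering, not
  nanosecond disruption times; absolute times in "ns" are nominal.
* Genotype effects enter only through the interface scale; electrostatic
  mechanisms, partial unfolding and solvent effects are absent.
* The imaging generator's idealizations (above) mean recovery accuracy
  on real SIM data will be worse than on synthetic stacks.
* The bundled human/mouse alphaN-end segment pair is a synthetic
  stand-in constructed to have the field-typical 62/75 (82%) identity
  with the conserved core residue matched and the peripheral one
  differing; it is not the biological sequence.
* `straighten` requires the whole band inside the image; traces near
  borders must be trimmed first.
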