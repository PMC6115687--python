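# Methods

`atriasim` models inter-nodal atrial conduction in a heart with an
atrioventricular septal defect (AVSD), where the compact AV node is
displaced posterior-inferiorly (anterior to the coronary-sinus ostium).
The displacement shortens the atrial "slow" pathway and elongates the
"fast" pathway, inverting the normal dual-pathway physiology.  The package
reproduces the computational chain from a 3D image volume to pacing-protocol
readouts: fiber-orientation extraction by structure-tensor eigen-analysis,
assembly of an anisotropic monodomain tissue model with region-specific
atrial cell types, and S1–S2 pacing analysis (activation maps, pathway
arrival at the compact node, conduction block, retrograde conduction).
Because the original micro-CT dataset is not public, all inputs are
synthetic and ground-truth-bearing; what that does and does not demonstrate
is discussed at the end.

## Synthetic inputs

### Fiber phantoms

`make_fiber_phantom` builds image volumes whose texture is elongated along
an analytically known direction field (parallel, circular about the z axis,
or helical at 30°).  Texture is white Gaussian noise convolved along
streamlines of the direction field (line-integral convolution with cubic
interpolation and a kernel half-length of ~1.5 texture periods), so
intensity varies least along the fiber — the contrast a structure tensor
exploits.  Defaults: 38.5 µm voxels, 300 µm texture period.  The noise is
pre-smoothed with a Gaussian whose width scales with the texture period
(σ = period/10 voxels, floor 0.5): too-fine cross-fiber grain leaves a
lattice-direction gradient bias on oblique fibers, too-coarse grain starves
the tensor window of independent grains.  `noise_sd` adds seeded Gaussian
intensity noise; ground truth is independent of the seed.

### The parametric AVSD sheet

`make_avsd_atria` rasterizes a flattened "unrolled-atria" sheet (default
0.15 mm isotropic voxels, 0.3 mm wall thickness).  Path lengths and
topology — not patient anatomy — drive the electrophysiological results, so
a parametric sheet is an adequate substrate.  The sinus node (SN) connects
to the compact node by three label-disjoint routes forming a closed
circuit:

* **slow route** (default 12 mm): terminal crest descending from the SN,
  then a short distal slow-pathway segment to the node — the shortened
  route of the AVSD anatomy;
* **fast route** (default 16.5 mm): a septal bundle arcing to the node;
* **valve annulus** (default 26 mm): the longest route, closing the
  circuit.

Routes are circular arcs with exactly the requested centerline lengths;
orientation vectors follow the local centerline tangent (unit norm on every
active voxel, zero on background).  A working-myocardium (RA) patch hangs
off the SN as an appendage stand-in, a configurable block zone sits between
the SN and the septal bundle, and inert fat/connective pads are included so
attenuation rendering spans all tissue contrasts.  `make_attenuation_volume`
renders labels to intensities with the iodine-contrast ordering
fat > working myocardium > nodal tissue > connective tissue.

**Geometry calibration.** Route-length defaults are calibrated so the
physiology matches the modeled heart: at the calibrated conduction velocity
the *effective* speed along curved, rasterized bundles is ≈ 0.58 mm/ms
(off-axis and curvature discretization bias relative to a straight strand),
so a fast/slow length difference of 4.5 mm puts the sinus-beat fast-minus-
slow nodal arrival at ≈ 8 ms, inside the reported 5–10 ms window.

**The slow-pathway entrance.** The slow route takes off from the SN region
through a narrow transitional isthmus (0.45 mm wide, 1.2 mm long) that
opens abruptly into the 1.35 mm-wide crest.  This geometric source–sink
mismatch is a classical substrate for unidirectional block: a premature,
partially recovered wavefront emerging from the SN cannot charge the
expansion and dies, while full-strength beats pass.  The vulnerability must
sit where the premature front is weakest (just outside the SN); a
constriction placed mid-route does not block, because a premature front
recovers progressively as it propagates into later-activated tissue.  This
is the package's model of the distorted nodal-input anatomy; a real
specimen provides the equivalent heterogeneity implicitly.

## Orientation extraction

The structure tensor J = G_σw ∗ (∇I ∇Iᵀ) is built from Gaussian-derivative
gradients (inner scale σ_g) and window-smoothed (outer scale σ_w); defaults
are σ_g = 1 voxel and σ_w = 4 voxels, both configuration-exposed.  Because
intensity varies least along a myocyte chain, the fiber direction is the
eigenvector of the *smallest* eigenvalue; coherence is
(λ₂ − λ₃)/(λ₁ + λ₂ + λ₃ + ε) with λ₁ ≥ λ₂ ≥ λ₃ and
ε = 10⁻¹² × the trace scale.  Orientation is axial (f ≡ −f); outputs are
made reproducible by flipping every vector into the z ≥ 0 hemisphere (ties
broken by y, then x).  Downsampling to modeling resolution (default
0.15 mm) uses block means for scalars, block majority votes for labels
(background loses ties to tissue), and for orientation the mean of the
outer products f fᵀ followed by re-extraction of the dominant eigenvector,
so antipodal vectors reinforce instead of cancelling.  Non-integer
decimation factors fall back to resampling with an explicit warning.

Known accuracy behaviour: on the lattice-aligned parallel phantom the
median axial error is < 2°; on curved fields the same scales give several
degrees more because discrete Gaussian derivatives of near-Nyquist texture
carry a lattice-direction bias — a coarser texture (larger period, e.g.
600 µm at 38.5 µm voxels) brings the circular phantom below 5°.

## Cell models

The detailed model is a biophysically complete human atrial myocyte
formulation of the Courtemanche family: INa, IK1, Ito, IKur, IKr, IKs,
ICaL, INaK, INaCa, IpCa, background Na/Ca currents, and SR calcium handling
(uptake, release, transfer; calmodulin/troponin/calsequestrin buffering) —
21 state variables.  All parameters live in `data/cell_params.json`.
Regional variants: `RA` (baseline working myocardium) and `CT`
(conduction-system/bundle type), the latter carrying ICaL × 1.68 from the
same model lineage's crista-terminalis modification, which lengthens the
plateau (APD90 at a 400 ms cycle: ≈ 245 ms RA, ≈ 275 ms CT).  The block
zone uses RA kinetics with gNa and gCaL scaled by exactly 0.5; the scaling
is tagged and cannot be applied twice.  Which conductances "sodium and
calcium" covers is configurable; the default is fast INa and ICaL only.

Sinus-node voxels carry ordinary CT-type kinetics and are driven by
external stimuli (20 pA/pF × 2 ms standard; 40 pA/pF × 4 ms fast pacing),
added directly to dV/dt in capacitance-normalized units.

A two-variable excitable fallback (`phenomenological`, Mitchell–Schaeffer
form, mapped to mV) serves cheap geometry and wave tests; it is never used
for the quantitative pacing results.

## Monodomain solver

dV/dt = ∇·(D∇V) − I_ion + I_stim on the active-node graph, by operator
splitting: an explicit sparse diffusion step and a Rush–Larsen reaction
step per time step.  The diffusion operator is a conservative face-flux
discretization with face-averaged tensors and averaged (one-sided at
boundaries) tangential differences for the cross-derivative terms, which
are required because fibers are not grid-aligned.  Links to inert or
out-of-domain voxels carry zero flux, so constant fields are exact
equilibria and the boundaries are naturally no-flux — appropriate for an
excised preparation.  D = d_t I + (d_l − d_t) f fᵀ with d_l/d_t = 8 by
default, read as a *coefficient* ratio (the resulting velocity ratio is
≈ √8).

Numerics: dt = 0.02 ms for the detailed model with tabulated
voltage-dependent rates (linear interpolation on a 0.02 mV grid) — halving
dt changes single-cell peak potential by < 0.5 mV and measured CV by < 2%.
Explicit diffusion additionally requires
dt ≤ 0.9 h²/(2 max trace D), enforced with an informative error.  The
kernels are serial and deterministic: identical inputs give bit-identical
trajectories.  Refining h from 0.15 to 0.075 mm changes CV by well under
10% (explicit-grid CV bias); the 0.15 mm default matches atrial myocyte
length.

`calibrate_diffusion` bisects d_l on a 20 mm fiber-aligned strand
(stimulating a 1.2 mm end segment — a single-voxel source cannot charge a
well-coupled cable) until the velocity between the 25% and 75% probes
reaches the target (68.2 cm/s for RA tissue) within 0.1 cm/s.  At very
large d_l the strand approaches isopotential and initiation fails; the
upper bracket shrinks automatically.  The calibrated value on the default
grid is d_l ≈ 0.186 mm²/ms.

## Pacing protocols and analysis

The S1–S2 protocol (8 S1 at 400 ms cycle length from the sinus node, then
one S2 from the sweep {250, 275, 300, 350, 400} ms with fast-pacing
settings) runs the conditioning train once and branches every S2 from the
checkpointed state.  A beat *captures* when ≥ 90% of active nodes activate
inside its window (the capture fraction is configuration-exposed since
"atrial activation" is not otherwise quantified).  Activation time is the
first upward crossing of −40 mV (sub-step interpolated); isochrone bands
partition activated nodes at a configurable interval.

**Pathway arrival.**  Once the node fires via the first route, its
activation spills backward into the other routes' insertions, so a plain
minimum over near-node voxels measures the spill, not route conduction.
`pathway_arrival` therefore identifies each route's own node-ward front by
local time-ordering along arc length (upstream neighbours earlier,
downstream not earlier, contiguous from the proximal end), fits a robust
Theil–Sen line of time versus arc length, and evaluates it at the route's
nodal end.  A front that met the opposing spill mid-route (collision: the
two fronts meet at nearly the same time) still gets an arrival; a front
that *blocked* (nothing distal activates, or the distal segment fires only
much later and backwards) reports NaN.  Route direction is the sign of the
Theil–Sen slope over the whole route (anterograde / retrograde / none).

**Capture margin.**  The qualitative dual-pathway signature lives at the
capture *margin* — the smallest coupling interval that still captures.  A
coarse sweep member can sit tens of ms above it, where premature beats are
no longer marginal and conduct normally; `find_capture_margin` bisects
between the largest blocked and smallest capturing sweep members.  On the
default geometry the margin beat blocks anterogradely at the slow-pathway
take-off isthmus, reaches the node via the fast (septal) route, and then
conducts retrogradely up the slow pathway and crest; the fast-pathway
bundles accordingly leave their refractory period before the slow-pathway
region.  Steady-rhythm (S1) beats show the opposite, slow-first
anterograde pattern.  These results are unchanged with the block zone
toggled off (its voxels then carry plain RA kinetics).

## Quantitative behaviour and the ionic-model substitution

The detailed ionic model is the Courtemanche-family formulation described
above rather than the CNZ parameterization sometimes used for this kind of
whole-atria modeling (its complete equation set is not openly available).
The consequences of that choice are
confined to absolute refractoriness: with CT-type bundles at a 400 ms
cycle the tissue-level capture boundary lands at 350 ms on the coarse
sweep — the member adjacent to the reported 300 ms — while the continuous
capture margin sits only ≈ 7 ms above 300 ms.  All other quantitative
readouts are insensitive to the substitution: the calibrated 68.2 cm/s
velocity is a fitted contract, the 8:1 tensor ratio and 50% block-zone
scaling are exact by construction, the 5–10 ms arrival window follows from
geometry at the calibrated velocity, and sustained pacing below the
boundary captures on alternating stimuli (exactly 2:1).

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in minutes on one CPU: the AVSD sheet has ≈ 5,800 active nodes
(0.15 mm spacing, 2-voxel wall), the calibration strand 134 nodes, and the
S1 train plus sweep simulate ≈ 6 s of tissue activity.  All sizes scale
through the geometry and protocol configuration.

## What the synthetic setting does and does not show

The generator reproduces the *conditions* of the modeled heart — tissue
contrast ordering, bundle topology with a shortened slow and elongated
fast pathway, region-specific cell types, calibrated conduction velocity,
and the pacing protocols — so passing tests show the computational chain
(orientation extraction, tensor assembly, monodomain propagation, protocol
analysis) behaves correctly and that the inverted dual-pathway mechanism
is reproducible from those conditions.  They do not validate patient-specific anatomy:
real atria are curved 3D walls with heterogeneous thickness, branching
bundles and imaging artifacts, and the real substrate for premature-beat
block at the slow-pathway entrance is anatomical detail that the sheet
represents only through an equivalent parametric isthmus.
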