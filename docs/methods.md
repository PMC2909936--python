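# Methods

Model conventions, default parameters and numerical choices, in pipeline
order. All lengths are nm unless noted; all randomness flows from
`numpy.random.Generator` seeded via `SeedSequence`, so every experiment is
reproducible from a single integer seed.

## Substrate geometry (`fragments`)

A fragment is `internal flank + 36 bp IR + external flank`, coordinates
0-based and half-open with the internal 5' end at position 0. The two
standard substrates are 14+36+50 = 100 bp and 164+36+50 = 250 bp.

* **Rise 0.332 nm/bp** (configurable), chosen so 250 bp → 83.0 nm and
  66 bp → 21.912 ≈ 22 nm exactly as conventionally printed; 0.34 nm/bp
  would give 85 nm.
* **Binding-site footprint**: 22 bp span (middle of the reported
  20–25 bp), placed 16 bp inward from the external IR tip, so the
  junction coordinate sits 50 + 16 = 66 bp from the external end of the
  250 bp fragment. The footprint interval of R250 is [162, 184) and the
  crossing coordinate is bp 184.
* Unspecified flank sequence is filled with a fixed seeded pseudorandom
  sequence so fragments are bit-reproducible.

## Chain model (`wlc`)

Deposited molecules are discrete 2D worm-like chains: per-step tangent
increments are independent `N(0, ds/P)` with persistence length
`P = 50 nm` and step `2 bp` (0.664 nm). This is the 2D *equilibrium*
statistics of a chain with bending stiffness `P·kT`; the in-plane tangent
correlation decays as `exp(-s/2P)` (asserted by a Monte-Carlo unit test).
We deliberately use this convention rather than forcing `exp(-s/P)`
in-plane, which would correspond to an effective 25 nm persistence length
— far floppier than deposited B-DNA and incompatible with resolvable
synapse arms. The total contour equals the fragment length exactly by
construction (the last step absorbs the bp remainder).

**Excluded volume / resolvable conformations.** Two ridges closer than
~10 nm merge into one binary mask under the 3 nm tip PSF
(`2σ·sqrt(2·ln(2/thr)) ≈ 10` at the operating threshold), so no tracer
could separate them even in principle. The generator therefore models the
*resolvable-conformation* population: conformations whose distant
segments (≥ 15 nm apart along the contour) approach below 10 nm are
rejected and redrawn. Near a prescribed crossing the full clearance is
geometrically impossible, so the requirement tapers to the separation a
straight crossing at the steepest allowed angle (40°) would give,
`2·sin(20°)·r ≈ 0.615·r` at radius `r` (with 10% tolerance). Synapse
pairs are drawn by joint rejection (redraw both molecules, up to 40×8
attempts, best-clearance fallback).

**Synapse assembly.** Both chains pass through the origin at their
crossing coordinate. The protein particle grips both duplexes, modelled
as a rigid (straight) 44 bp span — one 22 bp footprint's worth of DNA on
each side of the crossing — without which junction tangents would be
unmeasurable in principle. Crossing angle uniform in [40°, 90°]; pX puts
the two short (external) arms on the same side, Ap on opposite sides, and
pY replaces the crossing with a shared internal branch (two chains
following the same path at a 0.15 nm sub-resolution lateral offset) plus
two separate external arms. Incidental crossings (the protein-free
background) cross at uniform random internal coordinates (15–85% of the
length) and angles in [40°, 140°].

## Rendering (`render`)

Defaults: 512 px fields at 2 nm/px, tip PSF σ = 3 nm, ridge amplitude
1 nm, i.i.d. Gaussian pixel noise σ = 0.05 nm, molecule density
25 /µm². Chains are splatted as arc-length mass (bilinear, 0.5 nm
sub-steps) so the blurred ridge response is rotation-invariant, then
normalised so an isolated straight ridge peaks at the amplitude.

Mixtures: the protein condition is 76% free molecules and 24% in
synapses split 38:26:14 across pX:pY:Ap; the no-protein condition is 94%
free + 6% incidental crossings. Synapse classes are drawn per molecule
and rounded to whole pairs with a fair coin (always demoting leftovers
would bias the crossed fraction low). Placement rejects collisions with
previously placed material dilated by the 10 nm resolvability clearance,
so separate objects never merge into one traced component. Each field's
TIFF carries the pixel size in metadata and is paired with a full
ground-truth JSON (per-molecule polyline, morphology, partner, crossing
coordinate, true L_se).

## Tracing (`trace`)

Threshold (Otsu, floored at background median + 5 robust σ so
molecule-free images segment empty) → remove specks < 12 px →
skeletonize → endpoint/junction pixel graph with geodesic edge lengths
(chain metric: 1 px orthogonal, √2 px diagonal steps). Clean-ups, all in
physical units:

* spurs < 6 nm hanging off junctions pruned;
* junction pairs closer than 20 nm fused: tip broadening "zippers" a
  shallow-angle X crossing into two 3-way junctions up to ~17 nm apart,
  so the 2 px cluster radius alone is not enough. Arm lengths are
  corrected by the gap from the fused centroid to each arm's path start
  so fusing does not shorten arms;
* skeleton tips eroded by thinning inside rounded ridge caps are extended
  along their local direction to the mask boundary (≤ 8 px).

Components are typed by node census: 2 endpoints/0 junctions → linear;
1 junction of degree 4 with 4 endpoints → crossed_X; degree 3 with 3 →
branched_Y; anything else → other. Components with < 30 nm of skeleton
are dropped; components within 2 px of the border are flagged and
excluded from population statistics.

Measured contours are systematically a few % *high* (cap extension plus
skeleton wiggle), mirroring the known positive bias of AFM length
measurements; noise-free field recovery is within 5% of the 83 nm truth.

## Classification (`synapse`)

Arm directions are chords from the sub-pixel junction centroid to the
skeleton point at 12 nm *radius* — outside the ~9 nm zone where the two
ridges' skeletons splay at the steepest allowed crossing, close enough to
limit chain wander. The 4 arms are paired into molecules by maximal
tangent anti-alignment (a genuine crossing continues nearly straight
through the junction; worst-pair cosine margin 0.17, else unclassified).
Each molecule's axis is the normalised difference of its two arm
tangents, oriented toward the short arm; pX vs Ap is the sign of the two
axes' dot product. Calls require the short arms to match the expected
21.912 nm within 15 nm tolerance; L_se is the mean short-arm length.

3-branch objects: two external-length arms plus a longer shared branch →
pY (L_se = shorter external arm). Steep crossings whose adjacent arm
pair merged into one branch are still length-identifiable (only Ap pairs
short with long across the junction): short + internal-length + over-long
doubled branch → Ap; merged-shorts stub + two internal-length arms → pX;
these absorbed-arm calls carry no L_se estimate. Anything incompatible
with the substrate geometry (e.g. mid-molecule incidental overlaps) →
unclassified.

Near 90° crossings pX and Ap are geometrically degenerate (the
"same-side" notion vanishes), which bounds achievable recall; flips
concentrate in the 84–90° band.

## Population statistics and experiments

Each non-linear object counts as two molecules; the crossed fraction is
crossed molecules over all molecules. Confidence intervals for the
crossed fraction are computed on the independent sampling unit — the
placed object — via a 95% Wilson interval on the object fraction `q`,
mapped to the molecule fraction `p = 2q/(1+q)`; treating paired molecules
as independent Bernoulli trials under-covers. Recovery against ground
truth matches traced junctions to truth crossings within 20 nm.

`experiments` provides seeded end-to-end checks: noise-free contour
recovery, per-class synapse recall and L_se at default noise
(≥ 90% / within ±3 nm over 210 synapses), crossed-fraction CI coverage
for both conditions, and the EMSA dimer selection rate.

## EMSA (`emsa`)

Masses: untagged subunit 16.4 kDa, TrxA-tagged 33.9 kDa, dsDNA
0.66 kDa/bp (36 bp → 23.76 kDa). Under free subunit exchange an n-mer on
one DNA gives n+1 distinguishable bands; the dimer ladder is {56.56,
74.06, 91.56} kDa with binomial pool proportions ((1−f)², 2f(1−f), f²) at
tagged fraction f. Migration is modelled as `μ = a − b·log10(M)`
(defaults a = 150 mm, b = 60 mm/decade, 1% multiplicative noise).
Stoichiometry inference ranks candidate n by band-count match, then by r²
of the best order-preserving mass-to-band assignment; on synthetic dimer
gels at 2% noise n = 2 is selected in ≥ 95% of replicates.

## Limitations

* The generator is 2D-equilibrated and strictly planar: no height
  information is used beyond a single ridge amplitude, and no tip
  convolution asymmetry, scanner drift or line noise is modelled.
* The excluded-volume rule models the resolvable population, not full
  polymer self-avoidance; condensed or overlapping conformations that a
  human scorer would discard are simply never generated.
* The rigid 44 bp clamp is a stand-in for the unknown nucleoprotein core
  structure; only its span, not its shape, is modelled.
* pX/Ap assignment is undefined at exactly 90° crossings; recall
  criteria account for the degenerate band.
* EMSA modelling is purely arithmetic (masses and log-linear migration);
  no binding thermodynamics, band intensities or smile/edge artefacts.
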