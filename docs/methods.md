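# Methods

## The assembly and the question

The package models a hollow, symmetric multienzyme scaffold: an outer
shell of identical subunits (the transacetylase core of a pyruvate
dehydrogenase-type metabolon) enclosing a small number of interior trimers
of a binding protein. Three quantitative questions drive the design: does
a flexible element modeled into each shell subunit have supporting density
in the experimental map, and does that depend on how close the subunit is
to an interior partner; how much of the hollow interior is actually filled
by polypeptide; and which docking poses of a mobile domain are compatible
with a covalent-arm distance restraint and steric feasibility.

## Density enclosure

For each of M symmetry-related subunits the element's atoms are point-
sampled in the map by trilinear interpolation, and an atom is *uncovered*
at contour level ℓ when its value is strictly below ℓ (equality counts as
covered). Sweeping ℓ from 0.015 to 0.052 in steps of 0.0005 gives N = 75
levels and an M × N matrix of uncovered counts, non-decreasing in ℓ by
construction. Per level, the band is CI = μ ± z·σ/√M with the sample
standard deviation (M − 1 denominator) and z = 3.291 by default; the
per-subunit enclosure probability is p = n/N with n the number of levels
where that subunit's count is strictly below the lower bound.

Two readings of "below the confidence range" are possible; the default
counts only the lower tail, which makes p a probability of *enclosure*
(fewer uncovered atoms than the cohort expects means extra density covers
the element). An `outside` mode counting both tails is provided. The
z = 3.291 default is the two-sided 99.9% normal quantile even though such
bands are often described as "99% CI"; the formula, not the label, is
implemented. Coverage is sampled at atom centers, not volumetrically;
with a smooth simulated map and ~20-atom elements the two notions agree.

The statistic is one-sided by design: it flags subunits enclosed *more*
than the cohort. When enclosed copies are the majority, μ drops, the
lower bound goes negative and p saturates at 0 for everyone — recovery
studies therefore plant high weights on a minority (3–6 of 12) of
subunits, matching the situation the method is built for.

### Map–model correlation

`map_model_cc` renders the model on the experimental grid with the same
Gaussian convention used by the simulator and computes the Pearson
correlation over voxels within a mask radius (default 3 Å) of any atom.
Self-comparison against a noiselessly simulated map returns 1.0 to 1e−6,
which ties the simulator and the correlator to one convention.

## Synthetic study conditions

The toy assembly places subunits on a sphere: the exact icosahedron for
12 subunits, the exact dodecahedron for 20, a Fibonacci lattice otherwise.
Each subunit carries a rigid Gaussian blob of 30 pseudo-atoms plus a
separately tagged "flexible element" of 20 atoms displaced 10 Å radially
outward. The element is a compact uniform ball (radius 2.1 Å): every
element atom then sits in dense surroundings, so a fully weighted element
is enclosed across the entire default sweep and a weight-0 element across
none of it — without that compactness, outlying atoms of a Gaussian blob
dilute their own density and the planted split blurs. Interior trimers
sit at tetrahedral directions (pairwise center-of-mass spacing equal by
construction); each monomer is its own chain with a Cα anchor residue.

Maps are sums of normalized 3-D Gaussians, σ = resolution/(π√2) — a
common cryo-EM width convention; the simulator, the enclosure counter and
the correlator share it, which is what the self-consistency tests need.
Defaults: 8 Å nominal resolution on a 2 Å grid, white noise of 0.002 map
units (≈ 5% of a weighted element's peak). Element atoms are scaled by
their chain's weight ∈ [0, 1]; the map is linear in atoms and weights.

The proximity pipeline uses the 20-subunit shell (radius 85 Å) over four
trimers at 40 Å, because dodecahedron-over-tetrahedron geometry yields
three exact distance shells (~45, ~57–59, ~77 Å): the middle shell falls
in the proximal 55–70 Å bin, the outer one beyond the 75 Å distal
threshold, and the four aligned subunits in the deliberately open gap
below 55 Å. A 12-subunit icosahedral shell cannot produce distance
variety — every vertex is 37.4° from its nearest tetrahedral direction —
which is why the enclosure recovery scenario (12 subunits) and the
grouping scenario (20) differ.

Disordered ensembles are fixed-bond (3.8 Å) self-avoiding Cα chains
(excluded-volume radius 2 Å). Unanchored chains are generated by
whole-chain rejection, which is exactly uniform over self-avoiding
configurations and is validated against a brute-force rejection oracle;
end-anchored chains use biased growth (steps sampled uniformly from the
cone that keeps the anchor reachable with the remaining steps), which is
efficient but not strictly uniform — adequate for the volume estimates it
feeds, and stated here precisely because it is a bias.

What the generators do *not* emulate: real side-chain chemistry, B-factor
variation, solvent contrast, map anisotropy, or correlated noise. Passing
recovery tests therefore show the statistics behave correctly under their
own assumptions, not that a real reconstruction satisfies them.

## Volumetrics

Solvent-excluded (molecular) volume is computed on a voxel lattice by
morphological closing with sub-voxel accuracy. An exact margin field
m(v) = min_i(|v − x_i| − r_i) is stamped per atom; the probe-dilated
region is {m ≤ 1.4 Å}. Erosion uses probe witnesses: a point is outside
the closed surface iff a probe position with clearance ≥ probe sits
within probe of it, and by the 1-Lipschitz property of m it suffices to
carve, around every lattice point u with m(u) ∈ (probe, probe + 4h], the
ball of radius m(u). This reproduces the probe-closed sphere to ~0.2% at
h = 0.5 Å and converges under grid halving to < 2% for the compact
geometries the package integrates (overlapping 3 Å residue spheres on Cα
chains; probe-closed balls). Loose point scatters with deep crevices
converge only first-order — they are outside the intended use.

Occupancy reports intersect component grids with a spherical mask
(default radius 80 Å, spacing 0.5 Å; the toy pipeline scales the mask to
0.75 × shell radius and caps spacing at radius/40). Component volumes are
union volumes; for the pie fractions a voxel claimed by several
components is split equally among them, so fractions plus empty sum to 1
and nothing is double-counted. Ensemble volumes are reported as the mean
± sd of per-model volumes — the expected instantaneous occupancy — rather
than the union over models, which would grow without bound with ensemble
size.

Radii are a Bondi-style table; unknown elements raise rather than
default. Disordered-chain residues are 3.0 Å spheres on Cα positions.

## SASA, interfaces, energies

SASA is Shrake–Rupley with a deterministic Fibonacci point set (960
points default): a test point on the probe-extended sphere is accessible
when no neighbouring probe-extended sphere contains it. The isolated atom
reproduces 4π(r + 1.4)² to the sampling error (< 1%), and a touching pair
matches the spherical-cap closed form to 2%. BSA is Σ SASA(partner) −
SASA(complex), multi-body by summation.

The energy decomposition is a deliberately simplified, scoring-level
stand-in and is labeled as such in its output: Lennard-Jones 12-6 with
rmin = r_i + r_j and generic per-element well depths; Coulomb
332.06·q_iq_j/(r·ε(r)) with the distance-dependent dielectric ε(r) = r and
a coarse formal-charge template (carboxylates −1 split over the two
oxygens, Lys/Arg +1, His neutral, backbone ignored); desolvation as
atomic-solvation-parameter × ΔSASA on complexation. The three components
support *relative* comparisons between interfaces; absolute values are
not comparable to refined force-field energies, which is why BSA — pure
geometry — is the quantitatively comparable interface output.

Clashes are cross-partner heavy-atom pairs with vdW overlap strictly
greater than 0.4 Å, found by k-d-tree neighbor search and verified against
an O(N²) scan in the tests. Pose ranking is a stable sort: restraint
satisfied (inclusive 10–25 Å bounds) first, then fewer clashes, then
larger BSA.

## Kinetics

c = A/(ε·l) with ε = 3.07 × 10⁴ L mol⁻¹ cm⁻¹ and l = 1 cm defaults.
The hyperbola is fitted by unweighted nonlinear least squares
(Levenberg–Marquardt via `scipy.optimize.curve_fit`), initial guesses
V_max = max(v) and K_M = the interpolated half-max abscissa; standard
errors come from the Jacobian at the optimum. Replicate tables are fitted
on per-concentration means by default (matching error-bar plots), with a
pooled mode available. Monte-Carlo calibration (1000 replicates, 5% noise
on an 8-point grid) shows the SE-based 95% interval — using the t(6)
quantile appropriate to 8 points and 2 parameters — covers the truth at
~96%.

## Conservation

A 1-based position in the reference's ungapped sequence maps to the
alignment column containing its position-th non-gap character. Column
frequencies are computed over non-gap characters (gap fraction available
separately), case-insensitively, with 'X' its own category. Sequences are
counted per row; any de-duplication is the caller's responsibility.

## Problem sizes and determinism

All tests and the acceptance script run on the scaled-down conditions:
12–20 subunits, 20-atom elements, 2 Å map grids, masks of 15–60 Å at
0.25–2 Å spacing, 1000-replicate Monte-Carlo for the kinetics
calibration, 2460-sequence alignments. These sizes were chosen so the
statistics are well-resolved while a full run stays in the minutes range.
Every generator is a pure function of its seed; pipeline runs write a
resolved-config JSON and their outputs are byte-reproducible for a fixed
seed.

## Known limitations

* Enclosure coverage is center-point sampling, not the volumetric
  inside-contour test a rendering program performs; the two can differ
  for atoms near a contour surface.
* The enclosure statistic saturates when enclosed copies are the cohort
  majority (see above); p is also undefined in spirit when M < 2.
* SES volumes of high-curvature crevices converge only first-order in
  grid spacing.
* The energy decomposition is not a force field; desolvation parameters
  are generic atomic solvation values.
* End-anchored chain ensembles are biased toward feasible paths; their
  volumes carry that bias.
* mmCIF assembly operators are not expanded; maps must be orthorhombic.
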