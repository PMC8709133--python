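# Methods

## Models

### Proximity functions

The estimator implements the pair definition directly: for each track,
every ordered pair (i, j), i ≠ j, of energy transfers contributes
ε_i ε_j / T to the bin containing the pair distance, the per-bin mass is
divided by the bin width, and bins are averaged over tracks (a per-track
expectation). Counting ordered pairs means a two-deposit track of energies
ε each carries total mass ε, and the exact per-track identity

    ∫ t(x) dx  (+ overflow)  =  T − (Σ ε_i²)/T

holds to accumulation roundoff; the test suite checks both the identity
and exact agreement with an O(N²) double-loop reference. Pair distances
outside the binned range go to an explicit overflow accumulator, never
silently dropped. Default bins are log-spaced over 10⁻⁴–10³ μm (pair
distances in this problem span from nanometre Auger clusters to
millimetre-scale fast-electron ranges); the bin representative is the
geometric mean of its edges, appropriate on a log grid. The dose term
4πx²ρD is added bin-wise with the single unit bridge the package owns
(1 keV = 1.602176634×10⁻¹⁶ J; 1 g/cm³·μm³ = 10⁻¹⁵ kg).

### TDRA quantities

ξ is integrated by bin sum on the curve's grid; the inversion for the
distance parameter a uses Brent's method on a default bracket of
[10⁻³, 10] μm with the achievable ξ range reported when the target is
outside it. Δξ deliberately avoids binning: the per-event quantity
E·∫t_NP e^(−x/a)dx is evaluated as the exact pairwise sum
Σ_{i≠j} ε_i ε_j e^(−x_ij/a)/T over the nucleus deposits (T = E), so the
Monte-Carlo average over events carries no discretization error. Events
that miss the nucleus contribute zero and *are* included in the average —
the zero point mass of p(E) is part of the expectation. t_NP is normalized
by the in-nucleus energy E, the reading most consistent with the defining
text of the yield integrals; Δξ scales directly with this convention.

ζ is computed as n·μλ·Ē/(ρV) = n·p1Gy·z̄, the explicit definition
accompanying the yield decomposition. (The intermediate inter-track yield
expression in the source derivation carries an 8π prefactor that is
algebraically inconsistent with the terms it is assembled from, which give
4π and hence exactly this ζ; the explicit definition wins and the
discrepancy is documented rather than silently patched.) DER = 1 + ζ.

The constants c, k and the DNA volume fraction η are carried symbolically
only: every exported quantity (ξ, Δξ/ξ, ζ, RBE, DER) is a ratio in which
they cancel, so they are never instantiated numerically and absolute
lesion yields are out of scope.

RBE at dose D_NP is the closed-form positive root of the equal-yield
quadratic, verified against a brute-force root solver to 10⁻⁹ relative.

### Bomb model

Δα = p1Gy(N₁p₁ + N₂p₂) with N₂ = 0 by default (imaging studies do not
find NPs inside nuclei); p₁ inference is the exact inverse. Uncertainty
is first-order: σ_Δα = √(σ_α² + σ_α′²) for independent fit errors,
combined in quadrature with the relative uncertainty of p1Gy. The exact
scheme behind the published uncertainties is unstated, and at least one
published interval (the A549 low-concentration range) is not reproducible
by any obvious propagation, so σ values are reported but not asserted.
An inferred p₁ > 1 is returned as-is with a validity flag — it diagnoses
inconsistent inputs (one published 6 MV case does this) and clipping it
would hide the diagnosis. Published LQ tables occasionally report a
changed β with NPs; equal-effect RBE and survival use the with-NP β
(required to reproduce the published SF/RBE columns), while Δα for p₁
uses α′ − α only, as the model prescribes. A negative stored α (one
published fit) is kept for fixture completeness but refused by the RBE
solver with a clear error.

## Geometry

Cells are concentric spheres (presets: SQ20B 10.6/8.1 μm, HeLa 8.6/5.5 μm,
A549 7.4/4.8 μm; water density). NP uptake scenarios: uniform-in-volume in
the whole cell or the cytoplasmic shell (radial-CDF sampling), or
isotropic on the sphere r_nucleus + r_NP — "around the nuclear membrane"
is read as touching from outside, since uptake imaging places the NPs in
the cytoplasm; the placement radius is the one genuinely open choice here.
Deposits are generated in the NP-local frame and *translated* (never
rotated) into the nucleus frame, preserving the NP-relative track
orientation. NPs are points for scoring; the finite NP size enters only
through the placement radius and the generator's self-absorption
probability.

## The synthetic track generator

The generator emulates what the downstream estimators need from a
track-structure code — and nothing else:

- per NP ionization, 0 or 1 fast (photo/Compton) electron plus a
  Poisson number of Auger electrons;
- each surviving electron travels straight in an isotropic direction for
  R = b·E^p and lays down k equal-share energy transfers whose spatial
  density increases toward the track end (fractional arc positions
  √((j−½)/k)), emulating track-end clustering;
- NP self-absorption is a Bernoulli thinning, not in-NP transport.

Defaults (chosen once for realism, not tuned to any test outcome):
photoelectron scale 30 keV (exponential; a tens-of-keV scale typical of
kV-beam photoelectrons minus an inner-shell binding energy), emission
probability 0.9, Poisson mean 4 Auger electrons at 1 keV scale (several
low-energy electrons per cascade), range law b = 0.04 μm·keV⁻ᵖ, p = 1.7
(a power-law fit shape for low-energy electron ranges in water: 1 keV →
40 nm, 10 keV → 2 μm, so Auger energy stays within ~500 nm of the NP),
20 deposits per electron for cascade events, self-absorption 0.1. With
the packaged cell models these defaults give mean specific energies of
order 10⁻⁴–10⁻³ Gy per ionization — the decade the reference calculations
report — and the expected ordering of the zero-energy fraction across
uptake scenarios (cytoplasm ≥ whole cell ≥ membrane). Documented, not
asserted: the generator is a stand-in, and nothing downstream depends on
dosimetric accuracy.

For the *reference* water curve the pipeline raises the deposit count to
200 per electron: the ξ integral needs transfer points at sub-100 nm
spacing to carry short-distance mass, and with coarse tracks ξ(a) cannot
reach experimental α/β values anywhere on the bracket. Cascade events
stay coarse because Δξ is an exact pairwise sum per event and only the
relative spatial statistics matter there.

What the toy physics does **not** emulate: angular scattering and track
curvature, energy-loss straggling and realistic ionization spacing,
δ-rays, photon transport and beam spectra, NP-internal cascades,
radiochemistry. Passing tests therefore demonstrate the correctness of
the estimators and the analysis chain on data with the right spatial
statistics — not agreement of Δξ or a with values derived from real
track-structure simulations, which require a transport code.

## Numerical choices

- Brent root-finding for a: xtol 10⁻⁸ μm; ξ evaluated on the curve grid.
- Exact pairwise sums (scipy `pdist`) wherever a discretization would
  bias a result (Δξ, the per-event integrals).
- Degenerate inputs are defined, not special-cased: single-deposit tracks
  give t ≡ 0; events with < 2 nucleus deposits contribute 0 to Δξ; D = 0
  leaves t_D = t; empty nucleus intersections are valid (E = 0).
- One RNG stream per run (`numpy` PCG64), seed recorded in every output;
  fixed seed ⇒ bit-identical events and results.
- CSV floats are written at 17 significant digits and parsed with
  pandas' round-trip parser, so deposit files round-trip exactly.

## Problem sizes

The default analysis config uses 10⁴ cascade events and 200 water
reference tracks — enough for the zero-fraction and Δξ averages to
stabilize to a few percent while a full pipeline run stays around a
second; the test suite uses 10²–10⁴ events per case and finishes in well
under a minute.

## Known limitations

- The distance parameter a and Δξ obtained from the synthetic generator
  are internally consistent but not comparable to values derived from
  real Monte-Carlo track data; the published a values (0.122–0.234 μm)
  serve only as magnitude references in tests.
- The published TDRA RBE table cannot be regenerated from its own printed
  ξ′ and ζ (the printed values give ≈1.17 where 1.31 is tabulated,
  presumably from unrounded internals); that column is compared nowhere.
- Two published DER cells (membrane-scenario AGuIX) are unreachable from
  the printed two-significant-figure mean specific energy and are
  reported as known discrepancies by `reproduce-tables`.
- p₂ (in-nucleus kill probability) is carried in the data model but no
  published data constrains it; all fits set N₂ = 0.
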