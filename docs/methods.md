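# Methods

This note records the models, conventions and numerical choices behind the
package, in the order a dataset flows through it.

## Coordinate handling and the pigment registry

Structure I/O is delegated to gemmi; the package's own layer flattens the
model into plain atom records (coordinates in Å everywhere — no unit
conversion exists anywhere downstream) and resolves alternate locations
deterministically: for each atom name the highest-occupancy variant wins,
ties broken by altloc label order.

Pigment typing is pure data. The default registry maps the common chemical
component codes (CLA→Chl *a*, CHL→Chl *b*, BCR→β-carotene, DD6/DDX→
diadinoxanthin, PQN/PHQ→phylloquinone, SF4→Fe₄S₄, SQD/LHG/LMG/DGD→lipid)
and is fully overridable from YAML, because deposited models name pigments
by component code while papers name them chemically. A chlorin is usable
for geometry when it has its Mg or all four macrocycle nitrogens; anything
less is flagged degenerate and kept for censuses but excluded from dipole
and network computations.

Site labels follow the green-lineage antenna nomenclature: a chlorin with
residue number 600–699 is labelled e.g. "a603"; anything else is
"chain:resnum".

## Pigment geometry

* **Anchor.** The Mg position, falling back to the N-centroid when Mg is
  unmodelled. The same point serves as both the distance anchor (R is a
  Mg–Mg distance) and the point-dipole location, so orientation and
  distance are always mutually consistent.
* **Qy dipole.** Unit vector NB→ND of the macrocycle. This is the widely
  used convention; since κ² is invariant under dipole negation, only the
  axis matters, and the registry can switch it to NA→NC.
* **Ring plane.** Least-squares plane (smallest-singular-vector of the
  centered macrocycle N + inner-ring C coordinates). The normal's sign is
  fixed deterministically (positive z, then y, then x component). Collinear
  inputs (second singular value < 1e-9) are an error, not a garbage plane.
* **Cis/trans.** For backbone atoms a₁…a_N, bond *i* joins a_i and a_{i+1}
  and its dihedral is the torsion a_{i−1}–a_i–a_{i+1}–a_{i+2}; a bond is
  cis when |dihedral| ≤ 90°, with the boundary mapped to cis so the rule is
  deterministic. Cis positions are reported in backbone bond indices; the
  mapping to IUPAC carotenoid numbering (9-cis, 9,17-cis, …) depends on the
  residue's atom-naming scheme and is left to the registry's backbone list.
  Missing backbone atoms are reported as gaps and only the dihedrals that
  span them are skipped.
* **κ².** κ = μ̂_D·μ̂_A − 3(μ̂_D·R̂)(μ̂_A·R̂). The two projections are
  multiplied before the factor 3 so the result is bit-exact symmetric under
  donor/acceptor swap.

## Förster network

k = C κ² / (n⁴ R⁶) with R in Å and k in ps⁻¹, so C carries ps⁻¹·Å⁶. C and
n are almost never published alongside a structure; the defaults are C = 1
per class pair (relative rates only) and n = 1.55, a typical effective
protein refractive index. Both are configurable, including per-class-pair C
(Chl *b*→Chl *a* differs from Chl *a*→Chl *a*). Edges require R ≤ r_max
(default 30 Å — beyond this the R⁻⁶ factor makes rates negligible) and
κ² > 0; exactly-perpendicular geometries would contribute zero-rate,
infinite-τ edges and are excluded so path search terminates cleanly.

Pathway cost is the summed per-hop transfer time Σ 1/k, i.e. the mean
first-passage time of irreversible hopping along the chain; an alternative
−log(branching-probability) cost is available behind a flag. Ranking uses
Yen's k-shortest-paths over a virtual super-source/sink pair, with ties
broken by fewer hops and then lexicographic node order so output is
deterministic. The exhaustive simple-path enumeration used to validate it
in tests is an independent oracle, not the implementation.

Red-Chl candidate pairs are Chl *a* dimers with Mg–Mg ≤ 10 Å and ring
planes within 35°; these defaults capture the tightly clustered,
parallelogram-like a603–a609 geometry while excluding ordinary neighbours.

## Inventory

Censuses count registry-mapped residues by class and chain; protein chains
are chains with at least one standard amino-acid residue. Two totals are
printed with their definitions in the header: chromophores
(Chl a + Chl b + β-Car + Ddx) and cofactors (chromophores + PQN + Fe₄S₄ +
lipids) — published "pigment totals" are ambiguous between such
conventions, so both are always emitted and auditable. Mass estimates use
average (not monoisotopic) amino-acid residue masses plus one water per
protein chain plus registry cofactor masses; unknown residues go to a gap
report instead of silently vanishing. Chl *a/b* ratios return an explicit
"a-only" flag (None) for chains without Chl *b*, matching the behaviour of
Lhca-type antennae rather than reporting an infinity.

## TA global analysis

The parallel model treats the surface as independent exponentials convolved
with a Gaussian IRF. The convolution has the closed form
½·exp(σ²/(2τ²) − u/τ)·erfc(σ/(√2τ) − u/(√2σ)) with u = t − t0; for
positive erfc arguments it is evaluated as ½·erfcx(b)·exp(−u²/2σ²), which
is overflow-free at early delays even for nanosecond lifetimes (the naive
form overflows there).

Fitting is by variable projection: scipy's trust-region-reflective least
squares over {log τ_i, t0, log σ}, with the DADS solved exactly per iterate
by one matrix least-squares against the decay basis. Lifetimes are bounded
to [1e-3, 1e5] ps in log-space because photosystem kinetics span four
decades. Duplicate lifetimes make the basis rank-deficient and raise a
conditioning error rather than returning meaningless amplitudes. Outputs
are sorted by ascending τ with the spectra reordered to match, so "the
dominant trapping component" of a five-component fit is index 3 (fourth
slowest) by convention; components pinned at a bound or carrying a
near-zero DADS norm are flagged as redundant.

Chirp (dispersion) correction shifts each wavelength's time axis by a
polynomial t0(λ) (order ≤ 5 as an overfitting guard) and re-interpolates
linearly onto the common delay grid with edge values held.

Trapping efficiency is 1 − τ_trap/τ_intrinsic with a user-supplied
intrinsic excited-state lifetime; published quantum-efficiency figures use
unstated kinetic models, so this package makes no claim to reproduce any
particular one — the function is arithmetic, clearly defined, and its
inputs are the user's.

## Synthetic generators

Each generator emulates only the features its target operation consumes,
and writes its ground truth beside the data:

* **Chlorins**: Mg at the requested center, four N at 2.05 Å (typical Mg–N
  coordination) with NB→ND along the requested Qy axis (projected into the
  ring plane so extraction inverts generation exactly), plus eight in-plane
  ring carbons for the plane fit.
* **Polyenes**: zig-zag backbones (1.45 Å bonds, 120° angles) with 180°
  dihedrals except 0° at the planted cis bonds, built by torsion-driven
  chain extension.
* **Toy complexes**: chlorins placed uniformly in a box by rejection
  sampling with a minimum Mg–Mg separation (default 8 Å, about the closest
  packing in real antennae), isotropic orientations; the ground-truth edge
  table is computed by an explicit brute-force double loop over the planted
  vectors, independent of the structure pipeline. A "PSI-like" preset uses
  16 antenna chains of 8–16 chlorins plus an 88-chlorin core chain,
  echoing the supercomplex architecture at realistic network size.
* **TA surfaces**: Σ DADS_i(λ)·decay_i(t) with Gaussian spectral bands
  (signs allowed, emulating excited-state absorption vs ground-state
  bleach) and homoscedastic Gaussian noise — real TA noise is structured
  (probe-referencing, scatter around time zero), so recovery results on
  synthetic surfaces bound, rather than guarantee, real-data performance.

The reproduction-run convention for the five-component system is lifetimes
0.36 / 3 / 15 / 72 / 2500 ps with the dominant amplitude on the 72 ps
component; the 3 ps value is a declared convention for a component known
only to lie at "a few picoseconds". Axes are 150 log-spaced delays from
0.05 ps to 7 ns and 60 wavelengths over 640–760 nm, noise 1% of the peak
band amplitude; fits start from lifetimes randomly perturbed by factors in
[1/3, 3]. These problem sizes make a single fit run in well under a second
while leaving every lifetime identifiable.

## Known limitations

* Point-dipole Förster only: no transition-charge (TrEsp/TDC) couplings, no
  excitonic delocalization, no site energies, no master-equation kinetics.
  Absolute rates additionally require measured C and n.
* The parallel model cannot express sequential/target kinetics; DADS of a
  parallel fit are mathematical amplitudes, not species spectra.
* Chain→subunit naming (e.g. mapping deposited chain IDs to LHCE 1–16) is a
  user-supplied mapping; no sequence-level identification is attempted.
* No symmetry expansion, density-map handling, or model building.
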