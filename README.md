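# pigment-eet

Structural and spectroscopic analysis of excitation-energy transfer (EET) in
photosystem–antenna supercomplexes, built for the *Euglena gracilis*
PSI–LHCE system but applicable to any chlorophyll-binding pigment–protein
complex for which an atomic model is available.

Photosynthetic supercomplexes funnel absorbed photons through hundreds of
chlorophylls to a reaction center within ~100 ps. Given a cryo-EM (or X-ray)
coordinate model, this package answers the questions a structural
photosynthesis study asks of it:

* **Pigment inventory** — per-chain and total censuses of Chl *a*, Chl *b*,
  β-carotene, diadinoxanthin (Ddx), phylloquinone, Fe₄S₄ clusters and
  lipids; Chl *a/b* ratios; mass estimates; closest-approach distance
  reports.
* **Pigment geometry** — Mg anchors and Qy transition dipoles of the chlorin
  macrocycles, least-squares ring planes and inter-plane angles, polyene
  dihedral scans with cis/trans isomer classification (e.g. a 9,17-*cis*
  carotenoid), and detection of tightly coupled near-coplanar "red-Chl"
  dimers such as the a603–a609 pair.
* **Förster rate networks** — pairwise rate constants in the point-dipole
  approximation, inter-subunit summed-rate matrices, and ranked fastest
  energy-transfer pathways from antenna to core.
* **Transient-absorption global analysis** — variable-projection fitting of
  the parallel (sum-of-exponentials ⊗ Gaussian IRF) model to ΔA(delay,
  wavelength) surfaces, yielding decay-associated difference spectra (DADS)
  and kinetic lifetimes, plus chirp correction and trapping-efficiency
  arithmetic.
* **Synthetic data** — seeded generators for chlorins, polyenes, multi-chain
  toy complexes and TA surfaces, each carrying its exact ground truth, so
  every stage is testable without downloading a deposited model.

## The core quantities

The Förster rate between a donor and acceptor chlorophyll is

```
k_FRET = C κ² / (n⁴ R⁶)
```

where *R* is the Mg–Mg distance (Å), *n* the refractive index, *C* an
overlap-integral factor per pigment-class pair (in ps⁻¹·Å⁶), and the
orientation factor

```
κ = μ̂_D·μ̂_A − 3 (μ̂_D·R̂)(μ̂_A·R̂),   κ² ∈ [0, 4],  ⟨κ²⟩_iso = 2/3
```

couples the unit Qy transition dipoles μ̂ (taken along the NB→ND axis of the
macrocycle) with the separation direction R̂. The per-hop transfer time is
τ = 1/k, and pathway costs are summed transfer times. Because *C* and *n*
are rarely published, the default *C* = 1 gives **relative** rates; both are
configurable.

The TA parallel model describes the surface as

```
ΔA(t, λ) = Σ_i DADS_i(λ) · [exp(−t/τ_i) ⊗ IRF_σ](t)
```

with the IRF-convolved exponential in closed form
(`½ exp(σ²/2τ² − t/τ) erfc(σ/√2τ − t/√2σ)`). Lifetimes enter nonlinearly
and are optimized in log-space; the DADS enter linearly and are projected
out exactly at every iterate (variable projection).

## Worked example

```python
import numpy as np
from pigment_eet import (FretParams, build_network, cofactor_census,
                         extract_pigments, fastest_paths, make_toy_complex,
                         fit_parallel_model, simulate_ta)
from pigment_eet.synthetic import (EGRACILIS_LIFETIMES_PS,
                                   EGRACILIS_DADS_BANDS, default_ta_axes)
from pigment_eet.tafit import fit_report

model, truth = make_toy_complex(n_chains=3, chlorins_per_chain=6, seed=7)
census = cofactor_census(model)
print(census.n_chromophores, census.totals)   # 18 {'CHL_A': 18}

net = build_network(extract_pigments(model), FretParams())
for path, cost in fastest_paths(net, "A", "C", 2):
    print(" -> ".join(path), f"{cost:.2f} ps")

delays, wl = default_ta_axes()
surface, _ = simulate_ta(EGRACILIS_LIFETIMES_PS, EGRACILIS_DADS_BANDS,
                         delays, wl, irf_sigma=0.1, noise_sd=1e-4, seed=1)
rng = np.random.default_rng(1)
inits = np.array(EGRACILIS_LIFETIMES_PS) * 3.0**rng.uniform(-1, 1, 5)
print(fit_report(fit_parallel_model(surface, 5, inits)))
```

prints (abridged):

```
18 {'CHL_A': 18}
A:605 -> B:603 -> C:604 34897084.16 ps
A:606 -> C:601 43468815.59 ps
# parallel-model global fit
n_components    5
rss     8.656228e-05
lifetimes_ps    0.357793  3.18831  13.746  72.5971  2533.17
```

The five recovered lifetimes sit within a few percent of the planted
0.36 / 3 / 15 / 72 / 2500 ps ground truth — the dominant fourth component is
the ~72 ps antenna→core trapping time, and the ~2.5 ns component plays the
role of uncoupled antenna. (Path times are huge here only because the toy
complex uses the relative-rate default *C* = 1.)

A `pigment-eet` CLI wraps the same functions: `extract`, `geometry`,
`census`, `distances`, `fret`, `paths`, `tafit`, `simulate` — run
`pigment-eet --help`.

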