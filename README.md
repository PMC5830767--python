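# membranekit

Analysis of collective lipid-tail dynamics and lateral membrane
organization from coherent inelastic neutron scattering and molecular
configurations — built for oriented DMPC/cholesterol multibilayers with
and without small membrane-active molecules such as aspirin (ASA).

In cholesterol-containing DMPC membranes, three coexisting phases (gel,
fluid and liquid-ordered, the raft proxy) each carry their own phonon
branch in the in-plane dynamic structure factor S(q∥, ω). The package
implements the full chain from raw instrument scans to physical
parameters, plus synthetic-data generators with attached ground truth so
every stage can be validated end to end:

* **Spectral fitting** of constant-q∥ energy scans with an elastic
  Gaussian (fixed instrument width σ_el), an incoherent Lorentzian pinned
  at ω = 0, a linear background, and up to three phonon doublets whose
  anti-Stokes amplitudes follow detailed balance,
  A₋ = A₊ e^(−ℏω/k_BT); constant-energy scans with free Lorentzian peaks
  on an empirical exponential background.
* **Phonon-count selection** by sequential nested-model F-test,
  F_χ = (χ²(m) − χ²(m+4)) / (χ²(m+4)/(N−m−1)), with configurable
  degrees-of-freedom policy.
* **Dispersion analysis**: pooling (q∥, ℏω) points from both scan types,
  branch assignment by anchor curves, and weighted fits of the empirical
  minimum ℏω = α(q∥−q∥₀)² + ℏω₀, where ℏω₀ tracks lipid order and α is a
  softness metric; two-sample z comparison between samples.
* **Lamellar analysis**: Bragg-series detection and integration,
  d_z = 2π/Δq_z, Fourier reconstruction
  ρ(z) = Σ √(I_n q_n) ν_n cos(2πnz/d_z) with supplied ±1 phases, the
  head–head spacing d_HH from the headgroup minima, and the hexagonal
  area per chain A_T = 8π²/(√3 q_T²).
* **Configuration analyses**: per-leaflet lateral RDFs, grid-tessellation
  area per lipid, distance-resolved area and gauche-defect profiles
  around aspirin, electron / neutron scattering-length density profiles
  with deuteration handling, and close-contact statistics.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Generate a noisy constant-q scan from the default three-branch dispersion
(minima at 0.6/1.1/1.8 meV), select the phonon count by F-test, and
inspect the chosen fit:

```python
import membranekit as mk

scan = mk.simulate_constant_q_scan(mk.DispersionSpec.well_separated(),
                                   q=1.4, sigma_el=0.2, seed=11)
sel = mk.sequential_f_test(scan)
print(sel.summary())
print(sel.chosen_fit.summary())
```

```
Sequential F-test (alpha = 0.025, df policy = standard)
  adding phonon 2: F_chi = 39.78  critical = 11.71  -> accept
  adding phonon 3: F_chi = 62.32  critical = 11.73  -> accept
  chosen phonon count: 3

Constant-q spectral fit
  phonons: 3   converged: True
  chi2 = 87.23  (N = 108, free params = 14)
  elastic A = 8049  (sigma_el fixed at 0.2 meV)
  incoherent A = 479.3, HWHM = 0.5956 meV
  background: -3.322·ω + 74.52
  P1: mu = 0.5964 ± 0.0135 meV, sigma(HWHM) = 0.1448 ± 0.0383 meV, A+ = 224.7
  P2: mu = 1.1224 ± 0.0184 meV, sigma(HWHM) = 0.2446 ± 0.0467 meV, A+ = 179.4
  P3: mu = 1.8269 ± 0.0137 meV, sigma(HWHM) = 0.2857 ± 0.0354 meV, A+ = 160.4
```

Both increments clear their critical values, so three phonon modes are
retained; the fitted positions recover the generator's 0.6/1.1/1.8 meV
within one to two standard errors.

The elastic side reads structural parameters from a forward-modelled
nine-order lamellar Bragg series:

```python
refl = mk.simulate_reflectivity(seed=11)              # d_z = 61.1 Å truth
peaks = mk.find_bragg_peaks(refl)
profile = mk.reconstruct_sld(peaks, refl.meta["truth"]["phases"])
print(f"d_z  = {peaks.d_z:.2f} Å")
print(f"d_HH = {mk.head_head_spacing(profile):.2f} Å")
print(f"A_T(q_T = 1.37 Å⁻¹) = {mk.area_per_tail(1.37):.2f} Å²")
```

```
d_z  = 61.09 Å
d_HH = 45.79 Å
A_T(q_T = 1.37 Å⁻¹) = 24.29 Å²
```

The repeat spacing comes back within 0.02% of the generator truth, the
head–head spacing matches the band-limited profile's head-minimum
separation, and the area per chain at the measured chain-correlation peak
is the hexagonal-packing value.

A `membranekit` command-line entry point wraps the same operations
(`fit-spectrum`, `select-model`, `fit-dispersion`, `elastic`, `inplane`,
`simulate`, `run`); `run --config cfg.yaml` executes the full neutron or
MD workflow and writes JSON/TSV report bundles.

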