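# Methods

`membranekit` analyses the collective short-wavelength dynamics and lateral
organization of oriented DMPC/cholesterol/aspirin multibilayers from two
kinds of input: triple-axis neutron-spectrometer scans, and membrane
configuration frames of the kind produced by atomistic simulation. This
note records the models, the numerical choices, and what the synthetic
generators do and do not emulate.

## Spectral model for constant-q energy scans

A constant-q scan is modelled as

    I(ω) = A_el exp(−ω²/2σ_el²) + mω + b
         + Σ_{i=1..k} [ A₊ᵢ/(1+(ω−μᵢ)²/σᵢ²) + A₋ᵢ/(1+(ω+μᵢ)²/σᵢ²) ]
         + A_inc/(1+ω²/σ_inc²)

with ω the energy transfer in meV, positive on the neutron-energy-loss
(Stokes) side. The elastic Gaussian is pinned at ω = 0 with the
instrument-supplied width σ_el (0.3 meV and 0.2 meV for the two standard
spectrometer configurations; the full 4-D resolution-ellipsoid convolution
is out of scope — the width at the dispersion minimum is closest to the
true damping because the dispersion slope vanishes there, and widths are
therefore compared at the q nearest each branch minimum). The incoherent
Lorentzian is pinned at ω = 0 with its width bounded above by 1.5 meV — a
quasi-elastic line much broader than that would be indistinguishable from
background and tends to swallow low-lying phonons. Anti-Stokes amplitudes
are never fitted: A₋ = A₊·exp(−μ/k_B T) by detailed balance
(k_B = 0.0861733 meV/K, default T = 303.15 K).

σᵢ is the Lorentzian half-width at half-maximum; `PhononMode.fwhm` gives
2σᵢ for comparison with either width convention.

Fitting is bounded weighted least squares (lmfit Levenberg–Marquardt) on
(model − counts)/error. Initialisation is multi-start: a background-only
fit, peak picking on the smoothed weighted residual of its Stokes side,
then the best-scoring k-combinations of the candidate positions (plus a
user-supplied warm start); the lowest-χ² optimum is kept. Mode positions
are re-sorted by μ after fitting (label-switching guard). Phonon HWHMs are
bounded below by one grid step so a single noisy point cannot pose as a
phonon, and a mode narrower than 1.5 grid steps, or with amplitude below
twice its standard error, is reported as "not detected". When the
optimiser's covariance is singular (typically an amplitude collapsed to
zero making its width unidentifiable), standard errors are recovered from
a finite-difference Jacobian restricted to parameters away from their
bounds; if phonon errors remain unavailable the fit is flagged
non-converged rather than raising.

Constant-energy q-scans use an empirical exponential background, a broad
background Lorentzian initialised (but not fixed) at 2.5 Å⁻¹, and k free
Lorentzian peaks in q; all parameters are free.

## Phonon-count selection

Models with one, two and three phonon doublets are fitted successively
(each richer fit warm-started from the simpler optimum, which enforces the
nested-model χ² decrease). Each increment is scored with

    F_χ = (χ²(m) − χ²(m+4)) / (χ²(m+4)/(N − m − 1)),

where N is the number of points and m the simpler model's parameter count
in the conventional accounting (6 background parameters, 4 per phonon).
Note that F_χ is the χ² drop divided by the richer model's *reduced* χ² —
it is not divided by the number of added parameters — so the conventional
additional-term F-test compares F_χ/df₁ with the F(df₁, df₂) quantile;
the critical value on the F_χ scale is df₁ times the quantile. Degrees of
freedom are a configurable policy: `standard` (df₁ = 4 added parameters,
df₂ = N − m − 5, the default), `paper` (df₁ = 1, df₂ = N − m − 1, matching
the statistic's printed denominator), or an explicit pair; α defaults to
0.025. An increment is accepted when F_χ exceeds its critical value, and
the chosen count is the largest sequentially accepted. The decision logic
is exposed separately (`accept_increments`) so published (F_χ, critical)
pairs can be replayed directly.

Free-position multi-start fitting carries a look-elsewhere effect: the
added mode is free to sit on the largest noise feature anywhere in the
scan, so the realised false-acceptance rate is somewhat above the nominal
α. At the default generator statistics this procedure still keeps both
error rates below 5% over 100 seeds (verified in the acceptance suite).

## Dispersion analysis

Detected modes from constant-q fits (fixed q, fitted μ) and constant-E
fits (fitted q, fixed E) are pooled into (q∥, ℏω) points and assigned to
gel / fluid / liquid-ordered branches by nearest piecewise-linear anchor
curve in unit-normalised (q/1 Å⁻¹, ω/1 meV) coordinates; ties go to the
branch with lower anchor energy, and points beyond a configurable cutoff
stay unassigned. Anchor curves are configuration, not algorithm — the
source experiments assigned branches by visual correspondence with earlier
work, so defaults follow that morphology (steep gel branch, broad fluid
minimum near 1.1 meV, lowest-lying liquid-ordered minimum).

Each branch minimum is fitted with ℏω = α(q∥−q∥₀)² + ℏω₀ by weighted
least squares over 1.0–2.0 Å⁻¹ (default). α is an empirical softness
metric, ℏω₀ tracks lipid order. Samples are compared parameter-by-
parameter with the two-sample statistic z = |p_a − p_b|/√(se_a²+se_b²),
flagged at z > 1.96 (5% two-sided; the source states significance without
a procedure, so the conventional threshold is used, and the six-comparison
table can also be viewed Bonferroni-adjusted). Very large printed
uncertainties (the gel branch) are carried through without special-casing.

## Lamellar analysis

Out-of-plane reflectivity is searched for Bragg maxima (prominence
threshold, minimum peak separation 0.01 Å⁻¹); each is fit by a Gaussian
plus local linear background over a ±3·FWHM window, integrated intensity
= Gaussian area. Harmonic orders come from rounding q/Δq̂ with Δq̂ the
median successive spacing (a missing order does not shift labels);
d_z = 2π over the slope of the through-origin regression of q_n on n, with
a warning when peaks deviate from equidistance by more than 2%.

The relative scattering-length-density profile is

    ρ(z) = Σ_n √(I_n q_n) ν_n cos(2πnz/d_z)

on a ≤0.25 Å grid over one repeat, with the ±1 phase array ν_n supplied as
input (for these stacked systems the established phase sequence is
[1 −1 −1 −1 −1 1 1 −1 1]). √q_n is the Lorentz factor for oriented
multilayers; the amplitude is then |F_n| so a forward model
F_n = ∫ρ cos(2πnz/d_z) dz, I_n = F_n²/q_n round-trips exactly. For
chain-deuterated bilayers the profile's interior minima sit in the
headgroups; d_HH is the separation of the deepest interior minimum on each
side of the centre, refined by three-point parabolic interpolation
(edge extrema never qualify; asymmetry beyond 1 Å warns).

The in-plane chain-correlation peak q_T is fitted by a Lorentzian over
1.2–1.6 Å⁻¹ with the silicon/aluminium contaminant windows near 1.25, 1.7
and 1.95 Å⁻¹ masked. The area per acyl chain assumes hexagonal packing:
A_T = 8π²/(√3 q_T²).

## Lateral analyses of membrane frames

All configuration analyses are deterministic. Reference anchors: DMPC →
phosphorus atom, cholesterol → hydroxyl oxygen, aspirin → lateral centre
of mass (minimum-image unwrapped). Leaflets are assigned per frame by the
sign of the anchor's z relative to the lipid centre.

* **Lateral RDF** — in-plane minimum-image distances, same-leaflet pairs
  by default (a flag restores cross-leaflet pairs), normalised by the
  ideal two-dimensional density so g → 1 for homogeneous systems;
  periodic pair counting via a KD-tree. 3-D mode uses spherical shells.
* **Grid area per lipid** — the leaflet plane is tiled with ≤0.5 Å cells,
  each claimed by the nearest anchor (periodic images included); a
  lipid's area is its cell count times the cell area, so per-leaflet
  areas sum exactly to Lx·Ly. Cholesterol either competes for cells
  (default) or is excluded ("DMPC-only" areas) by policy. Aspirin never
  claims cells: it resides in the headgroup plane between lipids.
* **Distance-resolved profiles** — each DMPC is binned (half-open bins,
  default 2 Å) by same-leaflet lateral distance to the nearest aspirin;
  the binned statistic is its grid area or its tail gauche fraction.
  Shell membership for the gauche profile is recomputed every 50 frames
  by default and cached between updates, matching the index-file cadence
  of the original protocol; SN1/SN2 tails are averaged.
* **Gauche classification** — dihedrals are computed from chain beads
  (minimum-image unwrapped), trans at ±180° (IUPAC); gauche is |φ|<120°.
  Ryckaert–Bellemans input (trans at 0°) is shifted on entry so the
  classification is convention-independent; the threshold itself is a
  package choice since none is stated in the source analyses.
* **Density profiles** — z-histograms (≤1 Å bins) centred on the lipid
  centre, weighted by electrons per element or coherent neutron
  scattering lengths with an explicit deuteration selection (b_H = −3.74,
  b_D = +6.67 fm), conserving each group's totals exactly.
* **Contacts** — the hydrogen-bond observation is proxied by heavy-atom
  pairs within a 3.5 Å cutoff (3-D minimum image), reported as per-
  molecule-pair time fractions. No angular criterion is applied; the
  source reports the interaction from visual inspection.

## Synthetic generators

Generators draw from integer-seeded streams (`default_rng([seed, tag])`),
so fixed seeds give identical outputs, and attach their ground truth to
the output's `meta`; tests read truth only from those attachments.

**Scans.** Branch dispersions are quadratic minima; the default
three-branch set has well-separated minima at 0.6/1.1/1.8 meV (q₀ = 1.4
Å⁻¹), and the cholesterol-sample (α = 41/14.9/4.8 meV·Å², ℏω₀ =
0.72/1.09/0.51 meV, l_o width 0.14 meV) and aspirin-sample (1.5/11.0/3.7,
0.65/1.12/0.66, l_o width 0.31 meV) sets are shipped as presets. Counting
statistics (elastic amplitude 8000 counts, phonon amplitudes 160–240
counts, 108-point grid over −2…4 meV) are set so the nested-model F
statistics fall in the range the published fits report (≈90 for the second
phonon, ≈18 for the third); noise is Poisson on the expected counts.
Constant-E scans place Lorentzians at the quadratic's q-roots with
amplitudes scaled by the inverse local dispersion slope (bounded), on an
exponential background plus a broad Lorentzian near 2.5 Å⁻¹.

**Reflectivity.** The default profile is the nine-harmonic cosine series
of a Gaussian bilayer morphology (tail maxima at |z| ≈ 10 Å, headgroup
minima at d_HH/2 = 23 Å, a deuterated-water/tail maximum at the repeat
edge) with weak harmonics floored at 12% of the strongest so that all nine
orders carry measurable intensity, as in the experiments. Being
band-limited, its form factors are exact and the reconstruction has an
analytic truth, including the band-limited head-minimum separation.

**Membrane frames.** Acyl tails sit on a hexagonal lattice; each lipid
owns two x-adjacent tail sites, so the realised lipid area is √3·s². The
spacing follows from the target area (48.6 Å² → 5.30 Å) unless
`tail_spacing` is set explicitly (4.8 Å → 39.9 Å²); space filling forbids
honouring both at once — the real system reconciles chain packing with the
larger lipid area through its cholesterol content, which this coarse
construction does not attempt. Chains are grown bead-by-bead with ideal
bond geometry (1.54 Å, 111°) and per-dihedral gauche draws (±60° vs 180°,
8° jitter), zigzag plane perpendicular to the tail-pairing axis so straight
tails keep their lattice positions. Aspirin occupies a configurable subset
of the oblique superlattice (a = 21.2 Å, b = 18 Å, γ = 103°) in the
headgroup plane; cholesterol is placed on rings (11.5 and 19 Å) around
aspirin, keeping clear of all aspirin centres (the arrangement the
simulations report), with the nearest DMPC site vacated per cholesterol;
without aspirin it substitutes random sites. Local area dilation near
aspirin is a radial displacement field with ≈ +δ areal strain out past the
first neighbour shell, decaying over a wide annulus so the compensating
compression is spread thinly (as a barostatted membrane would); with the
full superlattice occupied, neighbouring fields overlap and the apparent
dilation is reduced — profile tests therefore use sparse aspirin. Water is
three-bead (O + 2H) in slabs outside the headgroup planes.

The frames emulate positions and labels only: no chemistry, no realistic
cholesterol geometry, no membrane undulations, no z-fluctuations of
lipids, and chain gauche states are independent between dihedrals. Passing
tests therefore validate the *analysis operations* — binning,
normalisation, tessellation, classification — on inputs with known truth;
they say nothing about force-field realism.

## Problem sizes and statistical checks

The acceptance suite uses 100 seeds for model-selection consistency and
parameter recovery (the counts at which ≥95%/≥90% bounds are meaningful),
12-point dispersion branches, 512-lipid frames with 2–3 frames per
condition, and 10-seed pooling for the width-discrimination check.
Interval-coverage checks count parameter estimates individually: the joint
probability that three 2σ intervals simultaneously cover is ≈0.87 even
for a perfectly calibrated fit, so a joint criterion at 90% would be
statistically unattainable by construction.

## Known limitations

* Phonon widths are not deconvolved from the instrumental resolution;
  they are compared at the dispersion minimum where the resolution bias is
  smallest.
* The branch-assignment anchors encode prior knowledge of the dispersion
  morphology; with badly mis-specified anchors points are silently
  assigned to the wrong branch (the cutoff mitigates this).
* The grid area map's cell assignment is a nearest-anchor tessellation,
  not a true Voronoi decomposition weighted by molecular shape.
* The F-test's printed-convention bookkeeping (6 + 4k parameters) counts
  more free parameters than the implementation actually varies (the
  elastic width is fixed and anti-Stokes amplitudes are derived); both
  counts are reported in fit results.
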