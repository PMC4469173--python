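# Methods

This note documents the model implemented by `ritdose`, the choices made
where the design was genuinely open, and the known limits of the
simplified engine.

## Decay data and beta spectra

Each packaged isotope carries its physical half-life, its electron and
photon multiplicities per decay (`p_e`, `p_γ`), one effective gamma line,
and its beta branch structure, stored as a human-readable YAML table under
`src/ritdose/data/nuclides/`.

Continuous beta spectra use the theoretical allowed shape
`N(E) ∝ F(Z,E) p W (W0−W)²` with the non-relativistic Fermi Coulomb factor
`F = x/(1−e^(−x))`, `x = ±2παZ W/p`.  Real decay schemes are not purely
allowed (⁹⁰Y in particular is a first-forbidden unique transition), so the
raw allowed shape misstates the mean energy by up to ~10%.  Because the mean
beta energy is the dominant dosimetric driver at this fidelity, branch
endpoints are **calibrated at load time**: a single scale factor per nuclide
(per branch for ¹²⁴I, whose two positron branches have individually
tabulated means of 0.686 and 0.974 MeV) is solved by bisection so that the
yield-weighted spectrum mean reproduces the tabulated value exactly.  The
calibrated endpoints therefore differ from the physical ones by up to ~10%;
the spectral *shape* is approximate, the mean is exact.

Two further simplifications, both toggleable or documented:

* all `p_γ` photons are emitted at the main line energy, although `p_γ`
  aggregates minor lines whose energies are not tabulated;
* ¹²⁴I positrons are transported as electrons, and annihilation-photon
  emission is off by default (`include_annihilation=True` adds two 511 keV
  photons at each positron stopping point).

## Geometry

The tumour is a sphere of radius `r_T` filled with 250 µm-radius spherical
cell clusters whose centres sit on a simple cubic lattice with spacing one
cluster diameter; a cluster belongs to the tumour if its centre is within
`r_T` (centre-in-sphere rule).  The surrounding lung is a 4 cm-thick shell
of identical subunits on the same lattice.  The lattice registration
("origin": a cluster centred at the origin; "half": shifted half a spacing
per axis) is configurable because no counting rule reproduces every
published cluster count; with the default origin registration a 0.5 cm
tumour holds 4169 clusters.  Densities default to ICRU-44 soft tissue
(1.06 g/cm³) and inflated lung (0.26 g/cm³).

Energy is tallied on concentric spherical shells of 0.05 cm thickness with
half-open radial bins `[r_i, r_{i+1})`; cluster centres falling exactly on
the outermost edge are assigned to the last shell so the FSU partition is
exhaustive.

## Sources, activity and cumulated decays

Every cluster surface is a potential emission site.  Antibodies per cluster
are `4πr² × covering fraction`; the tumour activity is
`A = λ_phys n_u n_a n_mAb` and cumulated decays are `A/λ_eff` with
`λ_eff = λ_phys + λ_bio` per compartment (tumour `T_bio` 2–6 d, default 6;
lung 3 d).  An uptake delay multiplies `n_a` by `e^(−λ_phys·t)`; the
published direct→two-day atom-count pairs are reproduced exactly by
applying this factor to the *real-valued* minimal count before ceiling.

Radial emission weighting inside the tumour: uniform; linear `w = r/r_T`
(zero at the centre); exponential `w = e^((r−r_T)/ℓ)` with `ℓ` set by a
configurable centre-to-surface weight ratio (default 0.01).  The original
description gives no formulas for the non-uniform profiles; these are the
simplest shapes matching it, and both are configurable.  Weights are
normalised so the *mean* tumour cluster weight is 7× the (uniform) lung FSU
weight; for the uniform shape the per-cluster ratio is exactly 7.

A consequence worth stating plainly: the 4 cm lung shell around a 0.5 cm
tumour contains ≈3×10⁶ FSUs, so under the per-cluster 7:1 rule the lung
compartment carries ≈400× the tumour activity and its *self-dose* dominates
the mean lung dose (tens of Gy per unit loading at a 10¹⁰ cm⁻² covering
fraction).  Published lung doses for this setup are several-fold lower,
implying a different — and not recoverable — lung activity normalisation;
absolute NTCP levels from this package are correspondingly conservative
(higher).  Tumour-side quantities are unaffected, and the lung source can
be disabled (`include_lung_source: false`) when only the tumour-bound
nanoobjects' dose shape is of interest.

## Transport engine

A deliberately simplified stand-in for a condensed-history code:

* **Electrons**: straight-line continuous-slowing-down tracks.  Step length
  is capped at 0.025 cm (half a tally shell) and at a 5% fractional energy
  loss; each segment deposits `S_lin·ds` into the shell containing its
  midpoint; below the 5 keV cut-off the residual is deposited locally.  No
  multiple-scattering deflection, no bremsstrahlung.
* **Photons**: free paths sampled from the total attenuation coefficient of
  the medium at the step's start point; each interaction deposits the
  energy-absorption fraction `μ_en/μ` locally (kerma approximation) and the
  remainder continues isotropically until cut-off or escape.
* One history = one disintegration; electron and photon multiplicities are
  floor-plus-Bernoulli with the tabulated expectations.  Escaped energy is
  tracked, so emitted = deposited + escaped closes to within Monte Carlo
  error by construction of every termination path.
* Uncertainties are batch-mean standard errors (10 batches by default);
  `estimate_required_histories` extrapolates by the 1/√N law.

Shell-averaged doses over 0.5 mm shells are accurate at the ~10–20% level
under straight-track CSDA; the known biases are an overestimated dose at
large radii (no angular straggling shortens real tracks radially) and a
crude spatial distribution of scattered-photon dose.  These are fidelity
limits of the engine, and the test suite asserts only shape- and
conservation-level properties of the transport, not absolute dose tables.

## Material data

Tables are generated from closed-form physics rather than shipped files:
Berger–Seltzer collision stopping power for a water-like medium
(Z/A = 0.55, I = 75 eV, no density-effect correction), CSDA ranges by
integrating its inverse, Klein–Nishina incoherent scattering (total and
energy-transfer cross-sections) plus an `E⁻³` photoelectric term calibrated
to water's low-energy attenuation.  Soft tissue and lung share the
mass-basis tables and differ by density — the dominant contrast between the
two media for this problem.  Accuracy is a few percent for electrons and
~10–30% for photon coefficients below ~50 keV; NIST-grade cross-sections
are out of scope.  The engine accepts any tables satisfying the
`MaterialTable` invariants.

## Radiobiology

`BED(r) = D(r) + [λ_eff/(λ_eff+μ)]·D(r)²/(α/β)` — the protracted-exposure
LQ form with mono-exponential dose rate and sublethal-damage repair rate
`μ`; no repopulation term.  Cluster kill is Poisson,
`p = exp(−N·e^(−α·BED))` with `N = ρ_cell·V_cluster` (≈6218 cells).
TCP is the product of `p^{K_r}` over tumour shells, with `K_r` from
cluster-centre binning, accumulated in log space (verified against the
brute-force per-cluster product to 1e-12 on toy tumours).  Parameter sets:
tumour α = 0.35 Gy⁻¹, α/β = 10 Gy, μ = 1.39 h⁻¹; lung α = 0.031 Gy⁻¹,
α/β = 3 Gy, μ = 0.46 h⁻¹; cell density 9.5×10⁷ cm⁻³ for both.
Radiosensitivity is uniform (no hypoxic subpopulations).

"TCP of 100%" is operationalised as TCP ≥ 0.99 (configurable): published
values are rounded to integer percent and define no cutoff.  Under these
parameters the minimal uniform dose for control of the 0.5 cm geometry
computes to ≈58 Gy, inside the published 46–64 Gy band of minimal
centre/surface doses.

## NTCP models

* **LKB**: probit in the physical mean lung dose, TD₅₀ = 30.8 Gy, m = 0.37
  (external-beam pneumonitis values; none exist for radioimmunotherapy).
* **Relative seriality**: s = 0.0061, K = 76 394 192 FSUs (5000 cm³ / FSU
  volume), driven by the per-FSU kill probability at the *mean lung BED*.
  Evaluated in log space with explicit underflow branches so that
  K ≈ 7.6×10⁷ and extreme `p` are handled exactly.
* **TRU**: complication when all tissue-rescue units die,
  `NTCP = Π_r exp(−N_r·e^(−α·BED(r))·v^c)` over lung shells, c = −0.98,
  v = 1.  The published typography is ambiguous about where `v^c` acts;
  the multiplier-on-the-lethality-exponent reading is the default and an
  alternative (`v^c` scaling the kill exponent) sits behind the same
  function's `reading` switch.  Note that raising the completed product to
  `v^c` is algebraically identical to the default.

That LKB consumes physical dose while the other two consume BED mirrors how
each model's parameters were originally reported; the mixture is retained
deliberately.

## Scans

One transport run per source compartment is performed at one atom per
nanoobject; dose is linear in `n_a`, so the scan reuses the tallies and
re-evaluates only BED/TCP/NTCP per grid point (the scaling shortcut is
asserted equal to re-running dosimetry to 1e-12).  The minimal loading is
the real-valued TCP-threshold crossing found by bisection; `direct` is its
ceiling and `two_day` is the ceiling after the 48 h decay factor.

## Synthetic data

The generator module provides everything the pipeline consumes: material
tables (above), miniature lattice tumours (5–100 clusters, closest-site
first with seeded tie-breaking) for brute-force oracles, and randomized LQ
parameter sets within physiological bands (α ∈ [0.01, 1] Gy⁻¹,
α/β ∈ [1, 20] Gy, μ ∈ [0.1, 3] h⁻¹, T_bio ∈ [1, 10] d) for property tests.
Everything regenerates byte-identically from its seed.  What the fixtures
do **not** emulate: realistic decay-scheme detail (conversion electrons,
minor gamma lines), evaluated cross-section accuracy, non-spherical
tumours, or time-resolved uptake kinetics — passing tests therefore
validate the modelling chain's internal correctness and its qualitative
physics, not clinical dosimetry.

## Problem sizes and numerical choices

Default runs use 2×10⁴–1.5×10⁵ histories: energy-balance checks use 10⁵
(balance closes within 3 batch-mean SE), and dose-shape comparisons of the
uniform distribution use 1.5×10⁵ because the innermost tally shell
(5×10⁻⁴ cm³) collects few events from short-range emitters.  The TCP
bisection is deterministic given a tally (xtol 1e-9).  All stochastic
stages take one integer seed through `numpy.random.default_rng`;
identical seeds give bit-identical profiles, files and manifests.

## Known limitations

* No electron multiple scattering, bremsstrahlung, or secondary-electron
  transport from photon interactions; no charged-particle-equilibrium
  corrections.
* Published dose tables for this problem are not bit-reproducible here (and
  their internal normalisations — covering fraction 10⁹ vs 10¹⁰, lung
  activity — are mutually inconsistent); the package targets the physics
  properties and orderings instead, with the covering fraction always
  explicit in configurations.
* Single-injection, instantaneous-uptake kinetics only; no fractionation,
  no administered-activity prescription.
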