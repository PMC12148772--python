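# Methods

This note records the physical model behind `kvdose`, the choices made
where the design was genuinely open, and the limits of what the packaged
tests demonstrate.

## Scope and model overview

The package models a superficial therapy unit with three techniques
(50, 70, 100 kVp; stated half-value layers 0.45, 1.10, 2.10 mm Al), a
tungsten target behind a 0.8 mm beryllium window, a 2 cm diameter
circular field and 15 cm source-to-surface distance.  The vendor's head
geometry is not public, so the treatment head is replaced by an analytic
point source with a filtered analytic spectrum.  All reported quantities
are dose *ratios* (percent depth dose, bone enhancement, transmission
ratios), which are insensitive to the spatial detail of the source at
this SSD and field size; absolute output calibration (the machine's
stated cGy output has no published time base) is deliberately excluded.

## Beam spectrum

Unfiltered continuum: Kramers form, intensity ∝ (kVp − E), converted to
fluence per energy by dividing by E, on 1 keV bins from 5 keV to the
tube potential.  Tungsten K characteristic lines (Kα1 59.32, Kα2 57.98,
Kβ1 67.24, Kβ2 69.07 keV) are added when the potential exceeds the
69.525 keV K-edge.  Their filtered fluence share is anchored at 6% of
total filtered fluence at 100 kVp — a typical value for a
moderately filtered tungsten anode — and scaled as
((kVp/E_K − 1)/(100/E_K − 1))^1.65 at other potentials, which makes the
lines negligible (≈0.1%) at 70 kVp, matching the observed absence of
visible peaks in 70 kVp spectra.  The 6% share and the production
exponent are configurable (`k_fraction`, `K_PRODUCTION_EXPONENT`).

Anode angle, target self-filtration and the 5.5 mm focal spot are not
modeled; their net spectral effect is absorbed into the calibrated
aluminum thickness.  Calibration brackets the added aluminum in
[0, 10] mm and solves HVL(al) = target to 0.005 mm; HVL is strictly
increasing in filtration, so bracketed root-finding is safe.  The
calibrated thicknesses come out at 0.46 / 1.12 / 1.82 mm Al — plausible
for this machine class.  Because filtration is fitted to the stated
HVLs, HVL agreement is a consistency check of the spectral chain, while
depth-dose and bone-dose ratios are genuine predictions.  The machine's
published beam qualities exist in two versions (manufacturer vs
simulation-derived, differing by up to 12% at 70 kVp); the calibration
targets the manufacturer values by default and accepts any target.

## Interaction data

Each material table carries total, photoelectric, incoherent and
coherent mass attenuation plus mass energy-absorption on a 42-point
5–150 keV grid (denser below 40 keV where the photoelectric component
varies fastest), log-log interpolated — the standard treatment for
photon cross sections.  Totals and μen/ρ are transcribed from the
standard published compilations for water, cortical bone, dry air,
aluminum and beryllium.  The partial split is modeled rather than
transcribed: incoherent scattering is Klein–Nishina per electron times
a low-Z binding-suppression factor, the photoelectric component is
recovered from μen/ρ minus the incoherent energy-transfer part, and
coherent scattering closes the residual so the three partials sum to the
total exactly.  The split only steers the Monte Carlo event-type choice;
the quantities that carry the dosimetry (total attenuation and μen/ρ)
remain at compilation accuracy, and a few-percent error in the
incoherent/coherent division moves broad-beam dose ratios well below
the statistical resolution of the study.  Absorption edges are absent
above 5 keV for these media except trace constituents of bone (treated
edge-free); the tables are smooth by construction.

Bone is packaged as cortical bone at 1.85 g/cm³ — the high-mineral
(≈21% calcium by mass) medium used in voxel Monte Carlo practice.  Water
is 1.0 g/cm³; dry air 1.205 mg/cm³.

## Transport engine

Analog photon transport with exact voxel-boundary ray tracing
(incremental voxel stepping, deterministic per seed).  Per event:

- **photoelectric** — full local absorption;
- **incoherent** — free-electron Klein–Nishina sampling of (E′, cos θ)
  via the standard two-branch composition-rejection scheme; the
  electron's share E − E′ deposits locally;
- **coherent** — Thomson angular redirection (1 + cos²θ), no energy
  loss; with Rayleigh disabled the event becomes a delta interaction
  (photon continues unchanged), equivalent to removing the coherent
  cross section without rebuilding the attenuation tables;
- below the 10 keV cutoff the photon deposits its energy locally.

Local deposition is the collision-KERMA approximation: the CSDA range
of a 100 keV electron in water is ≈0.014 cm, comparable to the finest
voxel (0.01 cm), so electron transport would blur doses by at most one
fine voxel and is omitted.  Binding corrections to the Compton energy
spectrum and fluorescence escape after photoabsorption (≤4 keV lines
for calcium) are likewise sub-percent effects on broad-beam ratios and
are not modeled.

With scattering disabled the engine switches to a primary collision-
KERMA estimator: each interaction deposits E·(μen/μ) and ends the
history, so the expected score equals the closed-form primary KERMA

    Σᵢ φᵢ Eᵢ (μen/ρ)(Eᵢ, z) · exp(−∫₀ᶻ μ(Eᵢ) dz′) · (ssd/(ssd+z))²

used as the deterministic oracle (`primary_kerma_analytic`).  This
choice makes the Monte-Carlo-versus-closed-form test exact in
expectation instead of comparing two slightly different energy-transfer
models.

Energies are looked up on a dense 0.25 keV pre-interpolated grid inside
the kernel (nearest-node); the public `coefficient` API interpolates
log-log exactly.  The air gap between source and surface does not
attenuate (it is absent from the primary-KERMA form as well); the ≈0.5%
effect cancels in every reported ratio.

Every run carries an energy audit — deposited + escaped + discarded
must equal emitted within 10⁻⁶ (violations raise) — and per-voxel
uncertainties from the variance of 10 batch means.  Scoring on the
central axis averages the central 2×2 lateral voxel block, which
quadruples the counting statistics of the reported depth profiles.

## Phantoms and study geometries

Voxel grids with half-open depth intervals, beam entering at z = 0, and
slab edges required to land on voxel boundaries (no partial-volume
voxels).  The study presets are: a 3 × 3 × 1.28 cm³ phantom with a
0.5 cm bone slab at 0.3 cm (0.01 cm depth voxels) and its all-water
twin for the transmission comparison at 0.9 cm; and 10 × 10 × 6 cm³
phantoms with the slab at 1.5 or 2.5 cm (0.05 cm depth voxels).  The
published five-slab description does not state which slabs are mineral,
so the builder is parametric in (bone depth, bone thickness); the 6 cm
total depth of the deeper presets guarantees water beyond the slab,
which a literal 3 cm stack could not provide for a 2.5 cm slab depth.
"Surface dose" is the first depth voxel's central-axis dose; an
extrapolation-to-zero alternative is deliberately not the default since
the published curves normalize to a scored surface voxel.

## Statistical design

Slab-preset runs use 2 × 10⁶ histories; the fine-voxel transmission
pair uses 8 × 10⁶ because its 0.9 cm scoring voxel at 50 kVp sits
behind both the bone slab and ≈0.8 cm of water, where the surviving
fluence is a few percent of the entrance value (converged transmission
ratio 6.16 ± 0.16 at 2 × 10⁷ histories; at 2 × 10⁶ the seed-to-seed
spread of the ratio is several times its nominal batch error because
rare hard photons dominate the deep voxel).  These counts hold the
statistical error of every reported quantity near or below the few-
percent level while keeping the full study under two minutes on one
CPU.  Batch count is 10 (20 for the convergence check); per-voxel
uncertainty is the standard error of batch means, a slightly noisy but
unbiased estimator at these event counts.

## Synthetic measured data

The laboratory depth-dose measurements the published RMSE values refer
to are not public, so the fixture generator emulates an ion-chamber
depth scan at 5/10/20/30/40 mm: attenuation × inverse square with
multiplicative Gaussian noise (default σ = 1%, the scale of the study's
reported simulation uncertainty), renormalized to 100 at the first
depth.  It contains no scatter buildup, beam hardening or chamber
perturbation — it exists to exercise the RMSE/comparison plumbing, so a
small RMSE against it validates the comparison code, not the physics of
a real measurement chain.

## Known limitations

- The bone/water μen/ρ contrast of the packaged high-mineral cortical
  bone is ≈6.2 when weighted over the calibrated 50 kVp spectrum
  (≈6.5–6.9 at single energies of 20–40 keV).  Literature f-factor
  figures of ≈4.25 for bone at superficial qualities derive from older,
  less mineralized compact-bone compilations and from the
  exposure-based definition (relative to air, times 0.873 rad/R); they
  are not comparable one-to-one with this ratio.  The packaged data set
  is the one consistent with the bone-dose enhancements this package
  reproduces.
- No electron transport: dose inside the first ≈0.01 cm of an interface
  is KERMA, not dose-with-buildup.
- Free-electron Compton and form-factor-free Rayleigh sampling.
- Point source: no focal-spot penumbra, heel effect, or applicator
  scatter.
- The spectrum model is semi-empirical; only its HVL is anchored to the
  machine.  Quantities dominated by the far low-energy tail would
  inherit model error, which is why the soft 50 kVp technique carries
  the widest tolerances in the acceptance checks (its transmission
  ratio runs ≈15–20% above the published value, consistent with a
  slightly soft modeled spectrum).
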