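# Methods

This note records the physical model behind `rotcam`, the parameters that
matter, the numerical choices, and what the simplified simulation can and
cannot say about a real detector.

## Geometry and rotation emulation

Six axis-aligned scintillator cubes sit at the vertices of a regular
octahedron of side `W` (default 10 cm), i.e. at distance `W/√2` from the
origin on the ±x, ±y, ±z axes. The cube side defaults to the scaling law
`3.5·(W/10)` cm, which keeps the solid angle between crystals — and hence
the geometry-dominated angular resolution — constant as the interval
changes; it can be overridden to study a fixed crystal size at a reduced
interval. Optional aluminum boxes (3.3×3.3×5.0 cm) model photomultiplier
bodies, either behind each crystal ("radial") or below it ("vertical");
they attenuate and scatter but register no signal.

The physical instrument rotates continuously about the vertical axis to
multiply the effective number of crystal positions and wash out "ghost"
ring artifacts. The simulator emulates this per event: a rotation angle
θ_rot ~ U[0°, 360°) is drawn, the *source* is rotated forward by θ_rot
(equivalent to rotating the detector backward), the photon is emitted and
tracked, and the reconstruction de-rotates the crystal coordinates by
−θ_rot. Forward-then-inverse rotation is the identity to 1e-12.

Coordinates are right-handed: +x is (azimuth, elevation) = (0°, 0°),
azimuth increases counterclockwise seen from +z, elevation is latitude.
Point sources are placed by direction and distance (default 1 m).

## Photon transport

The Monte Carlo tracks single photons through the crystal (and optional
PMT) boxes; everything between volumes is vacuum (air attenuation over
≤ 2 m is < 0.3% at these energies). Two processes are modelled:

* **Photoelectric absorption** — deposits the full photon energy locally
  and ends the history.
* **Incoherent (Compton) scattering** — scattering angle sampled from the
  exact Klein–Nishina distribution for free electrons by rejection under a
  constant envelope (f(c) = r²(r + 1/r − (1−c²)) ≤ 2 with r the energy
  ratio; acceptance ≈ 2/3 at low energy, validated against the analytic
  law by χ² test). The recoil-electron energy is deposited locally; the
  photon continues with E′ = E/(1 + (E/511)(1−cos θ)) and uniform azimuth.

Rayleigh (coherent) scattering, Doppler broadening, fluorescence X-ray
escape, pair production (irrelevant below 1.3 MeV except as a percent-level
cross-section correction) and electron transport are omitted. Photons
falling below the 10 keV table floor are absorbed on the spot (their range
is sub-millimetre in scintillator). Free-flight distances are sampled from
the exponential law with the total attenuation coefficient; interaction
type is chosen proportionally to the partial coefficients. Multiple
interactions inside one crystal are summed, matching physical pulse
formation. Histories touching three or more crystals are rejected at the
event-building stage.

Ray–box stepping uses the slab method with half-open boundaries and a
10⁻⁷ cm nudge across interfaces. The random stream is an explicit
xorshift64* generator seeded through numpy `SeedSequence` spawning, so
every run is bit-reproducible for a given seed; the inner loop is compiled
with numba.

**Importance sampling.** Emissions are restricted to a spherical cap
aimed at the detector, sized to 1.2× its angular radius (a cap that would
clip the detector raises an error). The cap's solid-angle fraction f
converts emitted photons into an effective isotropic emission count
C₀ = n_emitted / f, keeping sensitivity estimates unbiased; cap and
full-sphere estimates agree within Monte Carlo error (tested).

## Cross-section data

Per-element mass attenuation coefficients (photoelectric and incoherent,
10–2000 keV) ship as text fixtures generated by
`scripts/make_attenuation_tables.py`:

* incoherent: free-electron Klein–Nishina total cross section × N_A·Z/A.
  Binding corrections, a few percent below ~100 keV for high-Z elements,
  are neglected.
* photoelectric: hydrogenic power law τ/ρ = C·Z^4.44/A · E⁻³ ·
  (1 + E/511)/(1 + 100/511), with C calibrated to published 100 keV values
  for O, and the exponent fixed by the published Ca and I values (both
  reproduced to a few percent). K-edges for I (33.17 keV) and Cs
  (35.98 keV) use a jump ratio of 5.4; lighter elements have edges below
  the grid floor. Below ~60 keV the E⁻³ law underestimates the true
  steepening — a percent-level effect on the observables here, since the
  studied lines sit at 113 keV and above.

Compounds combine elements by mass fraction (water, CsI, NaI, CaF₂,
aluminum, and borosilicate glass decomposed from its oxide composition,
ρ = 2.23 g/cm³). Interpolation is log-log linear, the standard choice for
attenuation data (sub-percent error away from edges); water comes out at
0.135 cm⁻¹ total at 208 keV versus the published ≈ 0.137 cm²/g — within
the 2% expected from omitting coherent scattering.

## Event building and selection

True deposits are smeared with Gaussian energy resolution
σ(E) = a·E^b (keV). Two measured presets are included: CsI(Tl)
(a = 0.5746, b = 0.5736) and CaF₂(Eu) (a = 1.001, b = 0.4963). The CaF₂
preset is the default for CaF₂ detectors and the CsI preset for CsI and
NaI; the design studies used the CsI model throughout and reported the
results insensitive to this choice. Non-positive smeared values are
redrawn rather than truncated, which keeps the peak unbiased. Deposits
below a configurable 10 keV threshold are dropped (results are insensitive
to the exact value — checked at 2/10/20 keV); an event survives only if
exactly two crystals remain.

Selection applies, in order: the TDC cut (|time lag| ≤ 400 ns; simulated
events carry zero lag and always pass), the ADC cut (E₁+E₂ inside a closed
photopeak window, ±3σ for simulation-style analyses, ±2σ for
measurement-style ones), and scatterer/absorber ordering. The ordering
rule is a genuine design choice — the deposits do not label which crystal
scattered first. The default keeps every assignment with a physical
scattering angle (|cos θ| ≤ 1, with 10⁻³ slack for deposits quoted at keV
precision), splitting the event weight equally when both survive; at
208 keV both orderings are essentially never valid simultaneously (that
would need both deposits above the 114.7 keV backscatter floor), so the
rule mostly acts as a kinematic filter. `always-both` and `lower-first`
variants are available. Kinematically impossible events are discarded and
counted.

For overlapping 113/141 keV photopeaks the total-energy spectrum (2 keV
bins, 60–260 keV) is fitted with two Gaussians of fixed centers plus an
exponential continuum, by weighted least squares (Poisson σ = √counts);
the 141 keV selection window is asymmetric, [141−σ, 141+2σ], to reject
leakage from the stronger 113 keV peak.

## Reconstruction

Each ordered event defines a cone with apex at the scatterer crystal
center and axis pointing from the absorber center to the scatterer center
(the incident photon arrived from somewhere on that cone — note the axis
orientation: for a 180° backscatter the source lies opposite the scattered
photon's flight direction). Crystal centers stand in for the unknown
interaction points; the resulting ~1 cm position blur at a ~10 cm lever
arm is the dominant, geometry-limited contribution to the angular
resolution.

For every pixel of the 180×90 map the angle θ between the pixel center on
the radius-r sphere (seen from the cone apex) and the cone axis is
computed, and weight·G(θ) is accumulated. Kernels follow the ring
profiles G₀/G₁ with σ = 8°; kernels are truncated beyond 5σ (error
< 10⁻⁵ of the kernel scale) and are *not* renormalized per event (G₀
peaks at 1). Pixels carry no solid-angle weighting, matching the flat
pixel treatment of the reference analysis; a cos-latitude-weighted CNR
would change numbers only at the percent level for equatorial sources.
Back-projection is exactly additive over event subsets, and the
sharpening-kernel background integrates to ≈ 0 away from sources.

The intensity calibration k = N/V(N) is derived from one point-source
reconstruction with k = 1 (V(N) = peak value); with k applied, a map peak
reads directly in projected events. k is statistics-independent to first
order (back-projection is linear in the event list).

## Evaluation indices

* **Angular resolution**: weighted least-squares fit of
  p·exp(−(Δaz²+Δel²)/2σ²) to the map in a ±40° window of planar
  azimuth/elevation offsets around the nominal source direction. Sharpening
  maps are fitted without a pedestal (their background is ≈ 0 by
  construction); conventional maps add a constant offset term, a deliberate
  deviation without which the nonzero G₀ pedestal biases σ upward.
* **CNR** = (P − M_BG)/σ_BG, P the global maximum, background = all pixels
  more than 30° great-circle distance from the source direction.
* **Absolute sensitivity** = C(r)/C₀ with C(r) the ADC-cut survivor count
  and C₀ the effective isotropic emission count; **detection efficiency**
  = sensitivity × η_γ × 10⁶ cps/MBq (η_γ: 0.064 at 113 keV, 0.11 at
  208 keV, 2.00 at 511 keV, 1.00 at 1333 keV; 0.89 at 141 keV).
* **Elevation scan**: sensitivity at elevations 0–90°, rotation averaging
  on (as in the physical rotating measurement), normalized to elevation 0;
  the figure of merit is the peak-to-trough spread of the normalized curve.
* **Solid-angle fraction** beyond ±e elevation: 1 − sin e (13.4% for
  e = 60°).

## Vial self-absorption

The liquid source is modelled as 25 mL of water (fill height 3.92 cm)
inside a borosilicate cylinder: outer Ø 31.5 mm, inner Ø 28.5 mm, height
43 mm, 1.5 mm walls (the same thickness is assumed for the base and cap,
which the vial description leaves open). Origins are sampled uniformly in
the water, directions isotropically; the interaction probability along
each escape ray is 1 − exp(−μ_w L_water − μ_g L_glass) with analytic
cylinder path lengths. This attenuation-line-integral estimator converges
much faster than full transport and needs no scoring of what happens after
the first interaction, which is all the self-absorption question asks.

## Problem sizes and reproducibility

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest statistics that leave Monte Carlo error well inside
each quantity's tolerance: 5000–6000 ordered coincidences per
angular-resolution fit (the fitted σ is stable to ~±0.5° at this size),
3–4 million emitted photons per elevation-scan point (≲ 2% relative error
on each sensitivity), 4×10⁵ rays for self-absorption. Every random choice
descends from one integer seed via `SeedSequence` spawning; per-grid-point
seeds make sweep rows individually reproducible.

## Known limitations

* **Elevation uniformity at 208 keV and above.** The reference design
  study reports the elevation-normalized sensitivity uniform within ~5% at
  208 keV+; this model gives a 15–20% spread there (while matching the
  ~30% spread at 113 keV). The structure is a genuine property of bare
  axis-aligned cubes in vacuum: at elevation 0 the sensitivity varies by
  ±11% with azimuth (photons stream through the inter-crystal corridor at
  azimuth 45°, and in-line crystal pairs open extra coincidence channels at
  intermediate angles). Rotation averages over azimuth at low elevation but
  not at the zenith — S(90°) equals the *fixed-azimuth* S(0°) exactly, by
  octahedral symmetry (verified) — leaving an irreducible offset between
  the zenith and the azimuth-averaged equator plus mid-elevation bumps.
  The effect is insensitive to the detection threshold and to the energy
  window, and is larger (28%) without rotation averaging. Physics omitted
  here (bound-electron Compton profiles, Rayleigh scattering, fluorescence
  transport) plausibly softens the corridors in a full simulation.
  Consequently the elevation-spread numbers above ~141 keV should be read
  as upper bounds on the real detector's non-uniformity.
* Crystal centers stand in for interaction points; at W = 10 cm this is
  the resolution floor (~10–11° with σ = 8° kernels) and is intended —
  the instrument is designed to be geometry-limited.
* No dead time, pile-up, accidental coincidences, optical-photon or PMT
  gain effects: measured spectra contain continuum backgrounds the
  simulated ones lack, so simulated CNR values are optimistic at equal
  statistics.
* The cross-section parameterisation is calibrated, not tabulated; its
  few-percent accuracy is adequate for the stochastic tolerances here but
  it is not a dosimetry-grade data source.
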