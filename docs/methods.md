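# Methods

## Transport model

Photon packets carry a statistical weight W ∈ [0, 1] (times the roulette
multiplier after survival events) and are propagated by the standard
hop–drop–spin scheme.  Free paths are sampled from the extinction
coefficient, s = −ln ξ/μt; at each extinction event the Albedo–Weight (AW)
rule deposits W·μa/μt and the survivor scatters.  The direction update is
the usual rotation by the sampled deflection angle with uniform azimuth,
switching to the dedicated branch when |u_z| > 0.99999 to avoid the
1/√(1−u_z²) singularity.  Unpolarized Fresnel coefficients (mean of the s
and p reflectances) govern every boundary interaction; Snell's law bends
transmitted directions, and total internal reflection returns the packet
with reflectance 1.  The coordinate convention is MCML's: z grows downward
into the sample, the top surface is z = 0, and all intervals (layers,
voxels, detector bins) are half-open [low, high), so a packet exactly on a
boundary belongs to the deeper region.

Both engines run in double precision with 64-bit accumulators, propagate
packets sequentially from a single seeded RNG stream, and are therefore
bit-reproducible per (seed, configuration).  Packets are independent, so
batches may be distributed externally; reproducibility is then guaranteed
only per (seed, batch layout).

### Layered engine

Layer stacks follow the MCML layout: bounding half-spaces above and below
contribute only their refractive index; interior layers carry (μa, μs, n,
thickness, phase function).  The dimensionless residual step carries across
interfaces (s_left is rescaled by the local μt), so clear layers (μt = 0)
propagate packets geometrically.  An optional fiber-probe surface layout
replaces the plain top boundary: under a fiber core the Fresnel decision
runs against the core index and transmitted packets are attributed to that
fiber; under the metal housing (inside the probe-tip radius) the packet
reflects with the housing reflectivity (0.6 by default; the absorbed
complement is tracked separately in the energy balance), specularly by
default with a Lambertian option; outside the tip the boundary reverts to
the exterior medium.  Reflection from the housing is specular by default
because the probe tips being modeled are polished metal; the Lambertian
alternative is a config switch, not a guess about any particular probe.

### Voxel engine

The sample is a labeled 3D grid with per-label materials.  Steps are
clipped at every voxel face by an incremental face-crossing walk: the
crossed coordinate is snapped onto the face and the voxel index updated
arithmetically, which keeps the half-open convention exact without
nudging positions.  Index mismatches between neighboring voxels trigger
Fresnel decisions with the face normal.  Three deposition schemes are
selectable:

* **AW** — deposit W·μa/μt at extinction events (step from μt);
* **AR** — "ballistic": with probability μa/μt deposit the full weight and
  terminate (step from μt);
* **MBL** — sample the step from μs alone and deposit W(1−e^(−μa·ℓ))
  continuously along every sub-segment ℓ.

All three estimate the same expectations; they differ in variance.  AW
spreads deposits over few points and loses signal-to-noise when the
deposition voxels are much smaller than the mean free path, which is why
MBL is the recommended scheme for fine fluence grids; AR needs far more
packets than either.  The deposition/fluence grid is independent of the
sample grid; MBL sub-segment deposits are placed at the segment midpoint,
an approximation only visible when the deposition grid is finer than the
sample grid.  Lateral faces of the volume are escape boundaries (no
Fresnel); the escaped weight is tracked, and the shipped benchmark volumes
make the lateral voxels metres wide so the term is identically zero there.

### Roulette and the energy balance

Low-weight packets (W < threshold, default 1e-4) play Russian roulette:
survive with probability 1/m (default m = 10) and multiply by m.  The
identity specular + R + T + A(+ A_housing + lateral) = 1 then holds in
expectation; the realized residual is the net of killed weight against
survivor multiplication, with variance bounded by killed·m·threshold/N².
Killed weight is a diagnostic counter, not a balance term.  With roulette
*disabled* the engine instead deposits the sub-threshold residual as
absorbed and terminates, making the balance exact to roundoff — this mode
backs the exact-conservation tests and all trace recording.

### Boundary estimator

Two estimators are available at exterior boundaries.  `sample` (default)
draws the Fresnel decision, as in MCML.  `split` scores the transmitted
fraction W(1−R_F) deterministically and continues the reflected W·R_F — an
unbiased variance-reduction standard for total R/T estimates.  The
cross-engine benchmark uses `split` so that the 10^6-packet comparison
measures engine agreement rather than Monte Carlo noise; the RNG-bias
experiment uses `sample` to stay maximally faithful to the historical
code path it probes.

## Phase functions

Densities are normalized over the deflection cosine, ∫₋₁¹ p dx = 1.
Sampling uses an inverse-CDF lookup table: the CDF is integrated by the
trapezoid rule on a dense uniform grid (500,001 points) and inverted onto
a uniform ξ grid of 4096 entries with linear interpolation.  These defaults
keep the inversion error of a strongly forward-peaked HG (g = 0.9–0.95)
below 1e-4 while costing 32 KiB per table; both are configurable.  The
azimuth is always uniform — every supported family is azimuthally
symmetric.

Families: HG; modified HG (β·HG + (1−β)·(3/2)x²); Gegenbauer kernel with
the analytic normalization 2gα/((1−g)^(−2α) − (1+g)^(−2α)), which reduces
exactly to HG at α = ½; Power of Cosines; tabulated two-column tables; and
Mie.  The Mie module implements the Bohren–Huffman series (downward
recurrence for the logarithmic derivative, π/τ recurrences for S1/S2) for
non-absorbing spheres up to size parameter 300 and tabulates the
unpolarized intensity on 1801 uniformly spaced angles by default; the
closed-form asymmetry series over the expansion coefficients serves as an
independent cross-check of the tabulated density in the tests.

Legendre moments are adaptive quadratures of p·P_k (trapezoid sums on the
native grid for tabulated densities).  γ and δ follow from g₂ and g₃; the
generalized quantifier is σ = Σ_{k≥2} c^(k−2)(1−g_k)/(1−g₁), truncated at
15 moments with weight constant c = −0.5.  Truncation order and weight are
explicit arguments because published variants differ in both.

## Materials

Fused silica uses the Malitson Sellmeier fit (0.21–3.71 μm); water the
Daimon–Masumura fit at 20 °C (0.18–1.13 μm) — the temperature variant is
recorded because other tabulations differ in the fourth decimal;
polystyrene the Nikolov–Ivanov Cauchy fit n = 1.5663 + 0.00785/λ² +
0.000334/λ⁴ (λ in μm, 0.44–1.05 μm).  At 500 nm these give 1.462, 1.337
and 1.603.  Out-of-range wavelengths raise rather than extrapolate.
Constant-index media are declared as `{"n": value}` in configs.

## Detectors and normalization

Raw escaped weights are stored next to their bin edges; normalized views
are computed on demand.  Radial profiles normalize to 1/m² (per launched
packet, per annular ring area); Cartesian x-resolved profiles to 1/m
(y-integrated); energy deposition to 1/m³ (per packet, per voxel volume),
with fluence obtained by dividing by the local μa (μa = 0 voxels are
masked).  Acceptance tests use minimum direction cosines, or a numerical
aperture converted via sinθ = NA/n in the medium carrying the exit
direction.  Log-spaced radial bins put the first edge at 0 and space the
remaining edges geometrically from a configurable first radius (default
10 μm) — "log-spaced from zero" admits several dialects, so the choice is
an explicit parameter.  The tilted-camera detector is a Cartesian
accumulator whose acceptance is measured about an axis tilted in the x–z
plane (20° with a 10° half-angle cone in the shipped configuration).
Weights that fail acceptance or fall outside the edges are tracked in
dedicated counters, so scored + discarded + overflow always reproduces the
total escaped weight.

Fiber reflectance can also be estimated from a radial profile by exact
ring–disc overlap integration (circle–circle lens areas), the route used
with an index-matched fused-silica boundary above the sample.

## Traces and sampling volumes

Trace runs record (position, direction, weight) at launch, every
scattering, every boundary event and the terminal state, up to a capacity
of 1000 events per packet (the shipped probe fixture's detected packets
stay well under it; packets that overflow are excluded from sampling
volumes and counted).  Trace runs force sampled boundaries and
disabled-roulette termination so weights are non-increasing along a trace.
Terminal weights are taken after the final boundary transmission —
sampled Fresnel decisions do not change the weight, so this equals the
last interior weight; it is the weight the detector actually receives.
Events are stored float32 (28 bytes/event) and promoted to float64 before
any geometry; the sampling-volume walk advances exactly from face
parameter to face parameter so per-voxel lengths telescope to the clipped
segment length without truncation loss.  The probe driver runs in batches
(20k packets ≈ 0.5 GiB of trace storage) and accumulates the volume
incrementally.

## Spatial-frequency-domain reflectance

R(f) = 2π Σ_i R(r_i) J₀(2πf r_i) r_i Δr_i over the rings, with r_i the
ring's area-centroid radius (2/3)(r₂³−r₁³)/(r₂²−r₁²) — more accurate than
the midpoint for log-spaced rings near the steep source peak.  At f = 0
the sum collapses to the total binned reflectance exactly.  The
tilted-detector route uses the 1D cosine transform of the x-resolved,
y-integrated profile; the profile's x-symmetry makes the sine part vanish,
so the cosine form is exact for the symmetric component and annihilates
antisymmetric noise.  No tail extrapolation is performed beyond the last
bin edge (the shipped grids span 150 mm, far past where diffuse profiles
decay); a flag warns when the frequency band exceeds what the bin
resolution resolves.  Default frequency grid: 81 uniform points from 0 to
0.8 mm⁻¹.

## Random number generators

The default stream is xoshiro256** seeded via splitmix64.  A faithful
clone of `ran3` (the Numerical Recipes subtractive lagged-Fibonacci
generator, x_n = x_{n−55} − x_{n−24} mod 10⁹) is shipped because the
historical layered MC reference used it: driving the identical transport
code with `ran3` shifts the total reflectance of the two-layer benchmark
outside the 3σ Monte Carlo band at 10^7 packets, while two seeds of the
default generator agree.  The experiment reports signed relative
differences and z-scores; the sign of the bias depends on the
configuration and is reported, not asserted.

## Benchmarks and study conditions

The cross-engine benchmark is a 100 μm top layer over a 1 mm bottom layer
(bottom fixed at μa = 0.5 cm⁻¹, μs′ = 20 cm⁻¹, g = 0.9, n = 1.337; air
above, index-matched medium below) with three top-layer combinations —
(2.5, 30, 0.9), (5, 20, 0.8), (1, 10, 0.9) in (μa cm⁻¹, μs′ cm⁻¹, g).
Each combination runs through both engines at 10^6 packets with
independent seeds; the voxel twin uses 25 μm z-voxels (four across the top
layer, half the local mean free path) and metre-wide lateral voxels.  The
skin-with-vessel volume uses the printed dermis pair (μa = 45.9 cm⁻¹,
μs = 356.5 cm⁻¹, mean free path ≈ 25 μm) with representative 500 nm
literature values for epidermis and whole blood, a 100 μm epidermis, a
100 μm-radius vessel along y, and 26 vessel depths uniform on
[0.2, 0.8] mm; the default 50 μm voxels (21×21×20) keep desk-scale runs
honest for AW/MBL comparisons, with 5 μm voxelization available through
the same builder.  The probe sampling-volume fixture uses 200/220 μm
core/cladding fibers, NA 0.22, fused-silica cores (n = 1.462), 500 μm
separation and 60% housing reflectivity over a semi-infinite medium with
μa = 2.5 cm⁻¹, μs′ = 30 cm⁻¹, g = 0.9.

The shipped dataset families are reduced analogs: the full published grids
(tens of thousands of optical-property × phase-function combinations at
10^8–10^9 packets) exist only as figure tables in the original report, so
the module exposes its grids as plain data and runs outer products of
them; tests and the acceptance script use 10^5–10^7 packets.  What the
desk-scale runs establish is estimator correctness — conservation,
cross-engine and cross-method agreement within Monte Carlo error,
distributional fidelity of the samplers; they do not establish the
sub-0.1% noise floors of the full-size dataset, which scale as 1/√N.

## What the synthetic benchmarks do not capture

The generator-side fixtures are idealized: perfectly planar interfaces,
piecewise-constant optical properties, azimuthally symmetric phase
functions and index-matched or air boundaries.  Real tissue adds rough
interfaces, continuous property gradients and spatially varying phase
functions; real probes add epoxy gaps and imperfect housing reflectivity.
Passing tests therefore certify the transport machinery and its
estimators, not any particular biological parameter set.

## Numerical choices

* LUT: 4096 entries over a 500,001-point dense CDF; inversion error < 1e-4
  for HG g ≤ 0.95.
* Roulette: threshold 1e-4, m = 10 (config fields, not claims about other
  codes).
* Voxel walk: face distances recomputed per crossing from integer indices;
  crossed coordinates snapped to face values; no positional epsilons.
* Sampling-volume walk: 1e-12 parametric epsilon used only to pick the
  voxel index, never in accumulated lengths.
* Step guard: packets are killed (and counted) after 5×10⁷ events, a
  safety net for pathological non-absorbing mirror geometries.
* Mie series: Wiscombe truncation n = x + 4.05x^⅓ + 2, logarithmic
  derivative started 16 orders above.
* Degenerate inputs: μt = 0 media propagate geometrically; zero-length
  segments are skipped; empty detector selections yield zero volumes.

## Known limitations

Polarization, fluorescence, time-resolved transport and mesh geometries
are out of scope.  The layered engine alone records traces; voxel-engine
tracing is not implemented.  Surface layouts apply to the layered engine's
top boundary only.  MBL midpoint deposition blurs sub-sample-voxel detail
in finer deposition grids.  The `ran3` bias reproduction is qualitative:
its sign and size vary with configuration and seed.
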