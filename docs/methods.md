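# Methods

## Quencher-penetration model

The wall is treated as a lumped, structurally homogeneous porous slab: no
z-resolved concentration profile, no pore-blocking kinetics.  The membrane
quencher concentration follows first-order saturation,
`q_m(t) = q_b (1 − exp(−t/T))` with `T = h_m h η(φ) / (φ C D)`, and the
relative fluorescence is Stern–Volmer, `I = 1/(1 + K q_m)`.  Key
parameters and defaults:

| symbol | meaning | unit | default |
|---|---|---|---|
| `q_b` | bath quencher concentration | mol m⁻³ | 0.5 × 10⁻³ |
| `K`   | quencher constant (k_q·τ₀)  | m³ mol⁻¹ | ~10⁴ (fitted) |
| `h`   | wall thickness              | m | 280 × 10⁻⁹ |
| `h_m` | membrane thickness          | m | 10 × 10⁻⁹ |
| `D`   | bath diffusion coefficient  | m² s⁻¹ | 0.56 × 10⁻⁴ |
| `C`   | pore diffusion attenuation  | – | free (C ≪ 1) |
| `φ`   | porosity                    | – | inferred as a ratio |

`C` is never assigned: it cancels in the ratio inference and enters only
through `T`.  The listed `D` is kept as configured reference metadata; no
output of the package depends on it except through a user-constructed
`T`.  Tortuosity laws are pluggable via a registry; only the Bruggeman law
`η = φ^(−1/2)` ships, which assumes an isotropic, homogeneous pore
network.  Under it the porosity ratio of two otherwise-identical samples
is `(T_ref/T_alt)^(2/3)` — exact by construction, which the tests verify
to 1e-10.

### Fitting

Ordinary least squares on the intensities themselves (noise enters on
F/F₀, not on the linearised transform), through a log-parameterisation of
`(K, T)` that enforces positivity and evens the scales, solved by
Levenberg–Marquardt with `xtol = 1e-10` and a 10⁴-evaluation cap.  The
t = 0 point participates; I(0) is not pinned to 1.  Standard errors come
from the Gauss–Newton covariance with the delta-method back-transform.
Starting values: `K₀` from the plateau estimate `(1/I_last − 1)/q_b`, `T₀`
half the observation window — robust for saturating curves.  Degenerate
inputs (constant intensities, fewer than three distinct times) raise
typed errors rather than returning garbage; non-convergence is flagged on
the result, never silent.

Per-genotype fitting uses the ROI-averaged mean curve by default (the way
mean F/F₀ curves are usually presented), with a pooled mode that fits all
replicate points jointly.  Two estimators are available across genotypes:
independent `(K, T)` per label (the default, matching per-sample fitting
practice), and a joint fit tying one `K` across labels with per-label
`T` (`fit_shared_K`).  Because `K` characterises the quencher–fluorophore
pair rather than the wall, the shared-K model is the natural choice when
inferring a porosity ratio, and it removes the strong K–T anti-correlation
of the independent fits: at the simulated study design the spread of the
recovered ratio drops from ~4% to ~2.3% relative.  The ratio pipeline and
the reproduction script therefore use shared-K; both estimators are
reported by the analysis driver.

## Pore quantification

Pipeline: centred ROI crop (e.g. 750 nm × 500 nm) → global Otsu threshold
(dark phase = pore by default; manual level and inverted polarity
available) → one erosion then one dilation with a 3×3 square (an opening;
counts and element configurable) → 8-connected component labelling →
pixel-to-nm² conversion → inclusive area filter [5, 300] nm² → histogram
with 15-nm² bins over [5, 305] nm² (the last bin can only be populated up
to the 300 nm² filter bound) → porosity `φ = ⟨A_p⟩·N_p/A_s`, identically
the in-range pore-area fraction of the ROI.  Pores clipped by the ROI edge
are retained by default.  The distribution comparison reports per-bin
frequency differences and, when the sign pattern of nonzero differences
flips exactly once, the bin edge at which the balance tips from
small-pore-rich to large-pore-rich; with noisy, low-count distributions
that flip need not be unique, in which case no crossover is reported.

## Cross-link statistics

Three link types between **distinct** chains, all detected by distance
under the minimum-image convention in an orthorhombic box:

* calcium bridge — a Ca²⁺ within 0.30 nm of ≥1 carboxylate oxygen on each
  of two chains (event identity: the ion and the chain pair, so oxygen
  exchange does not break a bridge); a strict "zipper" mode requires two
  oxygens per chain;
* CH₃···O — methyl carbon within 0.40 nm of a carbonyl oxygen;
* COOH hydrogen bond — carboxyl hydrogen within 0.25 nm of a carboxyl or
  carboxylate oxygen.

The criteria are distance-only because the free-energy coordinates that
motivate the cutoffs are themselves interatomic distances; the cutoffs sit
inside the first coordination shell (0.25–0.40 nm) and are configurable
and logged.  Events are maximal presence runs per contact identity with a
configurable gap tolerance (default 0: strict, reproducible); lifetime is
`(end − start + 1) × frame spacing`, averaged per type over events (a
frame-weighted occupancy average is the documented alternative).  `N_agg`
is the per-frame largest connected component of the chain graph (any
active link = one edge), averaged over frames — hence fractional values; a
max-over-trajectory mode exists.  The eligible-site tally reported next to
each mean count is half the number of residues of the link's
functionalisation, which for calcium bridges equals the charge-balancing
ion count.

## Synthetic data

The generators emulate the study designs so that recovery can be scored
against planted truth:

* **Fluorescence** — 6 points at 3-min intervals over 0–15 min, 39/42
  replicate ROIs per genotype, additive Gaussian noise (sd 0.02) truncated
  at a small positive floor.  The reference characteristic time defaults
  to 300 s so the window spans ~3 characteristic times; the second
  genotype's time follows from the planted porosity ratio via the inverted
  two-thirds law.  Real ROI noise is likely heteroscedastic and spatially
  correlated; passing tests demonstrate estimator correctness under the
  stated noise model, not robustness to instrument artifacts.
* **Micrographs** — dark ellipses (aspect ratio 1–3) on a light
  background, placed without overlap (≥2 px gap) by rejection sampling;
  ground truth records exact rasterised pixel areas, so clean-scene
  recovery is exact by construction.  Real pores are irregular and the
  background textured; the area statistics, not the shapes, are what the
  downstream stages consume.
* **Trajectories** — parallel bead chains 2 nm apart (far beyond every
  cutoff) with per-residue functional atoms; scheduled links bring the
  participating atoms to a rendezvous point at 40–60% of the detection
  cutoff, and 0.02 nm isotropic jitter models thermal motion while leaving
  ≥5σ of margin, so planted schedules survive detection exactly.  No
  physical dynamics, water or electrostatics are implied.

Problem sizes in the tests and the reproduction script (200 Monte-Carlo
designs, 100–500-pore scenes, 40-frame 8-chain trajectories) were chosen
to characterise the estimators' spread at the study's operating points
while keeping a full run in seconds.

## Known limitations

Absolute porosity cannot be inferred from fluorescence alone (the model
would need calibration against samples of known porosity); only ratios
are reported.  The Bruggeman law is the sole tortuosity model shipped.
The pore stage performs no SEM artifact correction and no learned
segmentation.  The trajectory stage analyses existing trajectories only —
it never generates physical dynamics — and hydrogen bonds are detected
without an angular criterion by default (an optional donor–H···acceptor
angle ≥ 120° check is available for sensitivity analyses).
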