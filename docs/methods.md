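# Methods

## The reduced-dimensionality search model

The nucleoid is a cylinder of radius *R* and length 2*L*; the RecA–ssDNA
filament is a thin absorbing rod of reaction radius *r* on its axis, and the
homologous dsDNA segment diffuses with an effective diffusivity *D*. Because
chromosomal loci are subdiffusive, *D* is scale-dependent: the model uses the
value measured at the length scale that limits the motion —
*D*<sub>R</sub> = 7×10⁻⁴ µm²/s at the nucleoid-radius scale for the radial
(2D) search, and *D*<sub>L</sub> = *D*<sub>R</sub>/10 at the cell-length
scale for the naive 3D comparison. Walkers are normal-diffusive at those
effective coefficients; fractional Brownian motion is deliberately not
simulated, since the scale-appropriate effective *D* is the model's own
approximation of subdiffusion.

Two parameter conventions coexist on purpose:

- The symbolic 2D association time is *T* = *R*² ln(*R*/*r*)/(2*D*<sub>R</sub>)
  ≈ 151 s at *R* = 0.2 µm, *r* = 1 nm. The widely quoted numeric substitution
  *R*² ln(*R*/*r*)/*D*<sub>R</sub> = 303 s ≈ 5 min omits the factor ½; both
  are exposed through the `convention` switch of `search_time_2d`
  (default `"formula"`), so the headline 5-minute figure can be reproduced
  without corrupting the symbolic model.
- The absolute time prediction uses *R* = 0.2 µm while the 2D/3D speed-ratio
  estimate uses *R* = 0.3 µm; both radii are kept as named constants rather
  than silently reconciled.

The probing budget divides the ~9.6 Mb of cellular dsDNA (two ~4.8 Mb genome
equivalents) among the 2 kb of filament ssDNA: each filament segment must
test (9.6×10⁶/*n*)/(2000/*n*) = 4,800 dsDNA segments regardless of the
probing segment length *n*, leaving at most 300 s/4,800 ≈ 63 ms per test.

The "knitting needle" variant — a moving filament probing a static
chromosome — is recorded as out of scope; its kinetics depend on unknown
filament rigidity across length scales.

## Monte Carlo first-passage simulation

`simulate_radial_fpt` runs the literal 2D reduction: Brownian walkers in the
annulus *r* < ρ < *R* with an absorbing inner and reflecting outer circle.
`simulate_cylinder_fpt` runs the full 3D walk with either an absorbing axial
rod (cross-check that the axial coordinate is irrelevant) or an absorbing
sphere at a fixed mid-cell point on the axis (the naive 3D search; the
mid-cell choice is a documented convention — end positions differ only by
boundary effects).

Numerical choices:

- **Adaptive time stepping.** The local step is d*t* = ε·*d*²/*D* with
  ε = 0.01 and *d* the distance to the absorbing surface, floored at the
  configured near-boundary step (default 0.01·*r*²/*D*). The per-axis step
  sd is then ≲ 14% of the distance to the target everywhere, bounding the
  first-order overshoot bias of the post-step absorption test while letting
  walkers far from a nanometre target take macroscopic steps. Against the
  exact annulus closed form the residual bias is below the sampling error of
  2,000 walkers (deviation ≈ 0.04 SEM in the standing test).
- **Boundaries.** Absorption when the distance to the target surface is ≤ 0
  after a step; reflections are specular (positions mirrored across the
  wall), including the cylinder caps.
- **Oracle.** The radial backward equation *D*(T″ + T′/ρ) = −1 with
  T(*r*) = 0, T′(*R*) = 0 gives
  T(ρ₀) = (*R*²/2*D*) ln(ρ₀/*r*) − (ρ₀² − *r*²)/4*D*; the uniform-start mean
  is its closed-form area average. The fixed-point walk is checked against
  the Smoluchowski limit *V*/(4π*rD*).
- **Reproducibility.** One seeded generator drives all walkers in a fixed
  iteration order; a fixed seed reproduces the sample bit-for-bit. Censoring
  at `max_time` is counted and the mean flagged unreliable above 10%
  censoring.
- **Problem sizes.** Standing runs use 400–2,000 walkers, chosen so that the
  Monte Carlo standard errors are a few percent of the means; the 2D/3D
  ratio at the full parameter set (*r* = 1 nm, *D*<sub>L</sub> = 7×10⁻⁵
  µm²/s) is feasible at these sizes thanks to the adaptive stepping. The
  length-scan tests enlarge the target (5–20 nm) to stay cheap; the
  fixed-point scaling check uses *r* = 2 nm because with a large target the
  axial-transit time (∝ *L*²/*D*) competes with the Smoluchowski term and
  genuinely breaks the *T* ∝ *L* scaling.

## Synthetic cohort generator

The generator emulates a mother-machine DSB experiment: per-cell time series
of length and CFP (SOS reporter) intensity at a 1-min frame interval, focus
tracks for ParB (break marker), MalI (sister loci flanking the cut site,
protected from resection by chi sites) and RecA structures, with per-cell
ground-truth event times stored alongside. Defaults are the measured
population moments: repair 15.2 ± 5.0 min, colocalization 9.1 ± 3.3 min,
RecA lifetime 8.8 ± 3.0 min (spot phase 2.6 ± 1.4, filament phase
6.2 ± 2.8), RecA appearing 35 ± 98 s before ParB loss, division delay after
repair, generation time 35 ± 10 min, eightfold induced CFP amplitude with
5% multiplicative noise. The cut fraction (0.6) and the nuclease-to-cut and
SOS-rise delays (3 ± 1.5 min and 4 min) are generator conventions chosen to
give realistic induction timing; they are not measured quantities.

Distributional choices:

- All durations are gamma laws moment-matched to the stated mean ± sd,
  guaranteeing positivity. The gamma family is an assumption; only the
  repair, colocalization and lifetime distributions are constrained by data.
- Repair = colocalization + an independent gamma increment with moments
  (6.1, √(5.0² − 3.3²)) min, so colocalization always precedes reappearance
  while repair keeps exactly mean 15.2, sd 5.0. (The marginal of this sum is
  not exactly gamma; the standalone moment-matched samplers used for the
  dwell-time recovery analyses draw from the pure gamma laws.)
- RecA lifetime inside a cell is spot + filament phase (means add to 8.8
  exactly; sd √(1.4² + 2.8²) = 3.13 vs the printed 3.0). The RecA appearance
  lead has sd larger than its mean, so it is normal and may be negative;
  orderings involving it are not enforced. The disassembly lead is not drawn
  independently — it is implied by reappearance − disassembly (implied mean
  0.58 + 15.2 − 8.8 = 7.0 min vs the printed 6.6, within the slack between
  the two repair-completion definitions, reappearance vs segregation).
- SOS amplitude is log-normal around the eightfold induction, with its
  latent normal correlated (ρ = 0.36) with the standardized RecA lifetime —
  the observed lifetime–SOS coupling used as a generator parameter.
- Sister-locus kinematics are piecewise-linear position programs with
  Ornstein–Uhlenbeck jitter (sd 0.03 µm): slow approach to mid-cell, then a
  sharp capture through the 0.25 µm colocalization threshold exactly at the
  true colocalization time, segregation after reappearance. Capture as a
  discrete event is a kinematic convention, not a fitted polymer model.
- Growth is exponential in length with the drawn generation time as doubling
  time; division halves the length and may be delayed past one doubling in
  cut cells (SOS-delayed division), so growth rate and division timing are
  decoupled.

What the generator does **not** emulate: photophysics (blinking, bleaching),
segmentation errors, detection dropouts, multi-break cells, cells with >2
ParB foci, and real chromosome mechanics. Passing recovery tests therefore
demonstrates that the pipeline is unbiased under clean tracking at the study
conditions, not that it is robust to every real-data pathology.

## Single-cell pipeline

- **Gating:** a cell is analysed when CFP rises more than fourfold over the
  pre-induction baseline (median of the first 5 frames); induction time is
  the linearly interpolated first crossing of half the per-cell maximum.
- **Background subtraction** subtracts a Gaussian-smoothed copy (sigma 20 px)
  — a high-pass filter.
- **Foci detection:** candidate maxima from a local-maximum filter above a
  robust (median + 6·MAD) threshold, refined to sub-pixel centers by a
  gradient-based radial-symmetry estimator (each intensity gradient points
  through the center of a symmetric spot; the center is the weighted
  least-squares intersection of the gradient lines).
- **Event timing:** focus loss and reappearance both require two consecutive
  frames (rejects single-frame dropouts at the cost of ≤ 1 frame of bias);
  repair duration is reappearance − loss. Colocalization is the first
  sustained (2-frame) approach of the MalI sisters below 0.25 µm
  (≈ diffraction limit; the threshold is a config value), timed relative to
  ParB loss. Censored events (loss without reappearance before the movie
  ends) are counted, never dropped.
- **Statistics:** gamma dwell-time fits by maximum likelihood
  (moment-matched initialisation, loc fixed at 0), with the standard error
  of the fitted mean from the inverse Fisher information via the delta
  method; Pearson correlation; OLS for repair time vs cell length at break.

## STED filament width

The PSF of the STED system is calibrated by Lorentzian fits to line profiles
of sparse dye-coupled antibodies (FWHM 35 ± 11 nm). A filament profile is
modelled as the line-of-sight projection of an annular fluorophore shell —
outer radius *d*/2, thickness 3 nm (the antibody label layer), fluorophores
at the cylinder surface facing inward — convolved with the Lorentzian PSF on
a ≤ 1 nm grid; the model's width is the direct half-maximum width of that
profile. `invert_diameter` root-finds the diameter whose forward FWHM equals
the observed Gaussian-fit FWHM. With the observed 60 nm and the 35 nm PSF
this yields 41.4 nm (the quoted deconvolution result is 37.5 nm; placing the
shell outside *d*/2, or measuring the model profile by a Gaussian fit as the
measurement does, shifts the estimate to 33–39 nm — the convention above is
the most literal reading and all readings agree within the ±5 nm tolerance
adopted for this quantity). Uncertainty is propagated by Monte Carlo
resampling of the observed and PSF widths (±13, ±11 nm); the quoted ±23.5 nm
was derived by an unstated scheme and is not a target of the propagation.
Measured profiles are averaged over two adjacent scan lines (along the
filament) for noise reduction before Gaussian fitting; this does not broaden
the transverse profile, so synthetic 1D profiles are fit directly.

## Known limitations

- The simulator's first-order absorption test slightly advances capture near
  the floor timestep; the effect is below sampling error at the standing
  sizes but would matter for sub-percent-accuracy studies.
- The annulus oracle assumes a perfectly straight, static filament spanning
  the whole cell; filament flexibility and motion (which can only shorten
  the search) are not modelled.
- The gamma-MLE standard errors are asymptotic; for n < 50 the coverage of
  the mean CI is approximate.
- The cohort generator's clean tracks make the ±1-frame event-recovery
  guarantee achievable by construction; real tracking noise would degrade it.
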