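# recadim

Biophysical models and single-cell analysis of homology search during
double-strand-break (DSB) repair in *E. coli*.

After a DSB, RecBCD resects the broken ends into 3′ ssDNA on which a RecA
filament assembles; the filament must then locate the homologous sequence on
the sister chromosome. Single-cell measurements show this search finishes in
minutes — far faster than a naive 3D diffusion-limited encounter between two
slow chromosomal loci can explain. The package implements the
*reduced-dimensionality* model of that search and the analysis pipeline that
tests it: because the stretched RecA–ssDNA filament spans the cell pole to
pole, some filament segment is homologous to the chromosomal dsDNA segment at
every axial position, so capture depends only on *radial* diffusion of the
locus toward the filament. The search is effectively two-dimensional.

## The models

With the nucleoid a cylinder of radius *R* and length 2*L*, reaction radius
*r*, and scale-dependent locus diffusivity (*D*<sub>R</sub> at the
nucleoid-radius scale, *D*<sub>L</sub> ≈ *D*<sub>R</sub>/10 at the
cell-length scale, reflecting subdiffusion):

- **Reduced 2D search** — capture rate onto an absorbing axial rod
  *k* = 2π(2*L*)*D*<sub>R</sub>/ln(*R*/*r*), hence
  *T* = *V*/*k* = *R*² ln(*R*/*r*)/(2*D*<sub>R</sub>), independent of *L*.
- **Naive 3D search** — Smoluchowski rate *k* = 4π*r D*<sub>L</sub>, hence
  *T* = *L R*²/(2*r D*<sub>L</sub>), linear in *L*.
- **Speed ratio** — (*L*/(*r D*<sub>L</sub>))/(ln(*R*/*r*)/*D*<sub>R</sub>)
  ≈ 1,750 at *L* = 1 µm, *R* = 0.3 µm, *r* = 1 nm.

A Monte Carlo first-passage simulator (`recadim.fp_simulator`) is the
stochastic twin of these closed forms: Brownian walkers in the annulus or the
full 3D cylinder, with an exact annulus mean-first-passage-time oracle.
Around the models sit a synthetic mother-machine cohort generator
(`recadim.synthetic_data`), the single-cell repair pipeline
(`recadim.repair_analysis`: fourfold SOS gating, radial-symmetry foci
detection, focus-loss/reappearance timing, gamma dwell-time fits,
length regression), and a STED filament-width estimator
(`recadim.filament_width`: Lorentzian PSF, cylinder-with-fluorophore-shell
deconvolution).

## Worked example

```sh
$ python analysis/01_model_predictions.py
Reduced-dimensionality (2D) search:
  T = R² ln(R/r) / 2D_R = 151 s = 2.5 min
  printed substitution (no ½): 303 s ≈ 5 min
Naive 3D bimolecular search: T = 2.86e+05 s = 79 h
Speed ratio (R = 0.3 µm): 1753 ≈ 1,750
Probing: 4800 segments to test, ≤ 62.5 ms per test
Repair success from printed counts: 95.5% (447/468)
```

The 2D search completes in minutes while the naive 3D encounter would take
days; the fourfold gap between 151 s and the ~10-min measured search window
leaves ample time for the filament to reject the ~4,800 non-homologous
segments each filament segment must probe (≤ 63 ms per test). The remaining
drivers run the stochastic and data-analysis halves:

```sh
$ python analysis/02_first_passage.py
Radial annulus walk: mean 130.1 ± 2.9 s (closed form 130.0 s, deviation +0.04 SEM)
Full 3D central-rod walk: mean 129.6 ± 4.3 s — the axial coordinate is irrelevant...
2D vs 3D at D_R/D_L = 10: mean ratio 2236 (6.96e+05 s vs 311 s) — well above 100-fold
Central-rod MFPT vs L: slope -1.17 s/µm, 95% CI [-3.24, 0.90] — consistent with length invariance

$ python analysis/04_repair_pipeline.py
300 cells, 179 passed the fourfold SOS gate (179 repair events, 0 censored, ...)
Repair time: gamma mean 14.6 min (shape 9.7), colocalization 8.9 min, RecA lifetime 8.9 min
Repair time vs length at break: slope -0.28 min/µm, 95% CI [-1.53, 0.98]
RecA lifetime vs SOS amplitude: Pearson r = 0.45 (P = 3.1e-10)

$ python analysis/05_filament_width.py
Gaussian-fit FWHM over 74 profiles: 59.2 ± 2.0 nm
Deconvolving the observed 60 nm FWHM with the 35 nm Lorentzian PSF (3 nm
fluorophore shell): diameter 41.4 ± 15.5 nm
```

Each driver writes its tables under `results/`. A `recadim` console script
exposes the same functionality (`recadim predict | simulate | generate |
analyze | width`).

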