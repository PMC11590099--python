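# phasorph

Phasor-FLIM analysis of single secretory-granule pH, with a first-class
synthetic-data generator.

Insulin secretory granules (ISGs) acidify as they mature, so luminal pH is
a proxy for granule maturity. A granule-targeted two-state FRET biosensor
reads pH out through the donor's fluorescence lifetime: with the acceptor
deprotonated, FRET shortens the donor lifetime (τ_F); protonation of the
acceptor switches FRET off and the donor decays with its free lifetime
(τ_D > τ_F). The protonated fraction follows a single-site
Henderson–Hasselbalch equilibrium,

    f(pH) = 1 / (1 + 10^(pH − pKa)),

so a lifetime readout of *f* is a pH meter with midpoint pKa (≈ 5.7 for the
low-pKa acceptors mCitrine/mNeonGreen, matched to the ISG lumen).

`phasorph` implements the full measurement chain on simulated TCSPC
(time-correlated single-photon counting) data:

1. **Phasor transform** — each pixel's decay histogram maps to
   g = Σc·cos(nωt)/Σc, s = Σc·sin(nωt)/Σc at the laser repetition
   frequency (ω = 2π·80 MHz). Mono-exponential decays lie on the universal
   semicircle g² + s² = g; a two-state mixture lies on the chord between
   the pure-state phasors at the photon-weighted fraction.
2. **%Protonation** — pixels/ROIs are projected orthogonally onto the
   segment between the 0%-protonation anchor (pH 8 reference field) and the
   100% anchor (donor-only construct), both taken as phasor-histogram
   modes. The fractional position along the segment *is* the protonated
   fraction — no lifetime fitting.
3. **Calibration** — a third-order polynomial fitted to a synthetic
   titration (pH 4.0–7.6) maps %Protonation to pH; a separate sigmoid fit
   reports the apparent pKa.
4. **Segmentation & statistics** — LoG blob detection of ~350 nm puncta,
   local-annulus background subtraction, normalized membrane distance from
   the cell's distance transform, nearest-neighbour matching across
   repeated acquisitions, distance-stratified pH landscapes, and pairwise
   Kolmogorov–Smirnov comparisons of stimulation time bins.

The generator renders per-pixel Poisson-sampled decay stacks (bi-exponential
sensor mixtures, Gaussian IRF, period wrapping at 80 MHz, 60 nm pixels,
diffraction-blurred granules, autofluorescence, stimulation rules), so every
stage is testable without any external data.

## Worked example

`python examples/01_titration_calibration.py` runs the synthetic
calibration end to end:

```
pH      true f    measured f   pixel IQR
4.00     0.980       0.970      0.020
4.98     0.839       0.827      0.023
5.64     0.537       0.527      0.022
6.29     0.204       0.196      0.019
7.60     0.012       0.009      0.016

endpoint anchors: p0 (FRET on)  = (0.496, 0.497)
                  p100 (donor)  = (0.196, 0.396)
apparent pKa from sigmoid fit   = 5.698
```

(abridged; the script prints all 12 pH points). Each row is one uniform
sensor field pushed through transform → instrument calibration → wavelet
filter → projection: the measured %Protonation tracks the true protonated
fraction, the anchors sit at the closed-form semicircle positions of
τ = 2 ns and τ = 4 ns, and the fitted midpoint recovers the sensor pKa.

The other examples print the repeat-measurement uncertainty
(`02_granule_uncertainty.py`, mean per-granule pH SD ≈ 0.04), the
distance-stratified pH landscape (`03_ph_landscape.py`, peripheral
granules broad around pH 5.3, interior acidic around 4.6, pooled mean
≈ 5.0), and stimulation responses (`04_stimulation_response.py`: secretion
stimuli deplete acidic peripheral granules; exendin-4 acidifies without
acute count loss).

A thin CLI wraps the same chain:

```bash
phasorph calibrate --seed 1
phasorph analyze --seed 1
phasorph stimulate --stimulus glucose --seed 1
```

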