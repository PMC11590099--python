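# Methods

## The measurement model

The sensor is modeled as a two-state system. At local pH the acceptor
chromophore is protonated with probability
f = 1/(1 + 10^(pH − pKa)) (Henderson–Hasselbalch, Hill coefficient 1 —
single-site chromophore protonation; default pKa 5.7). Protonated sensor
emits donor photons with lifetime `tau_donor`, deprotonated (FRET-on)
sensor with `tau_fret`. Defaults are `tau_donor = 4.0 ns`,
`tau_fret = 2.0 ns`: mTurquoise2-plausible values, well separated within
the 12.5 ns period of an 80 MHz laser. They are generator defaults, not
claims about any real construct. `brightness_ratio` (default 1) scales the
detected brightness of the FRET-on state; at 1 the photon-weighted mixing
fraction equals the molar protonated fraction, which is the implicit
assumption behind reading %Protonation directly off the phasor chord. The
parameter is exposed so that bias from unequal state brightness can be
studied.

A pixel's expected decay is the brightness-weighted sum of IRF-convolved,
period-wrapped exponentials over all contributing species: the granule
mixture, a mono-exponential autofluorescence (default 2.5 ns), and a
temporally flat background (uncorrelated counts). The IRF is Gaussian
(default center 1.0 ns, σ 0.15 ns). Wrapping accumulates the tails of
previous excitation pulses — non-negligible for a 4 ns decay in a 12.5 ns
window. The exponentially-modified-Gaussian shape is evaluated with a
two-branch erfcx/erfc form that is stable at both early and late times.
Counts are independent Poisson samples per pixel per time bin (64 bins by
default).

## Phasor processing

The transform uses bin-center timestamps. Instrument calibration
multiplies every pixel phasor by the complex factor mapping a reference of
known lifetime onto its closed-form semicircle position; the reference is
a simulated decay (τ = 2.5 ns) rendered through the same IRF and binning,
which makes synthetic pipelines self-calibrating and cancels both the IRF
phase/modulation and the histogram discretization (residuals ~1e-7 at 256
bins, well under the 1e-3 contract).

The wavelet filter treats the g and s planes as the two parts of one
complex image and shrink-filters each independently: `db4`, 2 levels,
soft universal threshold σ·√(2 ln N) with σ estimated per level from the
MAD of the diagonal detail band. Approximation coefficients are untouched,
so large-scale means are preserved (measured drift of the photon-weighted
mean over a 128² uniform region: ≪ 1% of the endpoint-segment length);
per-pixel SD on Poisson-noise fields at ~50 counts/pixel drops by >2×.
Zero-photon pixels carry an explicit validity flag (never NaN) and are
mean-filled before the transform so they do not bleed artifacts.

Filtered images drive pixel-level products: endpoint histogram modes,
%Protonation maps, phasor histograms. Per-granule records, however, are
pooled from the *unfiltered* calibrated image: ROI pooling is already the
photon-weighted average, and measurements on synthetic repeats showed that
pre-smoothing adds repeat-to-repeat variance (neighbour-noise leakage into
the ROI) and a small accuracy bias, without any benefit to the pooled
estimate. `analyze_scene(records_from_filtered=True)` restores a strictly
filtered chain.

## Endpoints, %Protonation and calibration

Anchors are phasor-histogram modes (bin width 0.01 in (g, s); ties broken
by photon weight, then lexicographically) of a donor-only field (100%
protonation surrogate) and a pH 8 field (protonated fraction ≈ 0.5%,
the 0% surrogate, standing in for sensor targeted to the mitochondrial
lumen). Orientation is validated — the donor-only anchor must sit at the
longer-lifetime (smaller g) position — and anchors closer than 0.05 are
rejected as degenerate. The mode is used rather than the mean because it
is robust to a minority of contaminated pixels.

%Protonation is the orthogonal projection of a (pooled) phasor onto the
anchor segment, clipped to [0, 1]: under isotropic phasor noise the
projection is the maximum-likelihood position, and perpendicular
displacement (noise, residual background) is discarded.

Granule ROI phasors are background-corrected before projection: the local
non-granule signal (autofluorescence + flat background) is estimated from
an annulus around each ROI (excluding pixels claimed by any detection) and
its photon-weighted phasor contribution is subtracted from the pooled ROI
sums — spot photometry transplanted to phasor space. This matters because
the flat background's phasor sits at the origin, which projects *outside*
the anchor segment and would otherwise bias %Protonation upward, and
because per-granule brightness scatter makes the contamination fraction
granule-specific. ROIs whose background share exceeds 80% skip the
correction and fail QC. Calibration fields are rendered clean by default
(`af_fraction` adds contamination for robustness studies).

The calibration curve is a third-order polynomial fitted to
(pH, mean %Protonation) titration points as pH → fraction and inverted
numerically (dense-grid interpolation, equivalent to bisection on a
monotone function). An unconstrained cubic fitted to a sigmoid always
turns non-monotone at the flat ends of pH 4.0–7.6, so the fit is solved as
a convex QP with linear constraints: derivative ≤ −10⁻⁴ and values within
[0, 1] on the valid range. The apparent pKa is reported from a separate
free-endpoint sigmoid fit and never used for inversion. Known limitation:
a cubic cannot represent a sigmoid exactly, so inverting it carries an
intrinsic approximation error — up to ≈0.25 pH near the range edges,
≈0.1 within the physiological 4.5–5.7 band — even with noiseless data.
This is a property of the third-order calibration choice itself; the
measured %Protonation is unbiased to <0.01, round-trips through the curve
are identity to <0.01 pH, and repeat-measurement SDs are unaffected
(the bias is constant per granule). pH is reported at 0.01 resolution;
uncertainty is reported separately, never folded into the value.

## Scenes and segmentation

Scenes are 2D single planes (acquisition z-stacks are treated as
independent slices; all statistics are per-granule). The cell is a
low-order perturbed disc (~11 µm across at 60 nm pixels in a 256² frame).
Granules are 250 nm discs blurred to an apparent ~340 nm FWHM by a 300 nm
FWHM Gaussian PSF, with log-normal brightness scatter (σ = 0.2) for
expression variability, placed with ≥7 px mutual separation at normalized
membrane depths set per population. Photon budgets follow the imaging
conditions: in-cell median 70 counts/pixel for live frames (the 60–80
working criterion), 1000 for calibration fields (20 repetitions × ~50).
The default granule-peak-to-cytosol contrast (~16:1) puts roughly two
thirds of in-cell photons into puncta, consistent with a granule-targeted
sensor whose cytosolic signal is weak autofluorescence.

Cell segmentation thresholds a puncta-suppressed image: a 25th-percentile
rank filter (11 px window) removes granules — including the bright ring of
docked granules whose PSF wings spill past the membrane and would
otherwise inflate the boundary by several pixels — then a log-domain Otsu
split is refined to the half-intensity point between the inside and
outside medians, centring the boundary on the edge (residual bias
~0.1 px). Granule detection is multi-scale Laplacian-of-Gaussian at
σ ≈ diameter/(2√2·pixel) with non-maximum suppression; each detection
claims a disjoint disc of 2.5 σ (stronger responses claim first).
Normalized membrane distance is distance-transform depth divided by the
cell's maximum depth (0 at the membrane, 1 at the deepest point). This is
a stated stand-in for the unpublished original definition — the simplest
one consistent with a 0.05 peripheral threshold — and peripheral
classification is strict (< 0.05).

Matching across repeats is greedy nearest-neighbour in order of increasing
displacement, rejected beyond 3 px; only tracks spanning every frame are
kept, mirroring the exclusion of fast movers. Greedy (not Hungarian)
linking is adequate at these granule densities; documented limitation.

The photon-budget QC (ROI median pixel counts ≥ 60, configurable) flags
but never drops records. The repeat-uncertainty protocol restricts to
QC-passing records, matching the practice of fixing the photon criterion
before quantifying uncertainty.

## Population analyses

Landscape populations (per cell): 40 peripheral granules,
pH ~ N(5.3, 0.74) at depths 0–0.08, and 30 interior granules,
pH ~ N(4.6, 0.59) at depths 0.25–1, both truncated to [3.8, 7.4]. The
standard deviations are IQR/1.349 of the target central-50% intervals
([4.8, 5.8] and [4.2, 5.0]); the 40:30 mix makes the population mean pH
5.0. Densities are Gaussian KDE with Silverman bandwidth; raw values and
percentile intervals are always retained alongside.

Stimulation rules are free parameters calibrated only to qualitative
signatures (no quantitative rates exist to match): glucose removes
peripheral granules below pH 5.2 with probability 0.45 (0.06 otherwise
peripheral) and mildly acidifies the less-acidic pool; KCl removes
peripheral granules below pH 5.5 at 0.55 and transiently alkalinizes
merged granules; exendin-4 removes nothing in the first 15 min (later
losses are basal-like artifacts at 0.08) and acidifies toward pH 4.5
proportionally to maturity headroom. Secretion ramps in over the first
15 min; an unselective basal loss (default 0.03/epoch) covers basal
secretion and photobleaching. Time bins are fixed at pre / 1–15 / 16–40
minutes (acute and prolonged secretion phases).

KS comparisons are computed on %Protonation (the measured scale), pairwise
across time bins, with star tiers at 0.05/0.01/0.001/0.0001 (the standard
convention). No multiple-testing correction is applied to the headline
tiers — matching apparent practice — but a Holm-corrected tier column is
emitted as a labeled extension. Bins with fewer than 5 records are
reported as undersized, never silently skipped. Granules are pooled across
cells by default, with per-cell identifiers retained in every record for a
per-cell breakdown.

## Experiment sizes and seeds

One experiment seed fans out through `numpy.random.SeedSequence` children,
so stages are independently reproducible and identical seeds give
bit-identical scenes and stacks. Default problem sizes — 12-point
titrations on 64² calibration fields, 256² live frames, 4 scenes × 4
repeats × ~50 granules for uncertainty, 10 scenes for landscapes — were
chosen so each study resolves its quantity well inside its sampling error
on a single CPU in seconds; the acceptance script completes in ~20 s.

## What the generator does and does not emulate

Emulated: Poisson photon statistics at realistic budgets, IRF convolution
and period wrapping, two-state decay mixing, diffraction blur, granule
brightness scatter, autofluorescence and dark background, peripheral/
interior population structure, secretion/acidification dynamics.

Not emulated: 3D optics and z-stacks (single planes only), detector
afterpulsing and dead time, granule motion physics beyond per-frame jitter
(no directed transport), spatially varying autofluorescence, multi-cell
fields of view, photobleaching kinetics (folded into basal loss), and any
real construct's photophysics. Passing tests therefore certify the
analysis chain's correctness and its noise behaviour under the stated
model — not performance on real microscope data, where IRF drift,
heterogeneous autofluorescence and 3D effects would add error terms the
model excludes.
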