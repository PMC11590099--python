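"""Synthetic ground truth and TCSPC rendering for the granule-pH pipeline.

Emulates a single insulinoma-like cell expressing a granule-targeted
two-state FRET pH sensor, imaged by two-photon TCSPC FLIM:

* the sensor's donor decays fast (``tau_fret``) while the acceptor is
  deprotonated (FRET on) and slowly (``tau_donor``) while it is protonated
  (FRET off); the protonated fraction follows a single-site
  Henderson–Hasselbalch equilibrium in the local pH;
* granules are sub-diffraction (~250 nm) puncta blurred by a Gaussian PSF
  so they appear ~350 nm at 60 nm pixels;
* every pixel's expected decay is the brightness-weighted sum of
  IRF-convolved, period-wrapped exponentials from all contributing species
  (granule mixture, mono-exponential autofluorescence, flat background) and
  the recorded counts are Poisson samples of it;
* secretion/acidification stimuli remove or shift granule subpopulations
  according to simple pH- and location-selective rules.

Scenes are 2D single planes; acquisition z-stacks are represented as
independent slices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage import draw

from .phasor import IRFModel, TCSPCStack, decay_shape, flat_shape

__all__ = [
    "SensorModel",
    "AcquisitionParams",
    "GranuleTruth",
    "GranulePopulation",
    "CellScene",
    "StimulusModel",
    "protonated_fraction",
    "make_cell_mask",
    "make_scene",
    "render_decay_stack",
    "render_uniform_field",
    "simulate_titration",
    "apply_stimulus",
    "standard_stimulus",
    "landscape_populations",
    "uncertainty_population",
]

#: full width at half maximum of the imaging point-spread function, nm
PSF_FWHM_NM = 300.0
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SensorModel:
    """Two-state FRET pH sensor.

    ``tau_fret`` is the donor lifetime with the acceptor deprotonated
    (FRET on, short); ``tau_donor`` the donor-only lifetime with the
    acceptor protonated (FRET off, long); ``pka`` the acceptor chromophore
    pKa; ``brightness_ratio`` the relative detected donor-channel
    brightness of the FRET-on vs FRET-off state (1 = equally bright, in
    which case photon fraction equals molar fraction).
    """

    name: str = "granule-pH-sensor"
    tau_fret: float = 2.0
    tau_donor: float = 4.0
    pka: float = 5.7
    brightness_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.tau_fret < self.tau_donor):
            raise ValueError("require 0 < tau_fret < tau_donor")
        if not (3.0 < self.pka < 9.0):
            raise ValueError("pka must be in (3, 9)")
        if not self.brightness_ratio > 0:
            raise ValueError("brightness_ratio must be > 0")


@dataclass(frozen=True)
class AcquisitionParams:
    """TCSPC acquisition geometry and photon budget."""

    rep_rate: float = 8.0e7  # Hz
    n_bins: int = 64
    pixel_size: float = 60.0  # nm
    frame_shape: tuple[int, int] = (256, 256)
    target_median_counts: float = 70.0  # photons/pixel, median inside the cell
    n_repeats: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame_shape", tuple(self.frame_shape))
        if self.rep_rate <= 0 or self.n_bins < 4:
            raise ValueError("invalid rep_rate or n_bins")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.target_median_counts <= 0:
            raise ValueError("target_median_counts must be > 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def period(self) -> float:
        """Laser period, ns."""
        return 1e9 / self.rep_rate

    @property
    def bin_width(self) -> float:
        return self.period / self.n_bins


@dataclass
class GranuleTruth:
    """Ground truth for one secretory granule."""

    id: int
    centroid: tuple[float, float]  # (y, x) in pixels
    diameter_nm: float = 250.0
    true_ph: float = 5.5
    mobility: float = 0.0  # nm/frame displacement scale
    population_label: str = "interior"
    brightness: float = 1.0  # relative peak intensity (expression scatter)

    def __post_init__(self) -> None:
        if not (3.5 <= self.true_ph <= 8.5):
            raise ValueError("true_ph must be within [3.5, 8.5]")
        if self.diameter_nm <= 0:
            raise ValueError("diameter must be > 0")


@dataclass(frozen=True)
class GranulePopulation:
    """Specification for one granule subpopulation of a scene.

    ``ph_dist`` is "normal" (truncated to ``ph_range``) or "uniform" (over
    ``ph_range``).  ``depth_range`` restricts placement by normalized
    membrane depth (0 = plasma membrane, 1 = deepest interior point).
    """

    name: str
    n: int
    ph_mean: float = 5.5
    ph_sd: float = 0.5
    ph_dist: str = "normal"
    ph_range: tuple[float, float] = (3.6, 8.4)
    depth_range: tuple[float, float] = (0.0, 1.0)
    diameter_nm: float = 250.0
    mobility: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("population size must be >= 0")
        if self.ph_dist not in ("normal", "uniform"):
            raise ValueError("ph_dist must be 'normal' or 'uniform'")


@dataclass
class CellScene:
    """Synthetic ground truth: cell mask plus granule list."""

    cell_mask: np.ndarray
    granules: list[GranuleTruth]
    autofluorescence: tuple[float, float] = (2.5, 25.0)  # (lifetime ns, counts/px)
    background_counts: float = 3.0  # out-of-cell / dark counts per pixel
    timepoint: float = 0.0  # minutes
    pixel_size: float = 60.0  # nm

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, bool)
        if self.autofluorescence[1] < 0 or self.background_counts < 0:
            raise ValueError("counts parameters must be >= 0")
        for gr in self.granules:
            yy, xx = int(round(gr.centroid[0])), int(round(gr.centroid[1]))
            if not (
                0 <= yy < self.cell_mask.shape[0]
                and 0 <= xx < self.cell_mask.shape[1]
                and self.cell_mask[yy, xx]
            ):
                raise ValueError(f"granule {gr.id} centroid outside the cell mask")


@dataclass(frozen=True)
class StimulusModel:
    """Secretion / acidification rules for one stimulation condition.

    ``secretion_rule(ph, dist)`` returns the acute-phase removal probability
    for a granule at true pH ``ph`` and normalized membrane distance
    ``dist``; it is ramped in over the first 15 min.  ``acidification_rule
    (ph, minutes)`` returns the mean pH shift at ``minutes`` after onset.
    ``basal_loss`` is an unselective per-epoch loss probability (basal
    secretion / photobleaching) applied once ``minutes > basal_delay``.
    """

    name: str
    secretion_rule: Callable[[float, float], float]
    acidification_rule: Callable[[float, float], float]
    basal_loss: float = 0.03
    basal_delay: float = 0.0
    ph_jitter: float = 0.03  # per-granule scatter of the pH shift

    def __post_init__(self) -> None:
        if not (0.0 <= self.basal_loss <= 1.0):
            raise ValueError("basal_loss must be a probability")


def protonated_fraction(ph, pka):
    """Henderson–Hasselbalch protonated fraction, Hill coefficient 1.

    f = 1 / (1 + 10**(pH - pKa)); monotonically decreasing in pH with
    f(pKa) = 0.5.  Accepts scalars or arrays.
    """
    return 1.0 / (1.0 + np.power(10.0, np.asarray(ph, float) - pka))


def make_cell_mask(
    shape: tuple[int, int],
    rng: np.random.Generator,
    radius_frac: float = 0.37,
    irregularity: float = 0.07,
) -> np.ndarray:
    """Random smooth single-cell mask: a low-order perturbed disc."""
    ny, nx = shape
    cy = ny / 2 + rng.uniform(-0.03, 0.03) * ny
    cx = nx / 2 + rng.uniform(-0.03, 0.03) * nx
    base_r = radius_frac * min(ny, nx)
    theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    r = np.full_like(theta, 1.0)
    for k in range(2, 6):
        amp = irregularity * rng.uniform(0.3, 1.0) / (k - 1)
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r = base_r * r
    rr, cc = draw.polygon(cy + r * np.sin(theta), cx + r * np.cos(theta), shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return ndimage.binary_fill_holes(mask)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw_n = max(16, 2 * (n - filled))
        x = rng.normal(mean, sd, draw_n)
        x = x[(x >= lo) & (x <= hi)]
        take = min(x.size, n - filled)
        out[filled : filled + take] = x[:take]
        filled += take
    return out


def make_scene(
    populations: Sequence[GranulePopulation],
    seed: int,
    shape: tuple[int, int] = (256, 256),
    autofluorescence: tuple[float, float] = (2.5, 25.0),
    background_counts: float = 3.0,
    cell_mask: np.ndarray | None = None,
    min_separation_px: float = 7.0,
    brightness_sd: float = 0.2,
    pixel_size: float = 60.0,
    timepoint: float = 0.0,
) -> CellScene:
    """Generate a reproducible ground-truth cell scene.

    Granule centroids are placed inside the cell mask at normalized membrane
    depths drawn from each population's ``depth_range``, with a minimum
    mutual separation so puncta are resolvable; pH values follow each
    population's distribution.  Raises if the requested granules cannot be
    placed.
    """
    rng = np.random.default_rng(seed)
    if cell_mask is None:
        cell_mask = make_cell_mask(shape, rng)
    cell_mask = np.asarray(cell_mask, bool)
    depth = ndimage.distance_transform_edt(cell_mask)
    max_depth = depth.max()
    if max_depth <= 0 and any(p.n > 0 for p in populations):
        raise ValueError("empty cell mask cannot host granules")
    norm_depth = depth / max(max_depth, 1.0)

    granules: list[GranuleTruth] = []
    placed: list[tuple[float, float]] = []
    gid = 0
    for pop in populations:
        lo, hi = pop.depth_range
        candidates = np.argwhere(cell_mask & (norm_depth >= lo) & (norm_depth <= hi) & (depth >= 2.0))
        if pop.n > 0 and candidates.shape[0] == 0:
            raise ValueError(f"population '{pop.name}': no room inside the mask")
        rng.shuffle(candidates)
        if pop.ph_dist == "uniform":
            phs = rng.uniform(pop.ph_range[0], pop.ph_range[1], pop.n)
        else:
            phs = _truncated_normal(
                rng, pop.ph_mean, pop.ph_sd, pop.ph_range[0], pop.ph_range[1], pop.n
            )
        count = 0
        for yx in candidates:
            if count >= pop.n:
                break
            y, x = float(yx[0]), float(yx[1])
            if placed:
                d2 = min((y - py) ** 2 + (x - px) ** 2 for py, px in placed)
                if d2 < min_separation_px**2:
                    continue
            y += rng.uniform(-0.5, 0.5)
            x += rng.uniform(-0.5, 0.5)
            placed.append((y, x))
            granules.append(
                GranuleTruth(
                    id=gid,
                    centroid=(y, x),
                    diameter_nm=pop.diameter_nm,
                    true_ph=float(phs[count]),
                    mobility=pop.mobility,
                    population_label=pop.name,
                    brightness=float(rng.lognormal(0.0, brightness_sd)),
                )
            )
            gid += 1
            count += 1
        if count < pop.n:
            raise ValueError(
                f"population '{pop.name}': placed only {count}/{pop.n} granules "
                "(mask too small or min_separation_px too large)"
            )
    return CellScene(
        cell_mask=cell_mask,
        granules=granules,
        autofluorescence=autofluorescence,
        background_counts=background_counts,
        timepoint=timepoint,
        pixel_size=pixel_size,
    )


def _mixture_shape(
    ph: float, sensor: SensorModel, irf: IRFModel, n_bins: int, period: float
) -> np.ndarray:
    """Unit-sum decay of the two-state sensor at the given pH.

    The photon-weighted protonated fraction accounts for the relative
    brightness of the two states.
    """
    f = float(protonated_fraction(ph, sensor.pka))
    w_prot = f
    w_deprot = (1.0 - f) * sensor.brightness_ratio
    f_ph = w_prot / (w_prot + w_deprot)
    return f_ph * decay_shape(sensor.tau_donor, irf, n_bins, period) + (
        1.0 - f_ph
    ) * decay_shape(sensor.tau_fret, irf, n_bins, period)


def _granule_sigma_px(diameter_nm: float, pixel_size: float) -> float:
    # apparent Gaussian width: PSF blur combined with the finite granule
    # size (approximated by a Gaussian of sigma = diameter/4); at defaults
    # the apparent FWHM is ~340 nm, matching the ~350 nm puncta seen at the
    # diffraction limit.
    sigma_psf = PSF_FWHM_NM / _FWHM
    sigma = math.sqrt(sigma_psf**2 + (diameter_nm / 4.0) ** 2)
    return sigma / pixel_size


def render_decay_stack(
    scene: CellScene,
    sensor: SensorModel,
    irf: IRFModel,
    acq: AcquisitionParams,
    seed: int | None = None,
    granule_peak_counts: float = 400.0,
) -> TCSPCStack:
    """Render a scene into one Poisson-sampled TCSPC stack.

    Expected per-pixel decays are brightness-weighted sums of the granule
    two-state mixtures (diffraction-blurred puncta), the autofluorescence
    mono-exponential inside the cell and a temporally flat background; the
    whole expected image is scaled so the median expected total inside the
    cell equals ``acq.target_median_counts``, then counts are drawn
    pixel-by-pixel, bin-by-bin from independent Poisson laws.
    ``granule_peak_counts`` sets the pre-scaling peak amplitude of a
    brightness-1 granule relative to the scene's autofluorescence level.
    """
    if acq.bin_width > sensor.tau_fret:
        raise ValueError(
            "time bins too coarse to resolve tau_fret "
            f"(bin width {acq.bin_width:.3f} ns > {sensor.tau_fret} ns)"
        )
    if scene.cell_mask.shape != acq.frame_shape:
        raise ValueError("scene mask and acquisition frame shape differ")
    rng = np.random.default_rng(acq.seed if seed is None else seed)
    ny, nx = acq.frame_shape
    nb = acq.n_bins
    period = acq.period
    expected = np.zeros((ny, nx, nb))

    af_tau, af_counts = scene.autofluorescence
    if af_counts > 0:
        af = scene.cell_mask[..., None] * (
            af_counts * decay_shape(af_tau, irf, nb, period)[None, None, :]
        )
        expected += af
    if scene.background_counts > 0:
        expected += scene.background_counts * flat_shape(nb)[None, None, :]

    for gr in scene.granules:
        sigma = _granule_sigma_px(gr.diameter_nm, scene.pixel_size)
        cy, cx = gr.centroid
        if gr.mobility > 0:
            cy += rng.normal(0.0, gr.mobility / scene.pixel_size)
            cx += rng.normal(0.0, gr.mobility / scene.pixel_size)
        half = int(math.ceil(4 * sigma))
        y0, y1 = max(0, int(cy) - half), min(ny, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(nx, int(cx) + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1)[:, None] - cy
        xx = np.arange(x0, x1)[None, :] - cx
        amp = (
            gr.brightness
            * granule_peak_counts
            * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
        )
        shape_b = _mixture_shape(gr.true_ph, sensor, irf, nb, period)
        expected[y0:y1, x0:x1, :] += amp[..., None] * shape_b[None, None, :]

    totals = expected.sum(axis=2)
    in_cell = totals[scene.cell_mask]
    if in_cell.size and np.median(in_cell) > 0:
        expected *= acq.target_median_counts / np.median(in_cell)
    counts = rng.poisson(expected).astype(np.uint32)
    meta = {
        "pixel_size": scene.pixel_size,
        "rep_rate": acq.rep_rate,
        "n_bins": nb,
        "seed": seed if seed is not None else acq.seed,
        "timepoint": scene.timepoint,
    }
    return TCSPCStack(counts=counts, bin_width=acq.bin_width, rep_rate=acq.rep_rate, metadata=meta)


def render_uniform_field(
    fraction: float,
    sensor: SensorModel,
    irf: IRFModel,
    acq: AcquisitionParams,
    seed: int | None = None,
    af_fraction: float = 0.0,
    af_tau: float = 2.5,
) -> TCSPCStack:
    """Render a spatially uniform field of sensor at a fixed protonated fraction.

    Used for titration/calibration experiments (cytosolic sensor in
    permeabilized cells): every pixel shares one expected decay built from
    the sensor mixture at molar protonated fraction ``fraction`` plus an
    ``af_fraction`` share of autofluorescence photons.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(acq.seed if seed is None else seed)
    nb, period = acq.n_bins, acq.period
    w_prot = fraction
    w_deprot = (1.0 - fraction) * sensor.brightness_ratio
    f_ph = w_prot / (w_prot + w_deprot)
    shape_b = f_ph * decay_shape(sensor.tau_donor, irf, nb, period) + (
        1.0 - f_ph
    ) * decay_shape(sensor.tau_fret, irf, nb, period)
    mix = (1.0 - af_fraction) * shape_b + af_fraction * decay_shape(
        af_tau, irf, nb, period
    )
    expected = acq.target_median_counts * mix[None, None, :] * np.ones(
        acq.frame_shape
    )[..., None]
    counts = rng.poisson(expected).astype(np.uint32)
    meta = {"fraction": fraction, "af_fraction": af_fraction, "seed": seed}
    return TCSPCStack(counts=counts, bin_width=acq.bin_width, rep_rate=acq.rep_rate, metadata=meta)


def simulate_titration(
    sensor: SensorModel,
    ph_list: Sequence[float],
    acq: AcquisitionParams,
    irf: IRFModel,
    seed: int = 0,
    af_fraction: float = 0.0,
) -> list[tuple[float, TCSPCStack]]:
    """One uniform-field stack per buffer pH (default span 4.0–7.6)."""
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(max(len(ph_list), 1)) % (2**31)
    out = []
    for ph, child in zip(ph_list, children):
        frac = float(protonated_fraction(ph, sensor.pka))
        out.append(
            (
                float(ph),
                render_uniform_field(
                    frac, sensor, irf, acq, seed=int(child), af_fraction=af_fraction
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# stimulation

def _ramp15(minutes: float) -> float:
    return min(max(minutes, 0.0), 15.0) / 15.0


def standard_stimulus(name: str) -> StimulusModel:
    """Factory for the four modeled conditions.

    Magnitudes are free parameters chosen to reproduce the qualitative
    signatures of the three insulinotropic stimuli: glucose secretes acidic
    (pH < 5.2) peripheral granules selectively and mildly acidifies a
    less-acidic pool; KCl (depolarization) secretes peripheral granules
    across a broader range (pH < 5.5) and transiently alkalinizes granules
    that merge with the membrane; exendin-4 drives maturation
    (acidification) with no secretion — counts are unchanged in the first
    15 min and only basal-like losses appear later.
    """
    if name == "none":
        return StimulusModel(
            name="none",
            secretion_rule=lambda ph, dist: 0.0,
            acidification_rule=lambda ph, t: 0.0,
            basal_loss=0.03,
        )
    if name == "glucose":
        return StimulusModel(
            name="glucose",
            secretion_rule=lambda ph, dist: (
                0.45 if (dist < 0.15 and ph < 5.2) else (0.06 if dist < 0.15 else 0.02)
            ),
            acidification_rule=lambda ph, t: (-0.20 * _ramp15(t) if ph > 5.4 else 0.0),
            basal_loss=0.03,
        )
    if name == "kcl":
        return StimulusModel(
            name="kcl",
            secretion_rule=lambda ph, dist: (
                0.55 if (dist < 0.15 and ph < 5.5) else (0.10 if dist < 0.15 else 0.02)
            ),
            acidification_rule=lambda ph, t: (+0.25 * _ramp15(t) if ph > 5.3 else 0.0),
            basal_loss=0.03,
        )
    if name == "ex4":
        return StimulusModel(
            name="ex4",
            secretion_rule=lambda ph, dist: 0.0,
            acidification_rule=lambda ph, t: (
                -0.5 * min(max(t, 0.0), 40.0) / 40.0 * min(max((ph - 4.5) / 1.2, 0.0), 1.0)
            ),
            basal_loss=0.08,
            basal_delay=15.0,
        )
    raise ValueError(f"unknown stimulus '{name}'")


def apply_stimulus(
    scene: CellScene,
    stimulus: StimulusModel,
    minutes: float,
    seed: int,
) -> CellScene:
    """Granule population observed ``minutes`` after stimulus onset.

    Each granule is removed with probability ``secretion_rule(ph, dist) *
    ramp(minutes) + basal_loss * [minutes > basal_delay]`` (ramp saturating
    at 15 min), and surviving granules' pH is shifted by the acidification
    rule plus a small per-granule jitter.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    depth = ndimage.distance_transform_edt(scene.cell_mask)
    max_depth = max(depth.max(), 1.0)
    survivors: list[GranuleTruth] = []
    for gr in scene.granules:
        yy, xx = int(round(gr.centroid[0])), int(round(gr.centroid[1]))
        dist = depth[yy, xx] / max_depth
        p = stimulus.secretion_rule(gr.true_ph, dist) * _ramp15(minutes)
        if minutes > stimulus.basal_delay:
            p += stimulus.basal_loss
        p = min(max(p, 0.0), 1.0)
        if rng.uniform() < p:
            continue
        dph = stimulus.acidification_rule(gr.true_ph, minutes)
        if dph != 0.0 and stimulus.ph_jitter > 0:
            dph += rng.normal(0.0, stimulus.ph_jitter)
        new_ph = float(np.clip(gr.true_ph + dph, 3.5, 8.5))
        survivors.append(replace(gr, true_ph=new_ph))
    return CellScene(
        cell_mask=scene.cell_mask,
        granules=survivors,
        autofluorescence=scene.autofluorescence,
        background_counts=scene.background_counts,
        timepoint=scene.timepoint + minutes,
        pixel_size=scene.pixel_size,
    )


# ---------------------------------------------------------------------------
# canonical population specs

def landscape_populations(
    n_peripheral: int = 40, n_interior: int = 30
) -> list[GranulePopulation]:
    """Distance-stratified granule pH populations of a healthy cell.

    Peripheral granules span a broad pH range (quartiles ~[4.8, 5.8]) while
    interior granules lean acidic (quartiles ~[4.2, 5.0]); standard
    deviations are IQR_width/1.349 of those intervals.  With the default
    40:30 mix the population mean pH is 5.0.
    """
    return [
        GranulePopulation(
            name="peripheral",
            n=n_peripheral,
            ph_mean=5.3,
            ph_sd=0.741,
            ph_range=(3.8, 7.4),
            depth_range=(0.0, 0.08),
        ),
        GranulePopulation(
            name="interior",
            n=n_interior,
            ph_mean=4.6,
            ph_sd=0.593,
            ph_range=(3.8, 7.4),
            depth_range=(0.25, 1.0),
        ),
    ]


def uncertainty_population(n: int = 50) -> list[GranulePopulation]:
    """Stationary granules spanning pH 4.5–6.5 for repeat-imaging studies."""
    return [
        GranulePopulation(
            name="stationary",
            n=n,
            ph_dist="uniform",
            ph_range=(4.5, 6.5),
            depth_range=(0.05, 0.95),
            mobility=0.0,
        )
    ]
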