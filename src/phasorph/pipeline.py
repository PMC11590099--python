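"""End-to-end experiment orchestration.

Ties the stages together into the three canonical studies:

* ``run_titration`` — an in-cellulo-style calibration: uniform sensor
  fields across pH 4.0–7.6, endpoint derivation from donor-only and pH-8
  fields, a third-order calibration curve and an apparent pKa;
* ``run_uncertainty`` — four repeated acquisitions of one scene of
  stationary granules, segmentation, matching, and per-track pH standard
  deviations;
* ``run_landscape`` — distance-stratified population recovery over several
  scenes;
* ``run_stimulation`` — pre / acute / prolonged time bins under a secretion
  or maturation stimulus, with pairwise KS comparisons.

One experiment seed fans out deterministically into per-stage child seeds
so stages can be re-run independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import simulate
from .calibration import (
    CalibrationCurve,
    EndpointPair,
    derive_endpoints,
    fit_calibration,
    protonation_map,
)
from .phasor import (
    IRFModel,
    PhasorImage,
    PhasorPoint,
    TCSPCStack,
    calibrate_phasor,
    decay_shape,
    mono_exp_phasor,
    phasor_transform,
    wavelet_filter,
)
from .profiles import (
    TIMEBINS,
    ProfileComparison,
    UncertaintyReport,
    compare_profiles,
    measurement_uncertainty,
    ph_landscape,
)
from .segmentation import (
    build_records,
    detect_granules,
    match_granules,
    segment_cell,
)
from .simulate import (
    AcquisitionParams,
    CellScene,
    SensorModel,
    protonated_fraction,
)

__all__ = [
    "default_sensor",
    "default_irf",
    "calibration_acquisition",
    "live_acquisition",
    "reference_pair",
    "stack_to_phasor",
    "TitrationResult",
    "run_titration",
    "analyze_scene",
    "run_uncertainty",
    "run_landscape",
    "run_stimulation",
]

#: lifetime (ns) of the simulated calibration reference decay
REFERENCE_TAU = 2.5
#: default wavelet-shrinkage depth for pixel-level denoising
FILTER_LEVELS = 2


def default_sensor() -> SensorModel:
    return SensorModel()


def default_irf() -> IRFModel:
    return IRFModel(center=1.0, sigma=0.15)


def calibration_acquisition(frame: int = 64) -> AcquisitionParams:
    """Calibration fields: 20 acquisition repetitions at ~50 counts each."""
    return AcquisitionParams(frame_shape=(frame, frame), target_median_counts=20 * 50.0)


def live_acquisition(
    frame: int = 256, target_median_counts: float = 70.0
) -> AcquisitionParams:
    """Live single-cell imaging at the working photon budget (median 60–80)."""
    return AcquisitionParams(
        frame_shape=(frame, frame), target_median_counts=target_median_counts
    )


def reference_pair(
    acq: AcquisitionParams, irf: IRFModel, tau_ref: float = REFERENCE_TAU
) -> tuple[PhasorPoint, PhasorPoint]:
    """(measured, true) phasor pair of the simulated calibration reference.

    The measured point is the noiseless phasor of a ``tau_ref`` decay
    rendered through the same IRF and binning as the data; the true point
    is its closed-form semicircle position.  Calibrating with this pair
    removes the IRF phase/modulation and the histogram discretization.
    """
    omega = 2.0 * np.pi * acq.rep_rate * 1e-9
    shape = decay_shape(tau_ref, irf, acq.n_bins, acq.period)
    t = (np.arange(acq.n_bins) + 0.5) * acq.bin_width
    g = float(shape @ np.cos(omega * t))
    s = float(shape @ np.sin(omega * t))
    return PhasorPoint(g, s), mono_exp_phasor(tau_ref, omega)


def stack_to_phasor(
    stack: TCSPCStack,
    irf: IRFModel,
    acq: AcquisitionParams,
    filter_levels: int | None = FILTER_LEVELS,
    harmonic: int = 1,
) -> PhasorImage:
    """Transform, instrument-calibrate and (optionally) denoise a stack."""
    img = phasor_transform(stack, harmonic=harmonic)
    measured, true = reference_pair(acq, irf)
    img = calibrate_phasor(img, measured, true)
    if filter_levels:
        img = wavelet_filter(img, levels=filter_levels)
    return img


@dataclass
class TitrationResult:
    curve: CalibrationCurve
    endpoints: EndpointPair
    table: pd.DataFrame  # columns: ph, fraction_true, fraction_measured, iqr

    @property
    def apparent_pka(self) -> float:
        return self.curve.apparent_pka


def run_titration(
    seed: int,
    sensor: SensorModel | None = None,
    irf: IRFModel | None = None,
    acq: AcquisitionParams | None = None,
    n_ph: int = 12,
    ph_range: tuple[float, float] = (4.0, 7.6),
    af_fraction: float = 0.0,
    filter_levels: int | None = FILTER_LEVELS,
) -> TitrationResult:
    """Synthetic in-cellulo titration through the full phasor pipeline.

    Renders uniform sensor fields at ``n_ph`` pH values, derives the
    endpoint anchors from donor-only and pH-8 fields, computes the mean
    measured %Protonation per pH and fits the calibration curve.
    ``af_fraction`` adds a share of autofluorescence photons to every
    field (useful for contamination-robustness studies; granule
    measurements subtract their local background, so the default
    calibration is clean).
    """
    sensor = sensor or default_sensor()
    irf = irf or default_irf()
    acq = acq or calibration_acquisition()
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(2**31))  # noqa: E731

    def field_image(fraction: float) -> PhasorImage:
        stack = simulate.render_uniform_field(
            fraction, sensor, irf, acq, seed=child(), af_fraction=af_fraction
        )
        return stack_to_phasor(stack, irf, acq, filter_levels=filter_levels)

    donor_only = field_image(1.0)
    ph8 = field_image(float(protonated_fraction(8.0, sensor.pka)))
    endpoints = derive_endpoints(donor_only, ph8)

    ph_values = np.linspace(ph_range[0], ph_range[1], n_ph)
    rows = []
    for ph in ph_values:
        frac_true = float(protonated_fraction(ph, sensor.pka))
        img = field_image(frac_true)
        fr = protonation_map(img, endpoints)
        fr = fr[np.isfinite(fr)]
        rows.append(
            {
                "ph": float(ph),
                "fraction_true": frac_true,
                "fraction_measured": float(fr.mean()),
                "iqr": float(np.percentile(fr, 75) - np.percentile(fr, 25)),
            }
        )
    table = pd.DataFrame(rows)
    curve = fit_calibration(
        table[["ph", "fraction_measured"]].to_numpy(), valid_range=ph_range
    )
    curve.provenance.update({"seed": seed, "af_fraction": af_fraction})
    return TitrationResult(curve=curve, endpoints=endpoints, table=table)


def analyze_scene(
    stack: TCSPCStack,
    endpoints: EndpointPair,
    curve: CalibrationCurve,
    irf: IRFModel,
    acq: AcquisitionParams,
    timepoint: float = 0.0,
    cell_id: int = 0,
    filter_levels: int | None = FILTER_LEVELS,
    qc_median_photons: float = 60.0,
    detection_threshold: float = 0.3,
    records_from_filtered: bool = False,
):
    """Full single-frame chain: phasor -> filter -> segment -> records.

    The wavelet-filtered image drives pixel-level products (it is what is
    returned for maps and histograms), but per-granule records are pooled
    from the unfiltered calibrated image by default: ROI pooling is already
    the optimal photon-weighted average, and pre-smoothing correlates pixel
    noise and leaks neighbouring cytosol signal into the ROI.  Set
    ``records_from_filtered`` to mirror a strictly pixel-filtered chain.

    Returns (records, cell_mask, rois, phasor_image) with the filtered
    image in the last slot.
    """
    img_cal = stack_to_phasor(stack, irf, acq, filter_levels=None)
    img = (
        wavelet_filter(img_cal, levels=filter_levels) if filter_levels else img_cal
    )
    cell = segment_cell(img.photons)
    rois = detect_granules(
        img.photons,
        cell,
        pixel_size_nm=acq.pixel_size,
        threshold=detection_threshold,
    )
    records = build_records(
        img if records_from_filtered else img_cal,
        rois,
        endpoints,
        curve,
        cell,
        timepoint=timepoint,
        cell_id=cell_id,
        qc_median_photons=qc_median_photons,
    )
    return records, cell, rois, img


@dataclass
class UncertaintyExperiment:
    report: UncertaintyReport
    n_detected: list[int] = field(default_factory=list)
    n_tracked: int = 0


def run_uncertainty(
    seed: int,
    n_granules: int = 50,
    n_repeats: int = 4,
    n_scenes: int = 4,
    target_median_counts: float = 70.0,
    titration: TitrationResult | None = None,
    max_displacement: float = 3.0,
) -> UncertaintyExperiment:
    """Repeat-imaging measurement uncertainty on stationary scenes.

    Each of ``n_scenes`` scenes holds ``n_granules`` stationary granules
    spanning pH 4.5–6.5 and is rendered ``n_repeats`` times with
    independent Poisson noise; every frame runs the full analysis chain,
    granules are matched across the repeats of their scene, and the
    per-track pH standard deviation is averaged over all tracks.
    """
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(2**31))  # noqa: E731
    sensor, irf = default_sensor(), default_irf()
    acq = live_acquisition(target_median_counts=target_median_counts)
    if titration is None:
        titration = run_titration(child())
    all_sds: list[float] = []
    n_detected = []
    n_tracked = 0
    for _ in range(n_scenes):
        scene = simulate.make_scene(
            simulate.uncertainty_population(n_granules),
            seed=child(),
            shape=acq.frame_shape,
        )
        frames = []
        for _ in range(n_repeats):
            stack = simulate.render_decay_stack(scene, sensor, irf, acq, seed=child())
            records, _, rois, _ = analyze_scene(
                stack, titration.endpoints, titration.curve, irf, acq
            )
            # only readings meeting the photon-budget criterion qualify
            frames.append([r for r in records if r.ph_valid and r.qc_pass])
            n_detected.append(len(rois))
        tracks = match_granules(frames, max_displacement=max_displacement)
        n_tracked += len(tracks)
        all_sds.extend(
            measurement_uncertainty(tracks, curve=titration.curve).per_track_sd
        )
    report = UncertaintyReport(
        per_track_sd=all_sds, mean_sd=float(np.mean(all_sds)), n_tracks=len(all_sds)
    )
    return UncertaintyExperiment(
        report=report, n_detected=n_detected, n_tracked=n_tracked
    )


@dataclass
class LandscapeResult:
    records: list
    mean_ph: float
    peripheral_central50: tuple[float, float]
    interior_central50: tuple[float, float]
    n_scenes: int


def run_landscape(
    seed: int,
    n_scenes: int = 10,
    titration: TitrationResult | None = None,
    split_distance: float = 0.15,
) -> LandscapeResult:
    """Distance-stratified pH landscape recovered over several scenes.

    Scenes carry the canonical peripheral/interior populations; all
    detected granule records are pooled, and the peripheral and interior
    central-50% pH intervals are computed with the membrane-distance split
    at ``split_distance`` (between the generator's placement bands).
    """
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(2**31))  # noqa: E731
    sensor, irf = default_sensor(), default_irf()
    acq = live_acquisition()
    if titration is None:
        titration = run_titration(child())
    all_records = []
    for cell_id in range(n_scenes):
        scene = simulate.make_scene(
            simulate.landscape_populations(), seed=child(), shape=acq.frame_shape
        )
        stack = simulate.render_decay_stack(scene, sensor, irf, acq, seed=child())
        records, _, _, _ = analyze_scene(
            stack, titration.endpoints, titration.curve, irf, acq, cell_id=cell_id
        )
        all_records.extend(r for r in records if r.ph_valid)
    ph = np.array([r.ph for r in all_records])
    periph = np.array([r.ph for r in all_records if r.norm_distance < split_distance])
    inter = np.array([r.ph for r in all_records if r.norm_distance >= split_distance])
    q = lambda a: tuple(np.percentile(a, [25, 75])) if a.size else (np.nan, np.nan)  # noqa: E731
    return LandscapeResult(
        records=all_records,
        mean_ph=float(ph.mean()),
        peripheral_central50=q(periph),
        interior_central50=q(inter),
        n_scenes=n_scenes,
    )


def run_stimulation(
    seed: int,
    stimulus_name: str = "glucose",
    n_cells: int = 4,
    titration: TitrationResult | None = None,
    peripheral_threshold: float = 0.05,
    timepoints: tuple[float, float] = (8.0, 28.0),
) -> ProfileComparison:
    """Stimulation-response comparison across the canonical time bins.

    For each cell, the pre-stimulus scene and its evolutions at the acute
    (1–15 min, sampled at ``timepoints[0]``) and prolonged (16–40 min,
    sampled at ``timepoints[1]``) phases are rendered and analyzed;
    peripheral records (normalized distance < ``peripheral_threshold``)
    are pooled per time bin and compared pairwise by KS test.
    """
    from .profiles import classify_peripheral

    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(2**31))  # noqa: E731
    sensor, irf = default_sensor(), default_irf()
    acq = live_acquisition()
    if titration is None:
        titration = run_titration(child())
    stim = simulate.standard_stimulus(stimulus_name)
    by_bin = {lab: [] for lab in TIMEBINS}
    for cell_id in range(n_cells):
        scene0 = simulate.make_scene(
            simulate.landscape_populations(), seed=child(), shape=acq.frame_shape
        )
        scenes = {
            TIMEBINS[0]: scene0,
            TIMEBINS[1]: simulate.apply_stimulus(scene0, stim, timepoints[0], child()),
            TIMEBINS[2]: simulate.apply_stimulus(scene0, stim, timepoints[1], child()),
        }
        for lab, scene in scenes.items():
            stack = simulate.render_decay_stack(scene, sensor, irf, acq, seed=child())
            records, _, _, _ = analyze_scene(
                stack, titration.endpoints, titration.curve, irf, acq,
                timepoint=scene.timepoint, cell_id=cell_id,
            )
            peripheral, _ = classify_peripheral(
                [r for r in records if r.ph_valid], threshold=peripheral_threshold
            )
            by_bin[lab].extend(peripheral)
    return compare_profiles(by_bin)
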