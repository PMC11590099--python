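"""Population-level statistics on per-granule records.

Covers the three analyses built on top of single-granule pH measurements:
repeat-imaging measurement uncertainty (per-track pH standard deviations),
distance-stratified pH landscapes (kernel-smoothed distributions per
normalized-membrane-distance bin), and stimulation-response comparisons
(pairwise two-sample Kolmogorov–Smirnov tests across time bins plus
per-%Protonation-bin count changes).

Statistics are computed on the measured %Protonation scale; pH views are
derived through the calibration curve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import CalibrationCurve, fraction_to_ph
from .segmentation import GranuleTrack, ISGRecord

__all__ = [
    "UncertaintyReport",
    "PHProfile",
    "ProfileComparison",
    "measurement_uncertainty",
    "ph_landscape",
    "classify_peripheral",
    "compare_profiles",
    "delta_histogram",
    "significance_tier",
]

#: default time-bin labels: before stimulation, acute phase, prolonged phase
TIMEBINS = ("pre", "1-15", "16-40")


@dataclass
class UncertaintyReport:
    per_track_sd: list[float]
    mean_sd: float
    n_tracks: int

    def __post_init__(self) -> None:
        if self.n_tracks != len(self.per_track_sd):
            raise ValueError("n_tracks inconsistent with per_track_sd")
        if self.mean_sd < 0:
            raise ValueError("mean_sd must be >= 0")


@dataclass
class PHProfile:
    """Values and smoothed density of one normalized-distance bin."""

    distance_bin: tuple[float, float]
    values: np.ndarray
    grid: np.ndarray | None
    smoothed_density: np.ndarray | None
    mean_value: float
    central50: tuple[float, float]  # (25th, 75th percentile)
    n_excluded: int = 0


@dataclass
class ProfileComparison:
    labels: list[str]
    pairwise_ks: dict  # (label_a, label_b) -> (statistic, p)
    tiers: dict  # (label_a, label_b) -> tier string
    holm_tiers: dict  # extension: Holm-corrected tier per pair
    counts: dict  # label -> n records
    delta_edges: np.ndarray
    delta_hist: np.ndarray  # count change first -> second label
    undersized: list[str] = field(default_factory=list)


def _valid_ph(records) -> np.ndarray:
    return np.array(
        [r.ph for r in records if r.ph_valid and np.isfinite(r.ph)], float
    )


def _valid_fraction(records) -> np.ndarray:
    return np.array(
        [
            r.percent_protonation
            for r in records
            if np.isfinite(r.percent_protonation)
        ],
        float,
    )


def measurement_uncertainty(
    tracks: list[GranuleTrack],
    curve: CalibrationCurve | None = None,
) -> UncertaintyReport:
    """Per-track standard deviation of pH across repeats, and its mean.

    Tracks contribute if they hold >= 2 records with a valid pH.  If
    ``curve`` is given, pH values are (re)derived from each record's
    %Protonation through the curve so the report is consistent with a
    specific calibration.
    """
    sds = []
    for track in tracks:
        if curve is not None:
            fr = _valid_fraction(track.records)
            ph, in_range = fraction_to_ph(curve, np.clip(fr, 0.0, 1.0))
            ph = ph[in_range]
        else:
            ph = _valid_ph(track.records)
        if ph.size >= 2:
            sds.append(float(np.std(ph, ddof=1)))
    if not sds:
        raise ValueError("no eligible tracks (need >= 2 valid pH values each)")
    return UncertaintyReport(per_track_sd=sds, mean_sd=float(np.mean(sds)), n_tracks=len(sds))


def ph_landscape(
    records: list[ISGRecord],
    bin_edges,
    value: str = "ph",
    grid_points: int = 200,
) -> list[PHProfile]:
    """Distance-stratified pH (or %Protonation) profiles.

    Records are split by ``norm_distance`` into [lo, hi) bins; each
    nonempty bin gets its values, a Gaussian kernel density (Silverman
    bandwidth) on a common grid, the mean, and the central-50% interval.
    Flagged records (invalid pH) are excluded and counted.
    """
    if value not in ("ph", "fraction"):
        raise ValueError("value must be 'ph' or 'fraction'")
    edges = np.asarray(bin_edges, float)
    getter = (lambda r: r.ph) if value == "ph" else (lambda r: r.percent_protonation)
    all_valid = [
        getter(r)
        for r in records
        if r.ph_valid and np.isfinite(getter(r))
    ]
    if all_valid:
        lo_g, hi_g = min(all_valid), max(all_valid)
        pad = 0.05 * max(hi_g - lo_g, 1e-6)
        grid = np.linspace(lo_g - pad, hi_g + pad, grid_points)
    else:
        grid = None
    profiles = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [r for r in records if lo <= r.norm_distance < hi]
        vals = np.array(
            [getter(r) for r in in_bin if r.ph_valid and np.isfinite(getter(r))]
        )
        n_excl = len(in_bin) - vals.size
        if vals.size == 0:
            profiles.append(
                PHProfile((lo, hi), vals, None, None, float("nan"), (float("nan"),) * 2, n_excl)
            )
            continue
        if vals.size >= 3 and np.std(vals) > 0 and grid is not None:
            kde = stats.gaussian_kde(vals, bw_method="silverman")
            dens = kde(grid)
        else:
            dens = None
        q25, q75 = np.percentile(vals, [25, 75])
        profiles.append(
            PHProfile(
                distance_bin=(float(lo), float(hi)),
                values=vals,
                grid=grid if dens is not None else None,
                smoothed_density=dens,
                mean_value=float(vals.mean()),
                central50=(float(q25), float(q75)),
                n_excluded=n_excl,
            )
        )
    return profiles


def classify_peripheral(
    records: list[ISGRecord], threshold: float = 0.05
) -> tuple[list[ISGRecord], list[ISGRecord]]:
    """Partition records into (peripheral, interior) by membrane distance.

    Peripheral means normalized distance strictly less than ``threshold``;
    a record exactly at the threshold is interior.
    """
    peripheral = [r for r in records if r.norm_distance < threshold]
    interior = [r for r in records if not r.norm_distance < threshold]
    return peripheral, interior


def significance_tier(p: float, boundaries=(0.05, 0.01, 0.001, 0.0001)) -> str:
    """Star notation: ns above 0.05, then one star per decade down to ****."""
    if p > boundaries[0]:
        return "ns"
    for stars, (hi, lo) in enumerate(zip(boundaries[:-1], boundaries[1:]), start=1):
        if lo < p <= hi:
            return "*" * stars
    return "*" * len(boundaries)


def compare_profiles(
    records_by_timebin: dict,
    alpha_tiers=(0.05, 0.01, 0.001, 0.0001),
    min_n: int = 5,
    delta_bins: int = 20,
) -> ProfileComparison:
    """Pairwise KS comparison of %Protonation distributions across time bins.

    Every pair of time bins with at least ``min_n`` valid records is
    compared with a two-sample Kolmogorov–Smirnov test; tier labels follow
    the star convention at ``alpha_tiers``.  Undersized bins are reported,
    not silently skipped (their pairs carry NaN statistics and the tier
    "undersized").  A Holm-corrected tier per pair is attached as an
    extension; the primary tiers are uncorrected.  The count-change
    histogram is taken between the first two bins.
    """
    labels = list(records_by_timebin)
    if len(labels) < 2:
        raise ValueError("need >= 2 timebins to compare")
    samples = {lab: _valid_fraction(records_by_timebin[lab]) for lab in labels}
    counts = {lab: int(samples[lab].size) for lab in labels}
    undersized = [lab for lab in labels if counts[lab] < min_n]
    pairwise = {}
    tiers = {}
    pvals = {}
    for a, b in itertools.combinations(labels, 2):
        if a in undersized or b in undersized:
            pairwise[(a, b)] = (float("nan"), float("nan"))
            tiers[(a, b)] = "undersized"
            continue
        res = stats.ks_2samp(samples[a], samples[b], method="auto")
        pairwise[(a, b)] = (float(res.statistic), float(res.pvalue))
        tiers[(a, b)] = significance_tier(float(res.pvalue), alpha_tiers)
        pvals[(a, b)] = float(res.pvalue)
    # Holm step-down correction (extension; not the headline labels)
    holm_tiers = {k: "undersized" for k in pairwise if k not in pvals}
    if pvals:
        items = sorted(pvals.items(), key=lambda kv: kv[1])
        m = len(items)
        running_max = 0.0
        for rank, (key, p) in enumerate(items):
            adj = min(1.0, (m - rank) * p)
            running_max = max(running_max, adj)
            holm_tiers[key] = significance_tier(running_max, alpha_tiers)
    first_two = labels[:2]
    edges, delta = delta_histogram(
        records_by_timebin[first_two[0]],
        records_by_timebin[first_two[1]],
        n_bins=delta_bins,
    )
    return ProfileComparison(
        labels=labels,
        pairwise_ks=pairwise,
        tiers=tiers,
        holm_tiers=holm_tiers,
        counts=counts,
        delta_edges=edges,
        delta_hist=delta,
        undersized=undersized,
    )


def delta_histogram(
    records_t0: list[ISGRecord],
    records_t1: list[ISGRecord],
    n_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-%Protonation-bin count change between two timepoints.

    Returns (bin_edges over [0, 1], count(t1) - count(t0)); the vector sums
    to the total granule-count change.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    h0, _ = np.histogram(_valid_fraction(records_t0), bins=edges)
    h1, _ = np.histogram(_valid_fraction(records_t1), bins=edges)
    return edges, (h1 - h0).astype(int)
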