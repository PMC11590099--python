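"""Endpoint derivation, %Protonation projection and the pH calibration curve.

%Protonation is the fractional position of a pixel or ROI phasor along the
segment between the two pure-state anchors: ``p0`` (0% protonation, FRET on,
short lifetime) and ``p100`` (100% protonation, donor only, long lifetime).
The anchors are taken as the modes of the phasor histograms of a donor-only
acquisition and of sensor held at pH 8 (protonated fraction ~0.5%), both
recorded in the cellular context so autofluorescence contamination enters
the anchors the same way it enters the measurements.

A third-order polynomial fitted to (pH, mean %Protonation) titration points
is the working calibration; it is numerically inverted to convert fractions
back to pH.  A Henderson–Hasselbalch sigmoid is fitted separately and used
only to report the apparent pKa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .phasor import PhasorImage, PhasorPoint, histogram_mode

__all__ = [
    "EndpointPair",
    "CalibrationCurve",
    "derive_endpoints",
    "project_fraction",
    "protonation_map",
    "fit_calibration",
    "fraction_to_ph",
]

_INV_GRID_N = 4001


@dataclass
class EndpointPair:
    """The 0%/100% protonation phasor anchors."""

    p0: PhasorPoint  # FRET-on, deprotonated, short lifetime (larger g)
    p100: PhasorPoint  # donor-only, protonated, long lifetime (smaller g)

    def __post_init__(self) -> None:
        if self.separation == 0:
            raise ValueError("degenerate endpoint pair (p0 == p100)")

    @property
    def separation(self) -> float:
        return float(np.hypot(self.p100.g - self.p0.g, self.p100.s - self.p0.s))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from p0 toward p100 (the %Protonation axis)."""
        d = self.p100.as_array() - self.p0.as_array()
        return d / np.linalg.norm(d)


@dataclass
class CalibrationCurve:
    """Third-order polynomial mapping pH -> %Protonation (fraction).

    ``poly_coeffs`` are in numpy.polyval order (highest degree first); the
    polynomial must be monotone decreasing on ``valid_range``.
    ``apparent_pka`` comes from a separate sigmoid fit and is reported, not
    used for inversion.
    """

    poly_coeffs: np.ndarray
    apparent_pka: float
    valid_range: tuple[float, float] = (4.0, 7.6)
    provenance: dict = field(default_factory=dict)
    _inv_grid: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.poly_coeffs = np.asarray(self.poly_coeffs, float)
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("invalid valid_range")
        grid = np.linspace(lo, hi, 512)
        dp = np.polyval(np.polyder(self.poly_coeffs), grid)
        if np.any(dp >= 0):
            raise ValueError("calibration polynomial is not monotone decreasing")
        if not (lo <= self.apparent_pka <= hi):
            raise ValueError("apparent_pka outside valid_range")

    def fraction_at(self, ph) -> np.ndarray:
        """Evaluate the calibration polynomial (pH -> fraction)."""
        return np.polyval(self.poly_coeffs, np.asarray(ph, float))

    @property
    def attainable_range(self) -> tuple[float, float]:
        """(min, max) fraction reachable on valid_range."""
        lo, hi = self.valid_range
        return float(self.fraction_at(hi)), float(self.fraction_at(lo))


def derive_endpoints(
    donor_only: PhasorImage,
    fret_max: PhasorImage,
    bin_width: float = 0.01,
    min_separation: float = 0.05,
) -> EndpointPair:
    """Pure-state anchors from the histogram modes of two reference images.

    ``donor_only`` is an acquisition of the donor-only construct (100%
    protonation surrogate); ``fret_max`` of sensor at pH 8 (0% protonation
    surrogate).  The donor-only anchor must sit at the longer-lifetime
    (smaller g) position; an inverted orientation or a separation below
    ``min_separation`` raises.
    """
    p100 = histogram_mode(donor_only, bin_width=bin_width)
    p0 = histogram_mode(fret_max, bin_width=bin_width)
    pair_sep = float(np.hypot(p100.g - p0.g, p100.s - p0.s))
    if pair_sep < min_separation:
        raise ValueError(
            f"endpoint separation {pair_sep:.4f} below minimum {min_separation}"
        )
    if not p100.g < p0.g:
        raise ValueError(
            "endpoint orientation inverted: donor-only anchor must have the "
            "longer lifetime (smaller g)"
        )
    return EndpointPair(p0=p0, p100=p100)


def project_fraction(point: PhasorPoint, endpoints: EndpointPair) -> float:
    """%Protonation of a single phasor point (orthogonal projection, clipped).

    The projection onto the p0->p100 segment discards displacement
    perpendicular to the segment (the maximum-likelihood position under
    isotropic phasor noise); the result is clipped to [0, 1].
    """
    d = endpoints.p100.as_array() - endpoints.p0.as_array()
    rel = point.as_array() - endpoints.p0.as_array()
    t = float(rel @ d / (d @ d))
    return float(np.clip(t, 0.0, 1.0))


def protonation_map(image: PhasorImage, endpoints: EndpointPair) -> np.ndarray:
    """Per-pixel %Protonation (fraction in [0, 1]; NaN at invalid pixels)."""
    d = endpoints.p100.as_array() - endpoints.p0.as_array()
    denom = float(d @ d)
    t = ((image.g - endpoints.p0.g) * d[0] + (image.s - endpoints.p0.s) * d[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.where(image.valid, t, np.nan)


def _monotone_cubic(
    ph: np.ndarray, frac: np.ndarray, valid_range: tuple[float, float]
) -> np.ndarray:
    """Least-squares cubic constrained to be decreasing on valid_range.

    An unconstrained cubic fitted to a sigmoid typically wiggles upward at
    the flat ends of the titration range; the derivative is therefore
    constrained to stay below a small negative margin on a dense grid.
    """
    margin = 1e-4
    grid = np.linspace(valid_range[0], valid_range[1], 101)
    c0 = np.polyfit(ph, frac, deg=3)
    vals0 = np.polyval(c0, grid)
    if (
        np.all(np.polyval(np.polyder(c0), grid) <= -margin)
        and vals0.min() >= 0.0
        and vals0.max() <= 1.0
    ):
        return c0

    # convex QP: quadratic objective ||A c - frac||^2 with linear
    # constraints (derivative below -margin, values inside [0, 1] on grid)
    A = np.vander(ph, 4)
    D = np.column_stack([3 * grid**2, 2 * grid, np.ones_like(grid), np.zeros_like(grid)])
    G = np.vander(grid, 4)
    H = A.T @ A
    b = A.T @ frac

    res = optimize.minimize(
        lambda c: float(c @ H @ c - 2 * b @ c),
        c0,
        jac=lambda c: 2 * (H @ c - b),
        method="trust-constr",
        constraints=[
            optimize.LinearConstraint(D, -np.inf, -margin),
            optimize.LinearConstraint(G, 0.0, 1.0),
        ],
        options={"maxiter": 2000, "gtol": 1e-12, "xtol": 1e-14},
    )
    if not res.success:
        raise ValueError(f"monotone cubic fit failed: {res.message}")
    return np.asarray(res.x, float)


def _sigmoid(ph, top, bottom, pka):
    return bottom + (top - bottom) / (1.0 + np.power(10.0, ph - pka))


def fit_calibration(
    points,
    valid_range: tuple[float, float] = (4.0, 7.6),
) -> CalibrationCurve:
    """Fit the titration table to the working curve and the reporting sigmoid.

    ``points`` is a sequence of (pH, mean %Protonation) pairs covering the
    sigmoid transition (>= 5 distinct pH values required).  The third-order
    least-squares polynomial is stored and checked for monotonicity on
    ``valid_range``; the apparent pKa is the midpoint of a separate
    Henderson–Hasselbalch sigmoid fit with free endpoints.
    """
    pts = np.asarray(list(points), float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (pH, fraction) pairs")
    ph, frac = pts[:, 0], pts[:, 1]
    if np.unique(ph).size < 5:
        raise ValueError("need >= 5 distinct pH values spanning the transition")
    if np.polyfit(ph, frac, deg=1)[0] >= 0:
        raise ValueError("titration data are not decreasing in pH")
    coeffs = _monotone_cubic(ph, frac, valid_range)
    p0 = (float(frac.max()), float(frac.min()), float(np.median(ph)))
    popt, _ = optimize.curve_fit(
        _sigmoid,
        ph,
        frac,
        p0=p0,
        bounds=([0.0, -0.2, valid_range[0]], [1.2, 1.0, valid_range[1]]),
        maxfev=20000,
    )
    apparent_pka = float(popt[2])
    return CalibrationCurve(
        poly_coeffs=coeffs,
        apparent_pka=apparent_pka,
        valid_range=valid_range,
        provenance={
            "n_points": int(ph.size),
            "sigmoid_top": float(popt[0]),
            "sigmoid_bottom": float(popt[1]),
        },
    )


def _inversion_grid(curve: CalibrationCurve):
    if curve._inv_grid is None:
        lo, hi = curve.valid_range
        ph_grid = np.linspace(lo, hi, _INV_GRID_N)
        f_grid = curve.fraction_at(ph_grid)
        # fraction decreases with pH: reverse for np.interp
        curve._inv_grid = (f_grid[::-1].copy(), ph_grid[::-1].copy())
    return curve._inv_grid


def fraction_to_ph(curve: CalibrationCurve, fraction):
    """Invert the calibration polynomial: fraction -> (pH, in_range).

    Fractions must lie in [0, 1].  Values outside the curve's attainable
    range clamp to the corresponding end of ``valid_range`` and are flagged
    ``in_range=False``.  Scalar in, scalar out; array in, array out.
    """
    f = np.asarray(fraction, float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    if np.any(~np.isfinite(f)) or np.any(f < 0) or np.any(f > 1):
        raise ValueError("fraction must be finite and within [0, 1]")
    fmin, fmax = curve.attainable_range
    in_range = (f >= fmin) & (f <= fmax)
    f_grid, ph_grid = _inversion_grid(curve)
    ph = np.interp(np.clip(f, fmin, fmax), f_grid, ph_grid)
    if scalar:
        return float(ph[0]), bool(in_range[0])
    return ph, in_range
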