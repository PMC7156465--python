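"""Analysis of ramp-to-failure force-displacement curves.

Forearm interosseous-membrane ligaments fail biphasically: after a toe
region and a linear range, the thinner fibres fail first (a local force
peak followed by a drop), then the main bundle carries load up to the
ultimate force.  This module extracts the initial trapezoid CSA, the
linear-region stiffness, both peak forces, the ultimate strain and the
nominal stress from such curves.  Strain is grip-to-grip:
displacement / gauge length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientDataError,
    InsufficientLoadError,
    ValidationError,
)
from .io_core import PipelineConfig, TensileCurve


def trapezoid_csa(width_radial: float, width_ulnar: float, mean_thickness: float) -> float:
    """Initial cross-sectional area (mm^2) as a trapezoid: the average of
    the radial and ulnar attachment widths times the mean thickness."""
    if width_radial <= 0 or width_ulnar <= 0 or mean_thickness <= 0:
        raise ValidationError("widths and thickness must be positive")
    return 0.5 * (width_radial + width_ulnar) * mean_thickness


def nominal_stress(force: float, csa: float) -> float:
    """Nominal stress (MPa): force over the initial CSA."""
    if csa <= 0:
        raise ValidationError("CSA must be positive")
    return force / csa


def trim_preconditioning(displacement, force, tol: float = 1e-9):
    """Drop a leading cyclic (pre-conditioning) segment from raw arrays.

    Detects displacement reversals; everything up to and including the
    last reversal is discarded so the remainder is a monotone ramp.
    Returns the (displacement, force) arrays unchanged when no reversal
    is present.
    """
    d = np.asarray(displacement, float).ravel()
    f = np.asarray(force, float).ravel()
    reversals = np.nonzero(np.diff(d) < -tol)[0]
    if len(reversals) == 0:
        return d, f
    start = int(reversals[-1]) + 1
    return d[start:], f[start:]


def preprocess_curve(c: TensileCurve, cfg: PipelineConfig | None = None) -> TensileCurve:
    """Re-origin at the preload and truncate past the failure stop.

    Displacement is zeroed at the first sample whose force reaches
    ``cfg.preload`` (earlier samples are discarded); the curve is cut
    after the last sample before the force first falls below
    ``cfg.failure_stop_fraction`` times the maximum, past the global
    maximum — mimicking a machine's stop criterion.
    """
    cfg = cfg or PipelineConfig()
    above = np.nonzero(c.force >= cfg.preload)[0]
    if len(above) == 0:
        raise InsufficientLoadError(
            f"force never reaches the preload of {cfg.preload} N"
        )
    i0 = int(above[0])
    d = c.displacement[i0:] - c.displacement[i0]
    f = c.force[i0:]
    imax = int(np.argmax(f))
    post = np.nonzero(f[imax + 1:] < cfg.failure_stop_fraction * f[imax])[0]
    if len(post):
        end = imax + 1 + int(post[0])
        d, f = d[:end], f[:end]
    return c.replace(displacement=d, force=f)


@dataclass
class LinearRegion:
    """Best-fitting linear window of the pre-peak curve."""

    strain_lo: float  # %
    strain_hi: float  # %
    slope: float      # N/mm
    intercept: float  # N
    r2: float
    index_lo: int
    index_hi: int

    @property
    def linear_range(self) -> tuple[float, float]:
        return (self.strain_lo, self.strain_hi)


def detect_linear_region(c: TensileCurve, cfg: PipelineConfig | None = None) -> LinearRegion:
    """Find the linear range of a preprocessed curve by window search.

    Scans every contiguous sample window that ends at or before the
    global force maximum and spans at least ``cfg.linear_fit_min_span``
    of the pre-peak strain range, fits force on displacement by OLS and
    keeps the window with the highest r^2 (positive slopes only); exact
    ties go to the widest window, then to the earliest.  If no window
    reaches ``cfg.r2_threshold`` a poor-linearity warning is emitted and
    the best window is returned anyway.
    """
    cfg = cfg or PipelineConfig()
    imax = int(np.argmax(c.force))
    n = imax + 1
    if n < 20:
        raise InsufficientDataError(
            f"need >= 20 samples before the force maximum, got {n}"
        )
    x = c.displacement[:n]
    y = c.force[:n]
    span_min = cfg.linear_fit_min_span * (x[-1] - x[0])
    if span_min <= 0:
        raise InsufficientDataError("pre-peak displacement range is empty")

    # prefix sums for O(1) window statistics
    z = np.zeros(1)
    sx = np.concatenate([z, np.cumsum(x)])
    sy = np.concatenate([z, np.cumsum(y)])
    sxx = np.concatenate([z, np.cumsum(x * x)])
    syy = np.concatenate([z, np.cumsum(y * y)])
    sxy = np.concatenate([z, np.cumsum(x * y)])

    best = None  # (r2, width, -i_lo, i_hi, slope, intercept)
    tol = 1e-9
    for i in range(0, n - 1):
        j0 = int(np.searchsorted(x, x[i] + span_min))
        if j0 >= n:
            break
        j = np.arange(j0, n)
        m = (j - i + 1).astype(float)
        wx = sx[j + 1] - sx[i]
        wy = sy[j + 1] - sy[i]
        wxx = sxx[j + 1] - sxx[i]
        wyy = syy[j + 1] - syy[i]
        wxy = sxy[j + 1] - sxy[i]
        vx = wxx - wx * wx / m
        vy = wyy - wy * wy / m
        cxy = wxy - wx * wy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = cxy / vx
            r2 = np.where(
                (vx > 0) & (vy > 0), np.clip(cxy * cxy / (vx * vy), 0.0, 1.0), -np.inf
            )
        r2 = np.where(slope > 0, r2, -np.inf)
        if not np.isfinite(r2).any():
            continue
        r2max = r2.max()
        # among this row's near-ties, prefer the widest (largest j)
        kk = np.nonzero(r2 >= r2max - tol)[0]
        k = int(kk[-1])
        cand = (float(r2[k]), float(x[j[k]] - x[i]), -i, int(j[k]),
                float(slope[k]), float((wy[k] - slope[k] * wx[k]) / m[k]))
        if best is None:
            best = cand
            continue
        if cand[0] > best[0] + tol:
            best = cand
        elif abs(cand[0] - best[0]) <= tol:
            if cand[1] > best[1] + 1e-12 or (
                abs(cand[1] - best[1]) <= 1e-12 and cand[2] > best[2]
            ):
                best = cand
    if best is None:
        raise InsufficientDataError("no admissible linear-fit window found")
    r2, _width, neg_i, j_hi, slope, intercept = best
    i_lo = -neg_i
    if r2 < cfg.r2_threshold:
        warnings.warn(
            f"poorly linear curve: best window r^2 = {r2:.3f} < {cfg.r2_threshold}",
            stacklevel=2,
        )
    g = c.gauge_length
    return LinearRegion(
        strain_lo=100.0 * x[i_lo] / g,
        strain_hi=100.0 * x[j_hi] / g,
        slope=slope,
        intercept=intercept,
        r2=r2,
        index_lo=i_lo,
        index_hi=j_hi,
    )


def stiffness(c: TensileCurve, cfg: PipelineConfig | None = None) -> float:
    """Slope (N/mm) of the linear region of a preprocessed curve."""
    return detect_linear_region(c, cfg).slope


def detect_peaks(
    c: TensileCurve, drop_fraction: float = 0.05
) -> tuple[float, float, float]:
    """First-peak force, ultimate force and ultimate strain (%).

    The ultimate force is the global maximum; the ultimate strain is the
    grip-to-grip strain at that sample.  The first peak is the earliest
    local maximum that is followed, before the global maximum, by a
    relative force drop of at least *drop_fraction* — the signature of
    the thinner fibres failing first.  Monophasic curves (no such local
    maximum) report the ultimate force as the first peak.
    """
    if len(c.force) < 5:
        raise InsufficientDataError("need at least 5 samples to detect peaks")
    f = c.force
    iu = int(np.argmax(f))
    ultimate = float(f[iu])
    ultimate_strain = float(100.0 * c.displacement[iu] / c.gauge_length)
    first_peak = ultimate
    if iu >= 2:
        seg = f[: iu + 1]
        # running minimum of the forces after each index, up to the maximum
        suffix_min = np.minimum.accumulate(seg[::-1])[::-1]
        for i in range(1, iu):
            if seg[i] >= seg[i - 1] and seg[i] >= seg[i + 1]:
                if suffix_min[i + 1] <= (1.0 - drop_fraction) * seg[i]:
                    first_peak = float(seg[i])
                    break
    return first_peak, ultimate, ultimate_strain


@dataclass
class TensileResult:
    """Derived tensile properties of one specimen's ligament."""

    ligament_id: str
    specimen_id: str
    csa: float | None
    first_peak_force: float
    ultimate_force: float
    stiffness: float
    ultimate_strain: float
    linear_range: tuple[float, float]
    fit_r2: float

    def __post_init__(self) -> None:
        if self.first_peak_force > self.ultimate_force + 1e-9:
            raise ValidationError("first peak force cannot exceed ultimate force")
        if not self.stiffness > 0:
            raise ValidationError("stiffness must be positive")
        lo, hi = self.linear_range
        if not 0 <= lo < hi:
            raise ValidationError("linear range must satisfy 0 <= lo < hi")

    def to_dict(self) -> dict:
        return {
            "ligament_id": self.ligament_id,
            "specimen_id": self.specimen_id,
            "csa": self.csa,
            "first_peak_force": self.first_peak_force,
            "ultimate_force": self.ultimate_force,
            "stiffness": self.stiffness,
            "ultimate_strain": self.ultimate_strain,
            "linear_range": list(self.linear_range),
            "fit_r2": self.fit_r2,
        }


def analyze_curve(
    c: TensileCurve,
    cfg: PipelineConfig | None = None,
    csa: float | None = None,
) -> TensileResult:
    """Preprocess a raw curve and extract every tensile property."""
    cfg = cfg or PipelineConfig()
    pre = preprocess_curve(c, cfg)
    region = detect_linear_region(pre, cfg)
    first_peak, ultimate, ultimate_strain = detect_peaks(
        pre, drop_fraction=cfg.first_peak_drop
    )
    return TensileResult(
        ligament_id=c.ligament_id,
        specimen_id=c.specimen_id,
        csa=csa,
        first_peak_force=first_peak,
        ultimate_force=ultimate,
        stiffness=region.slope,
        ultimate_strain=ultimate_strain,
        linear_range=region.linear_range,
        fit_r2=region.r2,
    )
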