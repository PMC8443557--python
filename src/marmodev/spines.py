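"""Dendritic spine morphometry from intensity profiles.

Spine head diameters are estimated by fitting a 1-D Gaussian (with a
constant background offset) to transverse and axial intensity profiles and
taking 2σ as the diameter.  Spine head volume follows the spheroid closed
form π·d_t²·d_a/6.  Because direct diameter measurement is unreliable for
small spines, a proportional optical-density model volume = c·OD is
calibrated on reference spines (diameter > 0.4 µm and volume < 0.4 µm³) and
used to estimate the remaining volumes.  Spine density is reported per µm
of dendritic segment, and volume distributions are compared with the
two-sample Kolmogorov-Smirnov test (exact p for small samples).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._util import AnalysisError, ConfigurationError, require

__all__ = [
    "SpineProfile",
    "SpineRecord",
    "ODCalibration",
    "fit_profile_diameter",
    "spine_volume",
    "is_reference_spine",
    "calibrate_od",
    "estimate_volume_from_od",
    "spine_density",
    "compare_distributions_ks",
]

logger = logging.getLogger(__name__)

REFERENCE_MIN_DIAMETER_UM = 0.4
REFERENCE_MAX_VOLUME_UM3 = 0.4


@dataclass
class SpineProfile:
    """Intensity line profiles through a spine head along two axes."""

    positions_t_um: np.ndarray
    intensities_t: np.ndarray
    positions_a_um: np.ndarray
    intensities_a: np.ndarray

    def __post_init__(self) -> None:
        for name in ("positions_t_um", "intensities_t",
                     "positions_a_um", "intensities_a"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for pos, inten, ax in ((self.positions_t_um, self.intensities_t, "t"),
                               (self.positions_a_um, self.intensities_a, "a")):
            require(pos.size >= 5, f"positions ({ax})", "need >= 5 samples")
            require(bool(np.all(np.diff(pos) > 0)), f"positions ({ax})",
                    "must be strictly increasing")
            require(pos.size == inten.size, f"intensities ({ax})",
                    "length mismatch with positions")


@dataclass
class SpineRecord:
    d_t_um: float = math.nan
    d_a_um: float = math.nan
    volume_um3: float = math.nan
    optical_density: float = math.nan

    @property
    def is_reference(self) -> bool:
        return is_reference_spine(self.d_t_um, self.d_a_um, self.volume_um3)


@dataclass
class ODCalibration:
    coefficient: float  # µm³ per OD unit
    n_references: int = 0

    def __post_init__(self) -> None:
        require(self.coefficient > 0, "coefficient", "must be positive")


def _gaussian(x, amp, mu, sigma, offset):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2)) + offset


def _fit_axis(x: np.ndarray, y: np.ndarray, axis: str) -> float:
    if np.ptp(y) <= 0:
        raise AnalysisError(f"flat intensity profile on axis {axis!r}; no peak to fit")
    offset0 = float(y.min())
    amp0 = float(y.max() - y.min())
    mu0 = float(x[np.argmax(y)])
    # second-moment width of the background-subtracted profile
    w = np.clip(y - offset0, 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (x - mu0) ** 2) / np.sum(w))) or np.ptp(x) / 4
    span = float(np.ptp(x))
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, x, y, p0=(amp0, mu0, sigma0, offset0),
            bounds=([0, x.min() - span, 1e-6, -np.inf],
                    [np.inf, x.max() + span, 10 * span, np.inf]),
            maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise AnalysisError(f"Gaussian fit failed on axis {axis!r}: {exc}") from exc
    return 2.0 * float(popt[2])  # diameter = 2 sigma


def fit_profile_diameter(profile: SpineProfile) -> tuple[float, float]:
    """Least-squares Gaussian fit per axis; returns (d_t, d_a) = 2σ in µm."""
    d_t = _fit_axis(profile.positions_t_um, profile.intensities_t, "t")
    d_a = _fit_axis(profile.positions_a_um, profile.intensities_a, "a")
    return d_t, d_a


def spine_volume(d_t_um: float, d_a_um: float) -> float:
    """Spheroid volume π·d_t²·d_a/6 from transverse and axial diameters."""
    if not (d_t_um > 0 and d_a_um > 0):
        raise AnalysisError(
            f"diameters must be positive (d_t={d_t_um}, d_a={d_a_um})")
    return math.pi * d_t_um ** 2 * d_a_um / 6.0


def is_reference_spine(d_t_um: float, d_a_um: float, volume_um3: float) -> bool:
    """Reference spines: both diameters > 0.4 µm and volume < 0.4 µm³."""
    return (d_t_um > REFERENCE_MIN_DIAMETER_UM
            and d_a_um > REFERENCE_MIN_DIAMETER_UM
            and volume_um3 < REFERENCE_MAX_VOLUME_UM3)


def _as_record_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([
        {"d_t_um": r.d_t_um, "d_a_um": r.d_a_um,
         "volume_um3": r.volume_um3, "optical_density": r.optical_density}
        for r in records])


def calibrate_od(records, min_references: int = 3) -> ODCalibration:
    """Through-origin least squares volume = c·OD on reference spines.

    Records failing the reference criteria or lacking a positive OD are
    excluded (with a logged count); at least ``min_references`` must remain.
    """
    df = _as_record_frame(records)
    ok = (df.apply(lambda r: is_reference_spine(
            r["d_t_um"], r["d_a_um"], r["volume_um3"]), axis=1)
          & (df["optical_density"] > 0) & (df["volume_um3"] > 0))
    excluded = int((~ok).sum())
    if excluded:
        logger.info("calibrate_od: excluded %d non-reference records", excluded)
    ref = df[ok]
    if len(ref) < min_references:
        raise AnalysisError(
            f"need >= {min_references} reference spines, have {len(ref)}")
    od = ref["optical_density"].to_numpy()
    vol = ref["volume_um3"].to_numpy()
    coeff = float(np.dot(od, vol) / np.dot(od, od))
    return ODCalibration(coefficient=coeff, n_references=len(ref))


def estimate_volume_from_od(od: float, cal: ODCalibration) -> float:
    """Estimated spine volume c·OD (µm³)."""
    if not od > 0:
        raise AnalysisError(f"optical density must be positive, got {od}")
    return cal.coefficient * od


def spine_density(spine_count: int, segment: tuple[float, float]) -> float:
    """Spines per µm over a dendritic segment (start_um, end_um)."""
    start, end = segment
    if not end > start:
        raise AnalysisError(f"segment must have positive length, got {segment}")
    if spine_count < 0:
        raise AnalysisError("spine_count must be non-negative")
    return spine_count / (end - start)


def compare_distributions_ks(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample two-sided KS test (D, p); exact p when min(n) <= 10."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise AnalysisError("both samples must be non-empty")
    method = "exact" if min(a.size, b.size) <= 10 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)
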