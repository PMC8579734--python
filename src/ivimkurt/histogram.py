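"""First-order histogram summarization of a parameter map within an ROI.

Eight features per (ROI, parameter): mean, 10th/25th/50th/75th/90th
percentiles, skewness and kurtosis. Conventions (documented and fixed
package-wide):

* percentiles use linear interpolation at position 1 + q/100·(n−1) on the
  sorted values — the dominant convention in scientific software;
* moments are population (n-denominator) moments; kurtosis is the
  non-excess (Pearson) form m₄/m₂², i.e. 3 for a normal distribution.
  The non-excess choice matches ADC ROI kurtosis values clustering near 3
  on near-Gaussian data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "HistogramSummary",
    "percentile",
    "moment_stats",
    "summarize_roi",
]

FEATURE_NAMES = ("mean", "p10", "p25", "p50", "p75", "p90", "skewness", "kurtosis")


@dataclass(frozen=True)
class HistogramSummary:
    """The eight first-order features of one parameter within one ROI."""

    mean: float
    p10: float
    p25: float
    p50: float
    p75: float
    p90: float
    skewness: float
    kurtosis: float
    n_voxels: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        qs = (self.p10, self.p25, self.p50, self.p75, self.p90)
        if any(not np.isfinite(v) for v in qs):
            raise ValidationError("percentiles must be finite")
        if not all(a <= b + 1e-12 for a, b in zip(qs, qs[1:])):
            raise ValidationError("percentiles must be non-decreasing")

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile of a non-empty list of finite values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("percentile of an empty list is undefined")
    if not np.all(np.isfinite(values)):
        raise ValidationError("values must be finite")
    if not 0.0 <= q <= 100.0:
        raise DomainError(f"percentile rank must lie in [0, 100], got {q}")
    return float(np.percentile(values, q, method="linear"))


def moment_stats(values) -> tuple[float, float]:
    """Population skewness m₃/m₂^1.5 and non-excess kurtosis m₄/m₂².

    Requires at least two distinct values; a constant input has undefined
    standardized moments and raises.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("values must be finite")
    if x.size < 2 or np.ptp(x) == 0:
        raise ValidationError("moments undefined for fewer than 2 distinct values")
    d = x - x.mean()
    m2 = np.mean(d * d)
    if m2 == 0:  # numerically constant (spread below float resolution)
        raise ValidationError("moments undefined: zero variance at float precision")
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    return float(m3 / m2**1.5), float(m4 / (m2 * m2))


def summarize_roi(parameter_map, mask=None, values=None) -> HistogramSummary:
    """Full histogram summary of one parameter over one ROI.

    Either pass a 3-D ``parameter_map`` with a boolean/labelled ``mask`` of
    matching grid, or a flat ``values`` vector. Non-finite entries (excluded
    or failed fits) are dropped and counted in ``n_dropped``. Requires at
    least two distinct remaining values. Order-invariant by construction.
    """
    if values is None:
        arr = np.asarray(parameter_map, dtype=float)
        if mask is None:
            raise ValidationError("a mask is required with a parameter map")
        mask = np.asarray(mask)
        if mask.shape != arr.shape:
            raise ValidationError("mask grid does not match the map grid")
        raw = arr[mask != 0]
    else:
        raw = np.asarray(values, dtype=float).ravel()
    if raw.size == 0:
        raise ValidationError("empty ROI")
    finite = raw[np.isfinite(raw)]
    dropped = raw.size - finite.size
    if finite.size == 0:
        raise ValidationError("all in-ROI voxels are missing")
    if finite.size < 2 or np.ptp(finite) == 0:
        raise ValidationError("ROI needs at least 2 distinct valid values")
    skew, kurt = moment_stats(finite)
    return HistogramSummary(
        mean=float(finite.mean()),
        p10=percentile(finite, 10),
        p25=percentile(finite, 25),
        p50=percentile(finite, 50),
        p75=percentile(finite, 75),
        p90=percentile(finite, 90),
        skewness=skew,
        kurtosis=kurt,
        n_voxels=int(finite.size),
        n_dropped=int(dropped),
    )
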