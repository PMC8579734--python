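"""Closed-form diffusion signal representations.

Two forward models are provided:

* the combined IVIM-kurtosis representation

  .. math::

     S/S_0 = f\\,e^{-b D^*} + (1-f)\\,e^{-b D + (b D)^2 K / 6}

  where :math:`D` is the (slow) tissue diffusion coefficient, :math:`D^*`
  the pseudodiffusion coefficient of the perfusion compartment, :math:`f`
  the perfusion fraction and :math:`K` the kurtosis parameter;

* the monoexponential representation :math:`S(b) = S_0 e^{-b\\,\\mathrm{ADC}}`
  with its exact two-point inverse for a (b_low, b_high) pair.

All diffusion coefficients are carried in mm²/s; report writers scale
D, D* and ADC by 10³ for display (the "×10⁻³ mm²/s" convention).
The kurtosis term is evaluated exactly as written, with no clamping:
parameter bound constraints belong to the fitter, not the forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ValidationError

__all__ = [
    "DiffusionParams",
    "MonoParams",
    "ivim_kurtosis_signal",
    "mem_signal",
    "adc_two_point",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the IVIM-kurtosis model for one voxel.

    Attributes
    ----------
    D : float
        Tissue (virtual) diffusion coefficient, mm²/s. Non-negative.
    Dstar : float
        Pseudodiffusion coefficient, mm²/s. Non-negative.
    f : float
        Perfusion fraction in [0, 1].
    K : float
        Kurtosis parameter, dimensionless, non-negative.
    S0 : float
        Theoretical signal at b = 0 (arbitrary units), positive.
    """

    D: float
    Dstar: float
    f: float
    K: float = 0.0
    S0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("D", "Dstar", "f", "K", "S0"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")
        if self.D < 0:
            raise ValidationError(f"D must be >= 0, got {self.D}")
        if self.Dstar < 0:
            raise ValidationError(f"Dstar must be >= 0, got {self.Dstar}")
        if not 0.0 <= self.f <= 1.0:
            raise ValidationError(f"f must lie in [0, 1], got {self.f}")
        if self.K < 0:
            raise ValidationError(f"K must be >= 0, got {self.K}")
        if self.S0 <= 0:
            raise ValidationError(f"S0 must be > 0, got {self.S0}")

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.Dstar, self.f, self.K], dtype=float)


@dataclass(frozen=True)
class MonoParams:
    """Parameters of the monoexponential model: ADC (mm²/s) and S0 (> 0)."""

    ADC: float
    S0: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.ADC) or self.ADC < 0:
            raise ValidationError(f"ADC must be finite and >= 0, got {self.ADC}")
        if not np.isfinite(self.S0) or self.S0 <= 0:
            raise ValidationError(f"S0 must be > 0, got {self.S0}")


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise DomainError("b-values must be non-negative")
    return b


def ivim_kurtosis_signal(b, params: DiffusionParams) -> np.ndarray | float:
    """Relative signal S/S0 of the IVIM-kurtosis model.

    Parameters
    ----------
    b : float or array-like
        Diffusion weighting(s) in s/mm², non-negative.
    params : DiffusionParams
        Valid model parameters.

    Returns
    -------
    float or ndarray
        f·exp(−b·D*) + (1−f)·exp(−b·D + (b·D)²·K/6), same shape as ``b``.
    """
    b = _check_b(b)
    bD = b * params.D
    perf = params.f * np.exp(-b * params.Dstar)
    tissue = (1.0 - params.f) * np.exp(-bD + bD * bD * params.K / 6.0)
    out = perf + tissue
    return out if out.ndim else float(out)


def mem_signal(b, params: MonoParams) -> np.ndarray | float:
    """Monoexponential signal S(b) = S0·exp(−b·ADC)."""
    b = _check_b(b)
    out = params.S0 * np.exp(-b * params.ADC)
    return out if out.ndim else float(out)


def adc_two_point(s_low, s_high, b_low: float, b_high: float):
    """Closed-form two-point ADC: ln(S_low/S_high) / (b_high − b_low).

    Exact inverse of :func:`mem_signal` on noiseless input. Signals must be
    positive; ``b_high`` must exceed ``b_low``. Accepts arrays.
    """
    if b_high <= b_low:
        raise DomainError(f"b_high ({b_high}) must exceed b_low ({b_low})")
    s_low = np.asarray(s_low, dtype=float)
    s_high = np.asarray(s_high, dtype=float)
    if np.any(s_low <= 0) or np.any(s_high <= 0):
        raise DomainError("signals must be positive for the log-ratio ADC")
    out = np.log(s_low / s_high) / (b_high - b_low)
    return out if out.ndim else float(out)
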