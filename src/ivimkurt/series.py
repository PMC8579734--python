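"""Acquisition scheme and 4-D diffusion-weighted series containers.

The default scheme is the nine-point prostate protocol used throughout the
package: b = 0, 20, 50, 100, 200, 500, 1000, 1500, 2000 s/mm² with
NEX = 2, 2, 2, 2, 2, 3, 4, 6, 6 (number of excitations averaged per b-value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import ConfigurationError, ValidationError

DEFAULT_BVALUES: tuple[float, ...] = (0.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0, 1500.0, 2000.0)
DEFAULT_NEX: tuple[int, ...] = (2, 2, 2, 2, 2, 3, 4, 6, 6)


@dataclass(frozen=True)
class BValueScheme:
    """An ordered multi-b acquisition scheme with per-b-value averaging counts.

    Parameters
    ----------
    bvalues : tuple of float
        Strictly increasing diffusion weightings in s/mm².
    nex : tuple of int
        Number of excitations (signal averages) acquired at each b-value.
    """

    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    nex: tuple[int, ...] = DEFAULT_NEX

    def __post_init__(self) -> None:
        object.__setattr__(self, "bvalues", tuple(float(b) for b in self.bvalues))
        object.__setattr__(self, "nex", tuple(int(n) for n in self.nex))
        if len(self.bvalues) == 0:
            raise ValidationError("scheme needs at least one b-value")
        if len(self.bvalues) != len(self.nex):
            raise ValidationError("bvalues and nex must have the same length")
        if any(b < 0 for b in self.bvalues):
            raise ValidationError("b-values must be non-negative")
        if any(n < 1 for n in self.nex):
            raise ValidationError("NEX entries must be positive integers")
        diffs = np.diff(self.bvalues)
        if len(diffs) and not np.all(diffs > 0):
            raise ValidationError("b-values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def b(self) -> np.ndarray:
        """b-values as a float array (s/mm²)."""
        return np.asarray(self.bvalues, dtype=float)

    @property
    def nex_array(self) -> np.ndarray:
        return np.asarray(self.nex, dtype=int)

    def index_of(self, bvalue: float, atol: float = 1e-6) -> int:
        """Index of a b-value in the scheme; raises if absent."""
        hits = np.nonzero(np.isclose(self.b, bvalue, atol=atol))[0]
        if len(hits) == 0:
            raise ConfigurationError(f"scheme does not contain b={bvalue} s/mm²")
        return int(hits[0])

    def contains(self, bvalue: float) -> bool:
        return bool(np.any(np.isclose(self.b, bvalue, atol=1e-6)))

    def to_table(self, path: str | Path) -> None:
        """Write a two-column plain-text table: b-value and NEX per row."""
        lines = [f"{b:g}\t{n:d}" for b, n in zip(self.bvalues, self.nex)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "BValueScheme":
        bvals, nex = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            bvals.append(float(parts[0]))
            nex.append(int(parts[1]) if len(parts) > 1 else 1)
        return cls(tuple(bvals), tuple(nex))


DEFAULT_SCHEME = BValueScheme()


@dataclass
class DWISeries:
    """A 4-D diffusion-weighted signal array (x, y, z, b-index) with its scheme."""

    data: np.ndarray
    scheme: BValueScheme
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError("DWI series must be 4-D (x, y, z, b)")
        if self.data.shape[3] != len(self.scheme):
            raise ValidationError(
                f"fourth dimension ({self.data.shape[3]}) must match the scheme "
                f"length ({len(self.scheme)})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("DWI series contains non-finite values")
        if np.any(self.data < 0):
            raise ValidationError("DWI series contains negative signals")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def volume(self, bvalue: float) -> np.ndarray:
        """The 3-D volume acquired at one b-value."""
        return self.data[..., self.scheme.index_of(bvalue)]

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data, self.affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, scheme: BValueScheme | str | Path) -> "DWISeries":
        if not isinstance(scheme, BValueScheme):
            scheme = BValueScheme.from_table(scheme)
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), scheme, img.affine)
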