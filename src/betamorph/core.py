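"""Shared containers and errors for the morphometry pipeline.

Coordinates are 0-based ``(row, col)`` pixel indices; areas are reported in
mm^2 and volumes in mm^3 throughout the package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Fallback pixel calibration (mm per pixel) for micrographs that carry no
#: metadata; corresponds to 0.32 um/px, a typical stitched 20x acquisition.
DEFAULT_PIXEL_SIZE_MM = 3.2e-4


class BetamorphError(Exception):
    """Base class for package errors."""


class ConfigurationError(BetamorphError, ValueError):
    """Invalid or inconsistent configuration."""


class ConstantImageError(BetamorphError, ValueError):
    """Raised when automatic thresholding is asked for on a constant image."""


class LedgerError(BetamorphError, ValueError):
    """Raised when a correction ledger contains a malformed edit."""


@dataclass
class Micrograph:
    """One two-channel, 8-bit section image.

    Parameters
    ----------
    nuclear_channel, insulin_channel
        2-D ``uint8`` arrays of identical shape (Hoechst and anti-insulin
        channels of a whole-section acquisition).
    pixel_size_mm
        Side length of one pixel in mm.
    """

    nuclear_channel: np.ndarray
    insulin_channel: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    sample_id: str = ""
    section_index: int = 0

    def __post_init__(self) -> None:
        self.nuclear_channel = np.asarray(self.nuclear_channel, dtype=np.uint8)
        self.insulin_channel = np.asarray(self.insulin_channel, dtype=np.uint8)
        if self.nuclear_channel.ndim != 2:
            raise ConfigurationError("channels must be 2-D")
        if self.nuclear_channel.shape != self.insulin_channel.shape:
            raise ConfigurationError(
                "nuclear and insulin channels must have the same shape, got "
                f"{self.nuclear_channel.shape} vs {self.insulin_channel.shape}"
            )
        if self.pixel_size_mm <= 0:
            raise ConfigurationError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple:
        return self.nuclear_channel.shape


@dataclass
class BinaryMask:
    """A boolean foreground mask with calibration and provenance.

    ``provenance`` records whether the mask comes straight from the automatic
    chain (``"auto"``) or has been through investigator-style remediation
    (``"corrected"``).
    """

    mask: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    provenance: str = "auto"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ConfigurationError("mask must be 2-D")
        if self.pixel_size_mm <= 0:
            raise ConfigurationError("pixel_size_mm must be positive")
        if self.provenance not in ("auto", "corrected"):
            raise ConfigurationError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    @property
    def area_mm2(self) -> float:
        """Total foreground area (exact pixel-count arithmetic)."""
        return float(self.mask.sum()) * self.pixel_size_mm**2

    def copy(self, provenance: Optional[str] = None) -> "BinaryMask":
        return BinaryMask(
            self.mask.copy(),
            self.pixel_size_mm,
            self.provenance if provenance is None else provenance,
        )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between two boolean masks.

    Returns 1.0 when both masks are empty (perfect, if vacuous, agreement).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def sha256_of_array(arr: np.ndarray) -> str:
    """SHA-256 hex digest of an array's raw bytes (shape/dtype tagged)."""
    h = hashlib.sha256()
    h.update(str(arr.dtype).encode())
    h.update(str(arr.shape).encode())
    h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()
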