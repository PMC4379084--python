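"""Mean seasonal NDVI profiles and their temporal Fourier decomposition.

A multi-year stack of seasonal NDVI composites is first averaged year-wise
into one mean seasonal profile per pixel.  Temporal Fourier analysis then
summarises each profile by the additive term A0 (the series mean, a proxy for
seasonal net primary productivity) and the amplitudes A1 and A2 of the first
two harmonics (1 and 2 cycles per season, proxies for vegetation
seasonality).  Phases are discarded: only the amplitude spectrum is carried
forward into segmentation and clustering.

Amplitude normalisation is fixed so that a unit-amplitude cosine at the first
harmonic frequency yields A1 = 1 (coefficients 2/N; additive term 1/N).  Any
fixed affine rescaling of the amplitudes would leave segmentation and
clustering topology unchanged; only the numeric meaning of the segmentation
scale parameter shifts with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .raster import GridTransform, Raster

__all__ = [
    "NDVIStack",
    "MeanProfileImage",
    "FourierImage",
    "mean_seasonal_profile",
    "tfa_vector",
    "tfa_image",
    "DEFAULT_COMPOSITE_DAYS",
]

# Default seasonal window: 11 16-day composites from Julian day 113 (late
# April) to 273 (early October), the high-fire-occurrence season.
DEFAULT_COMPOSITE_DAYS: tuple[int, ...] = tuple(range(113, 274, 16))
TIME_LAG_DAYS = 16


@dataclass
class NDVIStack:
    """Multi-year seasonal NDVI series with georeferencing.

    ``values`` has shape (n_years, n_composites, n_rows, n_cols); ``mask``
    marks valid observations (same shape).
    """

    values: np.ndarray
    transform: GridTransform
    crs: str = ""
    years: list[int] = field(default_factory=list)
    composite_days: tuple[int, ...] = DEFAULT_COMPOSITE_DAYS
    time_lag: int = TIME_LAG_DAYS
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.values.ndim != 4:
            raise ValueError("NDVIStack values must be (year, composite, row, col)")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def n_composites(self) -> int:
        return self.values.shape[1]


@dataclass
class MeanProfileImage:
    """Per-pixel mean seasonal profile, shape (n_composites, n_rows, n_cols)."""

    values: np.ndarray
    valid_mask: np.ndarray
    transform: GridTransform
    crs: str = ""


@dataclass
class FourierImage:
    """Per-pixel Fourier summary of the mean seasonal profile."""

    A0: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    valid_mask: np.ndarray
    transform: GridTransform
    crs: str = ""

    def bands(self) -> np.ndarray:
        """(3, rows, cols) array in band order A0, A1, A2."""
        return np.stack([self.A0, self.A1, self.A2])

    def to_raster(self, nodata: float = -9999.0) -> Raster:
        out = self.bands().astype(np.float32).copy()
        out[:, ~self.valid_mask] = nodata
        return Raster(values=out, transform=self.transform, crs=self.crs, nodata=nodata)

    @classmethod
    def from_raster(cls, raster: Raster) -> "FourierImage":
        if raster.values.ndim != 3 or raster.values.shape[0] != 3:
            raise ValueError("Fourier raster must have 3 bands (A0, A1, A2)")
        mask = raster.mask()
        a0, a1, a2 = (np.asarray(b, dtype=float) for b in raster.values)
        return cls(A0=a0, A1=a1, A2=a2, valid_mask=mask,
                   transform=raster.transform, crs=raster.crs)


def mean_seasonal_profile(stack: NDVIStack, min_years_valid: int | None = None
                          ) -> MeanProfileImage:
    """Average the stack over years into one seasonal profile per pixel.

    A pixel is kept only if every composite index has at least
    ``min_years_valid`` unmasked years (default: ceil(n_years / 2)).
    """
    if stack.values.size == 0:
        raise ValueError("empty NDVI stack")
    if min_years_valid is None:
        min_years_valid = math.ceil(stack.n_years / 2)

    m = stack.mask
    counts = m.sum(axis=0)                                   # (composite, r, c)
    sums = np.where(m, stack.values, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    valid = (counts >= min_years_valid).all(axis=0)
    if not valid.any():
        raise ValueError(
            "no pixel has enough valid observations at every composite; "
            "inspect the stack's nodata masks or lower min_years_valid"
        )
    means[:, ~valid] = np.nan
    return MeanProfileImage(values=means, valid_mask=valid,
                            transform=stack.transform, crs=stack.crs)


def tfa_vector(profile: np.ndarray) -> tuple[float, float, float]:
    """Additive term and first two harmonic amplitudes of one profile.

    With t = 0..N-1: A0 = mean, a_k = (2/N) Σ x_t cos(2πkt/N),
    b_k = (2/N) Σ x_t sin(2πkt/N), A_k = sqrt(a_k² + b_k²) for k = 1, 2.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1:
        raise ValueError("profile must be 1-D")
    n = x.size
    if n < 5:
        raise ValueError("profile needs at least 5 samples to resolve two harmonics")
    if not np.isfinite(x).all():
        raise ValueError("profile contains missing values; resolve masks upstream")
    spec = np.fft.rfft(x)
    a0 = spec[0].real / n
    a1, a2 = 2.0 * np.abs(spec[1:3]) / n
    return float(a0), float(a1), float(a2)


def tfa_image(profiles: MeanProfileImage) -> FourierImage:
    """Apply the Fourier decomposition to every valid pixel of an image."""
    if not profiles.valid_mask.any():
        raise ValueError("no valid pixels in mean profile image")
    vals = np.where(np.isfinite(profiles.values), profiles.values, 0.0)
    n = vals.shape[0]
    spec = np.fft.rfft(vals, axis=0)
    a0 = spec[0].real / n
    amps = 2.0 * np.abs(spec[1:3]) / n
    bad = ~profiles.valid_mask
    for band in (a0, amps[0], amps[1]):
        band[bad] = np.nan
    return FourierImage(A0=a0, A1=amps[0], A2=amps[1],
                        valid_mask=profiles.valid_mask.copy(),
                        transform=profiles.transform, crs=profiles.crs)
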