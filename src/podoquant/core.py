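"""Shared in-memory containers for image data and derived measurements.

All images are 2D, stored channel-first as ``(C, H, W)``. Physical scale is
carried as pixels per micron on the stack itself; every length/area produced
downstream is derived from that single number. Coordinates are 0-based
``(row, col)``; label masks are integer images with 0 = background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageStack",
    "LabelMask",
    "GroundTruth",
    "SlitMorphometry",
    "ResolutionEstimate",
    "ConcordanceResult",
    "RoiMeasurement",
    "LarvaMeasurement",
]


@dataclass
class ImageStack:
    """A multi-channel 2D image with named channels and a physical pixel size.

    Parameters
    ----------
    data:
        Array of shape ``(C, H, W)``; any integer or float dtype.
    channel_names:
        One name per channel, unique.
    pixels_per_micron:
        Lateral sampling density; must be positive.
    """

    data: np.ndarray
    channel_names: list[str]
    pixels_per_micron: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3:
            raise ValueError(f"expected (C, H, W) data, got shape {self.data.shape}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.pixels_per_micron > 0:
            raise ValueError("pixels_per_micron must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(H, W)``."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the 2D array of the named channel (a view, not a copy)."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]


@dataclass
class LabelMask:
    """Integer-labeled ROI image; 0 is background, ROIs are 1..K."""

    labels: np.ndarray
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must have an integer dtype")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_labels(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))


@dataclass
class GroundTruth:
    """Known truth attached to a synthetic phantom; fields populated per kind."""

    label_mask: LabelMask | None = None
    vessel_mask: np.ndarray | None = None
    slit_mask: np.ndarray | None = None
    true_roi_means: dict[int, float] = field(default_factory=dict)
    true_slit_length_um: float | None = None
    true_capillary_area_um2: float | None = None
    true_plasma_level: float | None = None


@dataclass
class SlitMorphometry:
    """Filtration-slit morphometry of one image/marker.

    ``fsd_per_um`` is total slit length per capillary area (µm/µm² ≡ µm⁻¹),
    and equals ``total_slit_length_um / capillary_area_um2`` exactly.
    """

    marker: str
    total_slit_length_um: float
    capillary_area_um2: float
    fsd_per_um: float

    def __post_init__(self) -> None:
        if self.total_slit_length_um < 0:
            raise ValueError("slit length must be >= 0")
        if not self.capillary_area_um2 > 0:
            raise ValueError("capillary area must be > 0")


@dataclass
class ResolutionEstimate:
    """FWHM-based resolution over one or more line profiles, in nm."""

    fwhm_nm: float
    n_profiles: int = 1
    sd_nm: float = 0.0


@dataclass
class ConcordanceResult:
    """Paired per-image FSD values for two markers and their correlation."""

    pairs: list[tuple[float, float]]
    pearson_r: float
    p_value: float


@dataclass
class RoiMeasurement:
    """Per-ROI area and mean fluorescence intensity over all channels."""

    label: int
    area_um2: float
    mfi: dict[str, float]
    subject_id: str
    group: str


@dataclass
class LarvaMeasurement:
    """Per-larva mean vascular fluorescence; ratio filled by cohort normalization."""

    larva_id: str
    group: str
    mean_vascular_fluorescence: float
    ratio: float | None = None
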