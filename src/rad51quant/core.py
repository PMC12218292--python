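"""Core image containers shared by the simulation and analysis stages.

A nucleus crop is a small 3D fluorescence stack (z, y, x) with physical
calibration.  Two channels may be carried: the raw photon-count channel, on
which all intensity quantification is done, and an optional "denoised"
channel (e.g. a deconvolved rendition) used for segmentation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack3D"]


@dataclass
class ImageStack3D:
    """A 3D fluorescence image stack of one cropped nucleus.

    Parameters
    ----------
    data : ndarray, shape (n_z, n_y, n_x)
        Raw voxel intensities in photon (gray-level) units.
    pixel_nm : float
        Lateral pixel size in nanometres (camera pixel / magnification).
    z_step_nm : float
        Axial step between consecutive slices in nanometres.
    denoised : ndarray or None
        Optional denoised/deconvolved channel with the same shape as
        ``data``; segmentation prefers this channel when present.
    """

    data: np.ndarray
    pixel_nm: float
    z_step_nm: float
    denoised: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one z-slice")
        if self.pixel_nm <= 0 or self.z_step_nm <= 0:
            raise ValueError("physical calibration must be positive")
        if self.denoised is not None:
            self.denoised = np.asarray(self.denoised, dtype=float)
            if self.denoised.shape != self.data.shape:
                raise ValueError("denoised channel must match the raw shape")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def segmentation_channel(self) -> np.ndarray:
        """Channel used for segmentation: denoised if present, else raw."""
        return self.denoised if self.denoised is not None else self.data

    def sum_projection(self) -> np.ndarray:
        """Sum over z of the raw channel.

        The sum projection is the linear projection: it preserves the total
        photon count per (y, x) column and is therefore the image on which
        unbiased integrated intensities are measured.
        """
        return self.data.sum(axis=0)
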