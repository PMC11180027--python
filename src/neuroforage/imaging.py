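"""Masked immunofluorescence quantification.

Re-implements the confocal quantification macro: each channel of a
multi-channel z-stack is flattened by maximum projection and
background-subtracted (rolling ball); the cell-marker channel (NeuN, IBA1
or GFAP) is auto-thresholded with the iterative-intermeans ("Default")
method to build a compartment mask, optionally intersected with a DAPI
mask to restrict to nuclei; and the median intensity of the target channel
is measured over the mask. Bilateral comparisons are expressed as the
contralateral median as a percentage of the ipsilateral median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import tifffile
import yaml
from skimage.restoration import rolling_ball

__all__ = [
    "ImageStack",
    "ROIRecord",
    "BinaryMask",
    "ROIQuantResult",
    "EmptyMaskWarning",
    "max_project",
    "subtract_background",
    "auto_threshold_default",
    "combine_masks_and",
    "median_on_mask",
    "bilateral_ratio",
    "quantify_compartment",
    "read_stack",
    "write_stack",
]

ROLES = ("NeuN", "IBA1", "GFAP", "DAPI", "target")


class EmptyMaskWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ROIRecord:
    region: str = ""
    side: str = ""  # "ipsilateral" | "contralateral" relative to injury


@dataclass(frozen=True)
class ImageStack:
    """``(z, channel, h, w)`` intensities with channel-role annotations."""

    planes: np.ndarray
    channel_roles: dict[int, str]
    roi: ROIRecord = ROIRecord()

    def __post_init__(self) -> None:
        if self.planes.ndim != 4:
            raise ValueError("planes must be (z, channel, h, w)")
        n_ch = self.planes.shape[1]
        if not set(self.channel_roles) <= set(range(n_ch)):
            raise ValueError("channel_roles keys must index channels")
        roles = list(self.channel_roles.values())
        if roles.count("target") != 1:
            raise ValueError("exactly one target channel per quantification")

    def channel(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return idx
        raise KeyError(f"no channel with role {role!r}")


@dataclass(frozen=True)
class BinaryMask:
    pixels: np.ndarray
    source: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.pixels.dtype != bool or self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D boolean")


@dataclass(frozen=True)
class ROIQuantResult:
    roi: ROIRecord
    target_role: str
    compartment: str
    median: float | None   # arbitrary units; None when the mask is empty
    mask_px: int

    @property
    def defined(self) -> bool:
        return self.median is not None


def max_project(stack: ImageStack, role: str) -> np.ndarray:
    """Pixelwise maximum over z for one channel."""
    return np.asarray(stack.planes[:, stack.channel(role)]).max(axis=0)


def subtract_background(plane: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Rolling-ball background subtraction; output clipped at zero.

    A flat image maps to zero everywhere; isolated bright features smaller
    than the ball are preserved. In the large-radius limit this approaches
    subtracting the image minimum.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if radius >= max(plane.shape):
        raise ValueError(f"radius {radius} >= image extent {plane.shape}")
    background = rolling_ball(plane.astype(float), radius=radius)
    return np.clip(plane - background, 0, None)


def auto_threshold_default(plane: np.ndarray, n_bins: int = 256,
                           max_iter: int = 500) -> BinaryMask:
    """Iterative-intermeans (IsoData variant) auto-threshold.

    The threshold iterates ``t <- (mean(values <= t) + mean(values > t)) / 2``
    on a 256-bin histogram over the observed range until it stabilises;
    pixels strictly above the converged threshold are foreground. The rule
    is equivariant under affine intensity maps with positive slope. A
    constant plane has no threshold: an empty mask is returned with a
    warning.
    """
    plane = np.asarray(plane, dtype=float)
    lo, hi = float(plane.min()), float(plane.max())
    if hi <= lo:
        warnings.warn("constant plane: threshold undefined, mask empty",
                      EmptyMaskWarning, stacklevel=2)
        return BinaryMask(np.zeros(plane.shape, dtype=bool),
                          source="auto_threshold_default", threshold=None)
    counts, edges = np.histogram(plane, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    t = (lo + hi) / 2.0
    for _ in range(max_iter):
        below = centers <= t
        w_lo, w_hi = counts[below].sum(), counts[~below].sum()
        if w_lo == 0 or w_hi == 0:
            # walk toward the populated side until both classes are non-empty
            t = centers[counts > 0].mean()
            continue
        mu_lo = (counts[below] * centers[below]).sum() / w_lo
        mu_hi = (counts[~below] * centers[~below]).sum() / w_hi
        t_new = (mu_lo + mu_hi) / 2.0
        if abs(t_new - t) < (edges[1] - edges[0]) / 2:
            t = t_new
            break
        t = t_new
    return BinaryMask(plane > t, source="auto_threshold_default", threshold=float(t))


def combine_masks_and(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Pixelwise conjunction of two masks of identical geometry."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("mask geometries differ")
    return BinaryMask(a.pixels & b.pixels,
                      source=f"({a.source}) AND ({b.source})")


def median_on_mask(target: np.ndarray, mask: BinaryMask,
                   roi: ROIRecord = ROIRecord(), target_role: str = "target",
                   compartment: str = "") -> ROIQuantResult:
    """Median of the target channel over mask-true pixels.

    An even pixel count takes the mean of the central pair. Changing pixels
    outside the mask can never change the result. An empty mask yields an
    undefined (flagged) result, mirroring manual QC exclusion.
    """
    if target.shape != mask.pixels.shape:
        raise ValueError("target and mask geometries differ")
    n = int(mask.pixels.sum())
    if n == 0:
        warnings.warn("empty mask: median undefined", EmptyMaskWarning,
                      stacklevel=2)
        return ROIQuantResult(roi=roi, target_role=target_role,
                              compartment=compartment, median=None, mask_px=0)
    return ROIQuantResult(roi=roi, target_role=target_role,
                          compartment=compartment,
                          median=float(np.median(target[mask.pixels])),
                          mask_px=n)


def bilateral_ratio(contra: ROIQuantResult, ipsi: ROIQuantResult) -> float:
    """Contralateral median as a percentage of the ipsilateral median."""
    if contra.roi.region != ipsi.roi.region or contra.compartment != ipsi.compartment:
        raise ValueError("bilateral ratio requires matching region and compartment")
    if not (contra.defined and ipsi.defined):
        raise ValueError("bilateral ratio undefined for empty masks")
    if ipsi.median <= 0:
        raise ValueError("ipsilateral median must be > 0")
    return 100.0 * contra.median / ipsi.median


def quantify_compartment(
    stack: ImageStack,
    mask_role: str,
    background_radius: float | None = 50.0,
    and_dapi: bool = False,
) -> ROIQuantResult:
    """Run the full macro for one compartment of one stack.

    Projection → (optional) background subtraction per channel → 'Default'
    threshold of the mask channel → optional AND with a DAPI mask → median
    target intensity on the mask.
    """
    def prepared(role: str) -> np.ndarray:
        plane = max_project(stack, role)
        if background_radius is not None and plane.max() > plane.min():
            plane = subtract_background(plane, background_radius)
        return plane

    mask = auto_threshold_default(prepared(mask_role))
    compartment = mask_role
    if and_dapi:
        mask = combine_masks_and(mask, auto_threshold_default(prepared("DAPI")))
        compartment = f"{mask_role}∩DAPI"
    return median_on_mask(prepared("target"), mask, roi=stack.roi,
                          compartment=compartment)


# ---------------------------------------------------------------------------
# TIFF + YAML-sidecar IO

def write_stack(stack: ImageStack, tiff_path, roles_path) -> None:
    z, c, h, w = stack.planes.shape
    tifffile.imwrite(tiff_path, stack.planes.astype(np.float32),
                     photometric="minisblack", metadata={"axes": "ZCYX"})
    with open(roles_path, "w") as fh:
        yaml.safe_dump({"channel_roles": {int(k): v for k, v in
                                          stack.channel_roles.items()},
                        "roi": {"region": stack.roi.region,
                                "side": stack.roi.side}}, fh)


def read_stack(tiff_path, roles_path) -> ImageStack:
    planes = np.asarray(tifffile.imread(tiff_path))
    if planes.ndim == 3:  # single channel
        planes = planes[:, None]
    with open(roles_path) as fh:
        meta = yaml.safe_load(fh)
    roi = ROIRecord(**meta.get("roi", {}))
    roles = {int(k): str(v) for k, v in meta["channel_roles"].items()}
    return ImageStack(planes=planes, channel_roles=roles, roi=roi)
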