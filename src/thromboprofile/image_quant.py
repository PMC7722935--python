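"""Surface-area-coverage (%SAC) quantification of microscopy frames.

This module reproduces a microfluidic thrombus-formation image pipeline as
commonly scripted in Fiji/ImageJ for flow-chamber assays:

1. background-illumination correction with an FFT bandpass filter,
2. a threshold (Otsu, with an additive manual-adjustment offset),
3. for brightfield frames only, a chain of binary morphology steps
   (diamond close -> disk close -> small disk dilate) that repairs
   stripe artifacts and fragmented aggregate outlines,
4. the surface-area-coverage measurement itself: the percentage of the
   frame covered by segmented foreground.

Frames are single-channel 8-bit images (brightfield or GFP/RFP/Cy5
fluorescence).  All processing parameters are recorded in the mask
provenance so that every %SAC value can be traced to the settings that
produced it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import diamond, disk

CHANNELS = ("brightfield", "GFP", "RFP", "Cy5")

__all__ = [
    "CHANNELS",
    "ImageFrame",
    "BandpassSpec",
    "MorphologySpec",
    "BinaryMask",
    "SacValue",
    "fft_bandpass",
    "threshold_mask",
    "gray_morphology_chain",
    "compute_sac",
    "quantify_frame",
    "average_run",
]


@dataclass
class ImageFrame:
    """One single-channel microscopy frame with 8-bit intensity range.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities in ``[0, 255]``.  Integer or float dtype;
        filtered intermediates are kept as floats to avoid quantization
        of small residuals.
    channel : str
        One of ``brightfield``, ``GFP``, ``RFP``, ``Cy5``.
    pixel_size_um : float, optional
        Physical pixel size (metadata only; never used in computation).
    frame_id : str, optional
        Identifier carried through to the %SAC table.
    """

    pixels: np.ndarray
    channel: str = "brightfield"
    pixel_size_um: float | None = None
    frame_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("frame pixels must be a nonempty 2-D array")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities must lie in [0, 255], got [{lo}, {hi}]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BandpassSpec:
    """Cutoffs (in pixels) for the FFT bandpass background correction.

    ``large_cutoff_px`` sets the scale above which structures are treated
    as background illumination and suppressed; typical per-channel values
    lie in 60-200 px.  ``small_cutoff_px`` optionally low-pass filters
    sub-cutoff detail; by default small structures are left untouched
    because they carry the platelet detail of interest.
    """

    large_cutoff_px: float = 120.0
    small_cutoff_px: float | None = None

    def __post_init__(self) -> None:
        if self.large_cutoff_px <= 0:
            raise ValueError("large_cutoff_px must be positive")
        if self.small_cutoff_px is not None:
            if self.small_cutoff_px <= 0:
                raise ValueError("small_cutoff_px must be positive")
            if not self.small_cutoff_px < self.large_cutoff_px:
                raise ValueError("small_cutoff_px must be smaller than large_cutoff_px")


@dataclass(frozen=True)
class MorphologySpec:
    """Structuring-element radii for the brightfield morphology chain.

    The chain is a large diamond close, a medium disk close, then a small
    disk dilate; the final dilate is the user-adjustable step used to match
    detected area to the visible aggregate outline.
    """

    diamond_close_radius: int = 5
    disk_close_radius: int = 3
    disk_dilate_radius: int = 1

    def __post_init__(self) -> None:
        if not (self.diamond_close_radius > self.disk_close_radius > self.disk_dilate_radius >= 1):
            raise ValueError(
                "radii must satisfy diamond_close > disk_close > disk_dilate >= 1, "
                f"got {self.diamond_close_radius} / {self.disk_close_radius} / "
                f"{self.disk_dilate_radius}"
            )


@dataclass
class BinaryMask:
    """A segmentation mask plus the parameters that produced it."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("mask must be a nonempty 2-D boolean array")

    @property
    def coverage_percent(self) -> float:
        return 100.0 * float(np.count_nonzero(self.pixels)) / self.pixels.size


@dataclass(frozen=True)
class SacValue:
    """Surface area coverage of one frame, in percent of frame area."""

    value: float
    channel: str | None = None
    frame_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ValueError(f"%SAC must lie in [0, 100], got {self.value}")


def _bandpass_gain(shape: tuple[int, int], spec: BandpassSpec) -> np.ndarray:
    """Frequency-domain gain of the bandpass filter.

    The gain is expressed in spatial frequency magnitude k (cycles/px).
    A Gaussian high-pass ``1 - exp(-ln2 (k L)^2)`` attenuates a sinusoid
    of wavelength equal to the large cutoff L by exactly 50% in power
    terms; much larger structures (k L << 1) are removed almost entirely
    while structures a few times smaller than L pass essentially intact.
    The optional small cutoff multiplies in a matching Gaussian low-pass.
    """
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    k2 = fy * fy + fx * fx
    gain = 1.0 - np.exp(-np.log(2.0) * k2 * spec.large_cutoff_px**2)
    if spec.small_cutoff_px is not None:
        gain = gain * np.exp(-np.log(2.0) * k2 * spec.small_cutoff_px**2)
    return gain


def fft_bandpass(frame: ImageFrame, spec: BandpassSpec | None = None) -> ImageFrame:
    """Correct background illumination with an FFT bandpass filter.

    Structures larger than ``spec.large_cutoff_px`` (smooth illumination
    gradients, vignetting) are suppressed while smaller structures are
    preserved.  The frame mean is retained so a flat frame passes through
    unchanged, and the output is clipped back to the 8-bit range.

    Filtering is a pointwise multiplication in the frequency domain and is
    therefore equivariant under cyclic shifts of the input.

    Raises
    ------
    ValueError
        If a cutoff is not smaller than the frame's shorter side.
    """
    spec = spec or BandpassSpec()
    short_side = min(frame.height, frame.width)
    if spec.large_cutoff_px >= short_side:
        raise ValueError(
            f"large_cutoff_px={spec.large_cutoff_px} must be smaller than the "
            f"frame's shorter side ({short_side} px)"
        )
    img = frame.pixels.astype(np.float64)
    mean = img.mean()
    gain = _bandpass_gain(img.shape, spec)
    filtered = np.fft.ifft2(np.fft.fft2(img - mean) * gain).real + mean
    filtered = np.clip(filtered, 0.0, 255.0)
    return ImageFrame(filtered, channel=frame.channel,
                      pixel_size_um=frame.pixel_size_um, frame_id=frame.frame_id)


def threshold_mask(
    frame: ImageFrame,
    method: str = "otsu",
    manual_offset: float = 0.0,
    dark_objects: bool | None = None,
    fixed_threshold: float | None = None,
) -> BinaryMask:
    """Segment a background-corrected frame into foreground/background.

    Pixels strictly above ``threshold + manual_offset`` become foreground.
    Brightfield frames image platelet aggregates as phase-dense (dark)
    objects, so by default they are inverted before thresholding;
    fluorescence frames are bright-on-dark and are not.  ``manual_offset``
    is the programmatic stand-in for interactive threshold adjustment.

    A flat frame has no Otsu threshold; the returned mask is then empty
    and flagged ``degenerate`` in its provenance (a warning is emitted).
    """
    if not np.isfinite(manual_offset):
        raise ValueError("manual_offset must be finite")
    if method not in ("otsu", "fixed"):
        raise ValueError(f"unknown threshold method {method!r}")
    if dark_objects is None:
        dark_objects = frame.channel == "brightfield"

    img = frame.pixels.astype(np.float64)
    if dark_objects:
        img = 255.0 - img

    provenance: dict = {
        "channel": frame.channel,
        "frame_id": frame.frame_id,
        "method": method,
        "manual_offset": float(manual_offset),
        "inverted": bool(dark_objects),
        "degenerate": False,
    }

    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold is required with method='fixed'")
        threshold = float(fixed_threshold)
    else:
        if img.min() == img.max():
            warnings.warn("flat frame: Otsu threshold undefined, returning empty mask",
                          stacklevel=2)
            provenance.update(threshold=None, degenerate=True)
            return BinaryMask(np.zeros(img.shape, dtype=bool), provenance)
        threshold = float(threshold_otsu(img))

    provenance["threshold"] = threshold
    return BinaryMask(img > threshold + manual_offset, provenance)


def _pad_close(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Binary closing with explicit background padding.

    Padding by the footprint radius makes the result identical to closing
    on an infinite background plane, which guarantees extensivity
    (output contains input) and avoids spurious coverage at the border.
    """
    pad = max(footprint.shape) // 2 + 1
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=footprint),
        structure=footprint, border_value=0,
    )
    return closed[pad:-pad, pad:-pad]


def gray_morphology_chain(mask: BinaryMask, spec: MorphologySpec | None = None) -> BinaryMask:
    """Apply the brightfield detection-repair morphology chain.

    In order: closing with a large diamond (bridges stripe gaps, rewarding
    regions with many neighboring foreground pixels), closing with a
    medium disk (rounds shapes and suppresses straight-line artifacts),
    and dilation with a small disk (the user-matched final growth step).
    Each step is extensive on binary masks, so coverage never decreases.

    Raises
    ------
    ValueError
        If a structuring element does not fit inside the image.
    """
    spec = spec or MorphologySpec()
    h, w = mask.pixels.shape
    largest = 2 * spec.diamond_close_radius + 1
    if largest > min(h, w):
        raise ValueError(
            f"structuring element ({largest} px) larger than image ({h}x{w})"
        )
    out = _pad_close(mask.pixels, diamond(spec.diamond_close_radius))
    out = _pad_close(out, disk(spec.disk_close_radius))
    out = ndimage.binary_dilation(out, structure=disk(spec.disk_dilate_radius))
    provenance = dict(mask.provenance)
    provenance["morphology"] = {
        "diamond_close_radius": spec.diamond_close_radius,
        "disk_close_radius": spec.disk_close_radius,
        "disk_dilate_radius": spec.disk_dilate_radius,
    }
    return BinaryMask(out, provenance)


def compute_sac(mask: BinaryMask) -> SacValue:
    """Surface area coverage: percent of the frame that is foreground."""
    return SacValue(
        value=100.0 * float(np.count_nonzero(mask.pixels)) / mask.pixels.size,
        channel=mask.provenance.get("channel"),
        frame_id=mask.provenance.get("frame_id"),
    )


def quantify_frame(
    frame: ImageFrame,
    bandpass: BandpassSpec | None = None,
    morphology: MorphologySpec | None = None,
    threshold_method: str = "otsu",
    manual_offset: float = 0.0,
    dark_objects: bool | None = None,
    apply_morphology: bool | None = None,
    return_mask: bool = False,
):
    """Run the full per-frame pipeline and return the %SAC value.

    Brightfield path: bandpass -> threshold -> morphology chain -> %SAC.
    Fluorescence path: bandpass -> threshold -> %SAC (no morphology).
    ``apply_morphology`` overrides the channel-based default, which is
    useful for ablation comparisons on striped fixtures.
    """
    corrected = fft_bandpass(frame, bandpass)
    mask = threshold_mask(corrected, method=threshold_method,
                          manual_offset=manual_offset, dark_objects=dark_objects)
    if apply_morphology is None:
        apply_morphology = frame.channel == "brightfield"
    if apply_morphology:
        mask = gray_morphology_chain(mask, morphology)
    sac = compute_sac(mask)
    if return_mask:
        return sac, mask
    return sac


def average_run(values: Sequence[SacValue | float]) -> float:
    """Average per-image values into one value per parameter per microspot.

    Raises
    ------
    ValueError
        On an empty list, or when SacValue inputs mix channels.
    """
    if len(values) == 0:
        raise ValueError("cannot average an empty list of values")
    numeric = []
    channels = set()
    for v in values:
        if isinstance(v, SacValue):
            numeric.append(v.value)
            channels.add(v.channel)
        else:
            numeric.append(float(v))
    if len(channels) > 1:
        raise ValueError(f"values from mixed channels: {sorted(map(str, channels))}")
    return float(np.mean(numeric))
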