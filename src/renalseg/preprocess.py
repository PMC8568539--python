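"""CT input handling: HU conversion, windowing, resizing, flip doubling.

Windowing clips HU to [center - width/2, center + width/2] and maps that
range linearly onto [0, 1]; this mapping *is* the normalisation, no
per-image statistics are used. Images are resampled bilinearly, masks with
nearest-neighbour so they stay binary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from . import dicomio

__all__ = [
    "CTSlice",
    "WindowSetting",
    "TrainingSample",
    "read_dicom_series",
    "read_nifti_pair",
    "read_png_pairs",
    "window_and_normalize",
    "resize_pair",
    "flip_double",
    "prepare_training_samples",
]

PNG_HU_OFFSET = 1024  # uint16 PNG stores HU + offset


@dataclass
class CTSlice:
    """One 2-D CT slice in Hounsfield units with geometry metadata."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    slice_thickness_mm: float | None = None
    z_position_mm: float | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError(f"{self.source_id or 'slice'}: non-finite HU values")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be strictly positive")


@dataclass(frozen=True)
class WindowSetting:
    """Display window: width and centre (level) in HU."""

    width_hu: float = 420.0
    center_hu: float = 60.0

    def __post_init__(self):
        if self.width_hu <= 0:
            raise ValueError("window width must be positive")

    @property
    def bounds(self) -> tuple[float, float]:
        half = self.width_hu / 2.0
        return self.center_hu - half, self.center_hu + half


@dataclass
class TrainingSample:
    """Windowed image in [0, 1] paired with a binary mask."""

    image: np.ndarray
    mask: np.ndarray
    flipped: bool = False
    source_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0, 1]")


def read_dicom_series(path) -> list[CTSlice]:
    """Read a directory of single-frame CT DICOM files as one z-sorted series.

    Stored values are converted to HU via the per-file rescale slope and
    intercept. Files must belong to a single series (same SeriesInstanceUID,
    shape and pixel spacing); a mixed directory is rejected.
    """
    slices = []
    meta = None
    for filename in dicomio.list_series_files(path):
        attrs = dicomio.read_dicom_file(filename)
        spacing = attrs.get("PixelSpacing", [1.0, 1.0])
        if np.isscalar(spacing):
            spacing = [spacing, spacing]
        key = (attrs.get("SeriesInstanceUID"), attrs["Rows"], attrs["Columns"],
               tuple(spacing))
        if meta is None:
            meta = key
        elif key != meta:
            raise dicomio.DicomError(
                f"{path}: mixed series (differing UID, shape or spacing)")
        hu = attrs["pixels"].astype(np.float64) * attrs["RescaleSlope"] \
            + attrs["RescaleIntercept"]
        slices.append(CTSlice(
            pixels=hu,
            pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
            slice_thickness_mm=attrs.get("SliceThickness"),
            z_position_mm=attrs.get("SliceLocation"),
            source_id=os.path.basename(filename),
        ))
    slices.sort(key=lambda s: (s.z_position_mm is None, s.z_position_mm))
    return slices


def read_nifti_pair(image_path, mask_path=None):
    """Read a NIfTI volume (and optional mask) into lists of CTSlice/masks."""
    import nibabel as nib

    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 2:
        data = data[..., None]
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    dz = float(zooms[2]) if len(zooms) > 2 else 1.0
    slices = [CTSlice(pixels=data[..., k], pixel_spacing_mm=spacing,
                      slice_thickness_mm=dz, z_position_mm=k * dz,
                      source_id=f"{image_path}[{k}]")
              for k in range(data.shape[-1])]
    if mask_path is None:
        return slices
    mdata = np.asanyarray(nib.load(str(mask_path)).dataobj)
    if mdata.ndim == 2:
        mdata = mdata[..., None]
    if mdata.shape != data.shape:
        raise ValueError("image and mask volumes have different shapes")
    masks = [mdata[..., k] > 0 for k in range(mdata.shape[-1])]
    return slices, masks


def read_png_pairs(directory, spacing_mm: float = 0.625):
    """Read ``*_img.png`` / ``*_mask.png`` pairs written by the phantom CLI."""
    import imageio.v3 as iio

    names = sorted(f[:-8] for f in os.listdir(directory) if f.endswith("_img.png"))
    if not names:
        raise FileNotFoundError(f"no *_img.png files in {directory}")
    slices, masks = [], []
    for stem in names:
        raw = iio.imread(os.path.join(directory, f"{stem}_img.png"))
        hu = raw.astype(np.float64) - PNG_HU_OFFSET
        slices.append(CTSlice(pixels=hu, pixel_spacing_mm=(spacing_mm, spacing_mm),
                              source_id=stem))
        mpath = os.path.join(directory, f"{stem}_mask.png")
        masks.append(iio.imread(mpath) > 0 if os.path.exists(mpath) else None)
    return slices, masks


def window_and_normalize(ct: CTSlice | np.ndarray,
                         window: WindowSetting = WindowSetting()) -> np.ndarray:
    """Clip HU to the window and map linearly to [0, 1]."""
    hu = ct.pixels if isinstance(ct, CTSlice) else np.asarray(ct, dtype=np.float64)
    lo, hi = window.bounds
    return (np.clip(hu, lo, hi) - lo) / (hi - lo)


def resize_pair(image: np.ndarray, mask: np.ndarray | None,
                target_size: int = 256):
    """Resize to a square: bilinear for the image, nearest for the mask."""
    if target_size <= 0:
        raise ValueError("target size must be positive")
    shape = (target_size, target_size)
    out_img = _sk_resize(np.asarray(image, dtype=np.float64), shape, order=1,
                         mode="edge", anti_aliasing=False, preserve_range=True)
    if mask is None:
        return out_img, None
    out_mask = _sk_resize(np.asarray(mask).astype(np.float64), shape, order=0,
                          mode="edge", anti_aliasing=False, preserve_range=True)
    return out_img, out_mask > 0.5


def flip_double(samples: list[TrainingSample]) -> list[TrainingSample]:
    """Deterministic dataset doubling: originals first, then horizontal flips."""
    flips = [TrainingSample(image=np.fliplr(s.image).copy(),
                            mask=np.fliplr(s.mask).copy(),
                            flipped=not s.flipped,
                            source_id=s.source_id)
             for s in samples]
    return list(samples) + flips


def prepare_training_samples(slices, masks, window: WindowSetting = WindowSetting(),
                             target_size: int = 256,
                             flip: bool = True) -> list[TrainingSample]:
    """Full preprocessing chain: window -> resize -> (optionally) flip-double."""
    out = []
    for ct, mask in zip(slices, masks):
        img = window_and_normalize(ct, window)
        img, m = resize_pair(img, np.asarray(mask), target_size)
        out.append(TrainingSample(image=img, mask=m, source_id=ct.source_id))
    return flip_double(out) if flip else out
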