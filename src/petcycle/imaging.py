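"""Image containers, intensity normalization, and NIfTI volume I/O.

The unit of work throughout the package is a single axial 2D PET slice with
its in-plane pixel spacing. Training consumes aligned low-quality /
high-quality slice pairs (domains A and B of the translation problem) whose
intensities have been linearly mapped to [-1, 1]; evaluation happens on the
physical intensity scale, so the normalization here is exactly invertible and
the (vmin, vmax) window used is recorded alongside the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

import nibabel as nib

logger = logging.getLogger(__name__)

VALID_LABELS = {"head", "lung", "abdomen", "synthetic"}


@dataclass
class ImageSlice:
    """One 2D single-channel intensity grid with pixel spacing in mm."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    label: Optional[str] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(VALID_LABELS)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "ImageSlice":
        return ImageSlice(self.pixels.copy(), self.spacing, self.label)


@dataclass
class PairedSample:
    """A spatially aligned (low-quality, high-quality) slice pair."""

    lq: ImageSlice
    hq: ImageSlice

    def __post_init__(self):
        if self.lq.shape != self.hq.shape:
            raise ValueError(
                f"LQ shape {self.lq.shape} != HQ shape {self.hq.shape}; "
                "pairs must be pixel-aligned"
            )


def normalize(slc: ImageSlice, vmin: float, vmax: float) -> ImageSlice:
    """Linearly map the window [vmin, vmax] onto [-1, 1], clipping outside it.

    A degenerate window (vmin == vmax, i.e. a constant image) maps to all
    zeros with a logged warning rather than raising, since constant slices do
    occur at the ends of a field of view.
    """
    if vmin > vmax:
        raise ValueError(f"vmin ({vmin}) must not exceed vmax ({vmax})")
    if vmin == vmax:
        logger.warning(
            "normalize: degenerate window vmin == vmax == %s; returning zeros", vmin
        )
        return ImageSlice(np.zeros_like(slc.pixels), slc.spacing, slc.label)
    clipped = np.clip(slc.pixels, vmin, vmax)
    scaled = 2.0 * (clipped - vmin) / (vmax - vmin) - 1.0
    return ImageSlice(scaled, slc.spacing, slc.label)


def denormalize(slc: ImageSlice, vmin: float, vmax: float) -> ImageSlice:
    """Inverse of :func:`normalize` for in-range values: [-1,1] -> [vmin,vmax]."""
    restored = (slc.pixels + 1.0) * 0.5 * (vmax - vmin) + vmin
    return ImageSlice(restored, slc.spacing, slc.label)


def pair_window(pair: PairedSample) -> tuple[float, float]:
    """Normalization window for a pair: min/max of its high-quality member.

    Sharing the HQ window with the LQ member keeps both on one intensity
    scale so the supervised loss compares like with like.
    """
    return float(pair.hq.pixels.min()), float(pair.hq.pixels.max())


def normalize_pair(pair: PairedSample) -> tuple[PairedSample, tuple[float, float]]:
    vmin, vmax = pair_window(pair)
    return (
        PairedSample(normalize(pair.lq, vmin, vmax), normalize(pair.hq, vmin, vmax)),
        (vmin, vmax),
    )


def read_volume(path) -> list[ImageSlice]:
    """Read a NIfTI volume and return its axial slices in index order.

    The axial axis is the third array axis; a (H, W, n) volume yields n
    slices of shape (H, W). In-plane spacing comes from the header zooms.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else (1.0, 1.0)
    return [ImageSlice(data[:, :, i], spacing) for i in range(data.shape[2])]


def read_dicom_series(directory) -> list[ImageSlice]:
    """Read a directory of single-frame DICOM files as ordered axial slices.

    Files are sorted by InstanceNumber; rescale slope/intercept are applied
    when present. Read-only convenience behind the same slice interface as
    :func:`read_volume`.
    """
    import pydicom

    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"not a directory: {directory}")
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise IOError(f"no .dcm files in {directory}")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception as exc:
            raise IOError(f"cannot read DICOM file {f}: {exc}") from exc
    datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
    out = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing",
                                                  [1.0, 1.0]))[:2]
        out.append(ImageSlice(arr * slope + intercept, spacing))
    return out


def write_volume(slices: Sequence[ImageSlice], path) -> None:
    """Stack slices along the third axis and write a NIfTI-1 volume."""
    if len(slices) == 0:
        raise ValueError("cannot write an empty volume")
    shape = slices[0].shape
    for i, s in enumerate(slices):
        if s.shape != shape:
            raise ValueError(f"slice {i} shape {s.shape} != slice 0 shape {shape}")
    vol = np.stack([s.pixels for s in slices], axis=2)
    sr, sc = slices[0].spacing
    affine = np.diag([sr, sc, 1.0, 1.0])
    img = nib.Nifti1Image(vol, affine)
    path = Path(path)
    if path.name.endswith(".gz"):
        # gzip with a fixed mtime so identical volumes are byte-identical
        import gzip
        path.write_bytes(gzip.compress(img.to_bytes(), mtime=0))
    else:
        nib.save(img, str(path))
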