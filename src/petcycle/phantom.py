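"""Synthetic paired-phantom generation for the quality-translation pipeline.

Real training data for this problem are pairs of PET reconstructions of the
same acquisition: a high-quality image using the full detector of a
total-body scanner and a low-quality image restricted to a short axial field
of view (FOV). Scanner sensitivity grows with axial FOV, so the short-FOV
image is the same scene with fewer detected counts — noisier and slightly
softer. Such hospital data are access-restricted, so this module emulates
their *structure*: a noise-free activity phantom (elliptical "organs" on a
uniform background, plus small high-contrast "lesions") stands in for the
high-quality image, and its degraded counterpart is produced by a
count-limited imaging model

    LQ = Poisson(s * kappa * blur(HQ)) / (s * kappa) + N(0, sigma)

where ``s`` in (0, 1] is an effective sensitivity (1 ~ total-body FOV,
smaller ~ shorter FOV), ``kappa`` the expected counts per unit activity at
unit sensitivity, ``blur`` a Gaussian point-spread function and the additive
Gaussian term electronic noise. The Poisson term has variance proportional
to 1/s, so dialling sensitivity down monotonically degrades the image — a
single knob mirroring shorter and shorter axial FOVs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import ImageSlice, PairedSample, read_volume, write_volume


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and activity of one synthetic ground-truth slice."""

    grid_size: int = 64
    n_organs: int = 4
    activity_range: tuple[float, float] = (0.5, 2.0)
    n_lesions: int = 2
    lesion_contrast: float = 3.0
    background_activity: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.grid_size < 16:
            raise ValueError(f"grid_size must be >= 16, got {self.grid_size}")
        if self.n_organs < 1:
            raise ValueError(f"n_organs must be >= 1, got {self.n_organs}")
        lo, hi = self.activity_range
        if lo < 0 or not lo < hi:
            raise ValueError(
                f"activity_range must satisfy 0 <= min < max, got {self.activity_range}"
            )
        if self.n_lesions < 0:
            raise ValueError(f"n_lesions must be >= 0, got {self.n_lesions}")
        if self.lesion_contrast <= 1:
            raise ValueError(
                f"lesion_contrast must be > 1, got {self.lesion_contrast}"
            )
        if self.background_activity < 0:
            raise ValueError(
                f"background_activity must be >= 0, got {self.background_activity}"
            )


@dataclass(frozen=True)
class DegradationSpec:
    """Count-limited imaging model parameters for the low-quality branch."""

    sensitivity: float = 0.15
    psf_sigma_lq: float = 1.0
    count_scale: float = 200.0
    gauss_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.sensitivity <= 1:
            raise ValueError(
                f"sensitivity must be in (0, 1], got {self.sensitivity}"
            )
        if self.psf_sigma_lq < 0:
            raise ValueError(f"psf_sigma_lq must be >= 0, got {self.psf_sigma_lq}")
        if self.count_scale <= 0:
            raise ValueError(f"count_scale must be > 0, got {self.count_scale}")
        if self.gauss_sigma < 0:
            raise ValueError(f"gauss_sigma must be >= 0, got {self.gauss_sigma}")


def generate_phantom(spec: PhantomSpec) -> ImageSlice:
    """Draw one noise-free activity phantom (the high-quality ground truth).

    Uniform background, ``n_organs`` randomly placed/oriented ellipses with
    additive activities from ``activity_range`` (overlaps allowed — organs
    overlap in projections), then ``n_lesions`` small discs that multiply the
    local activity by ``lesion_contrast``. Deterministic for a given spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_size
    img = np.full((n, n), float(spec.background_activity))
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)

    for _ in range(spec.n_organs):
        cy, cx = rng.uniform(0, n, size=2)
        a = rng.uniform(n / 8, n / 3)
        b = rng.uniform(n / 8, n / 3)
        theta = rng.uniform(0, np.pi)
        activity = rng.uniform(*spec.activity_range)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] += activity

    for _ in range(spec.n_lesions):
        cy, cx = rng.uniform(0, n, size=2)
        r = rng.uniform(1.0, max(n / 16, 1.5))
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img[mask] *= spec.lesion_contrast

    return ImageSlice(img, spacing=(1.0, 1.0), label="synthetic")


def degrade(hq: ImageSlice, d: DegradationSpec) -> ImageSlice:
    """Produce the low-quality counterpart of a noise-free slice.

    Gaussian blur (resolution loss), scaled-Poisson counting noise whose
    variance grows as sensitivity drops, then additive Gaussian noise.
    """
    d.validate()
    if np.any(hq.pixels < 0):
        raise ValueError("degrade expects a nonnegative activity image")
    rng = np.random.default_rng(d.seed)
    blurred = gaussian_filter(hq.pixels, d.psf_sigma_lq) if d.psf_sigma_lq > 0 \
        else hq.pixels.copy()
    scale = d.sensitivity * d.count_scale
    noisy = rng.poisson(scale * blurred).astype(np.float64) / scale
    if d.gauss_sigma > 0:
        noisy = noisy + rng.normal(0.0, d.gauss_sigma, size=noisy.shape)
    return ImageSlice(noisy, spacing=hq.spacing, label=hq.label)


def make_dataset(
    spec: PhantomSpec,
    d: DegradationSpec,
    n_pairs: int,
    split_seed: int,
    group_of: Optional[Callable[[int], object]] = None,
) -> tuple[list[PairedSample], list[PairedSample]]:
    """Generate ``n_pairs`` aligned pairs and split them 9:1 (train:test).

    Pair ``i`` uses phantom seed ``spec.seed + i`` and degradation seed
    ``d.seed + i``, so every LQ is computed from its own HQ and the whole
    dataset is reproducible. ``group_of`` is a hook mapping a pair index to a
    group key (e.g. a patient) so grouped splits can be layered on later; the
    default splits by pair.
    """
    if n_pairs < 10:
        raise ValueError(f"n_pairs must be >= 10 for a 9:1 split, got {n_pairs}")
    spec.validate()
    d.validate()
    pairs = []
    for i in range(n_pairs):
        hq = generate_phantom(replace(spec, seed=spec.seed + i))
        lq = degrade(hq, replace(d, seed=d.seed + i))
        pairs.append(PairedSample(lq=lq, hq=hq))

    rng = np.random.default_rng(split_seed)
    if group_of is None:
        order = rng.permutation(n_pairs)
    else:
        # keep members of a group together: shuffle groups, then expand
        groups: dict[object, list[int]] = {}
        for i in range(n_pairs):
            groups.setdefault(group_of(i), []).append(i)
        keys = list(groups)
        rng.shuffle(keys)
        order = np.array([i for k in keys for i in groups[k]])
    n_test = n_pairs // 10
    test_idx = set(order[:n_test].tolist())
    train = [pairs[i] for i in range(n_pairs) if i not in test_idx]
    test = [pairs[i] for i in range(n_pairs) if i in test_idx]
    return train, test


def write_paired_dataset(train, test, out_dir, spec: PhantomSpec,
                         d: DegradationSpec, split_seed: int) -> Path:
    """Persist a paired dataset as two NIfTI volumes plus a JSON manifest.

    Slices are stacked on the third axis, train split first, then test; the
    manifest records the generating specs, the split seed and the index
    boundary, so the dataset can be reloaded (or regenerated) exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = list(train) + list(test)
    write_volume([p.lq for p in pairs], out_dir / "lq.nii.gz")
    write_volume([p.hq for p in pairs], out_dir / "hq.nii.gz")
    manifest = {
        "phantom_spec": asdict(spec),
        "degradation_spec": asdict(d),
        "split_seed": split_seed,
        "n_train": len(train),
        "n_test": len(test),
        "files": {"lq": "lq.nii.gz", "hq": "hq.nii.gz"},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_paired_dataset(manifest_path):
    """Inverse of :func:`write_paired_dataset`: returns (train, test)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    lq = read_volume(base / manifest["files"]["lq"])
    hq = read_volume(base / manifest["files"]["hq"])
    if len(lq) != len(hq):
        raise IOError("lq/hq volumes have different slice counts")
    pairs = [PairedSample(lq=a, hq=b) for a, b in zip(lq, hq)]
    n_train = manifest["n_train"]
    return pairs[:n_train], pairs[n_train:]
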