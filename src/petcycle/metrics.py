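"""Image-quality metrics: NRMSE, PSNR and SSIM, plus per-volume aggregation.

Conventions (all computed on physical-scale intensities, since every one of
these quantities is scale-dependent through a reference normaliser):

* ``NRMSE = sqrt( sum (x-y)^2 / sum y^2 ) * 100`` — the reference image y in
  the denominator; the x100 factor is applied as printed in the defining
  formula and can be disabled via :class:`MetricConfig`.
* ``PSNR = 20 log10( MAX / sqrt(MSE) )`` in dB, with MAX the peak intensity
  of the reference image by default (a fixed dynamic range may be supplied
  instead). Identical images have MSE = 0 and are reported as the +inf
  sentinel, flagged in the aggregate report.
* ``SSIM`` is the mean over all valid window centres of the local statistic

      (2 mu_x mu_y + C1)(2 sigma_xy + C2)
      -----------------------------------
      (mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)

  with moments taken over an 11x11 Gaussian-weighted window (sigma = 1.5;
  ``ssim_sigma = 0`` switches to a uniform window), C1 = (k1 L)^2,
  C2 = (k2 L)^2, and dynamic range L = reference max - reference min.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import correlate

from .imaging import ImageSlice

ArrayLike = Union[np.ndarray, ImageSlice]


def _pixels(x: ArrayLike) -> np.ndarray:
    return x.pixels if isinstance(x, ImageSlice) else np.asarray(x, dtype=np.float64)


@dataclass(frozen=True)
class MetricConfig:
    ssim_window: int = 11
    ssim_sigma: float = 1.5          # 0 -> uniform window
    k1: float = 0.01
    k2: float = 0.03
    max_convention: str = "reference_peak"   # or "fixed"
    fixed_max: Optional[float] = None
    nrmse_percent: bool = True

    def validate(self) -> None:
        if self.ssim_window < 3 or self.ssim_window % 2 == 0:
            raise ValueError(f"ssim_window must be odd >= 3, got {self.ssim_window}")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be > 0")
        if self.max_convention not in ("reference_peak", "fixed"):
            raise ValueError(f"unknown max_convention {self.max_convention!r}")
        if self.max_convention == "fixed" and self.fixed_max is None:
            raise ValueError("fixed max_convention requires fixed_max")


def nrmse(x: ArrayLike, y: ArrayLike, cfg: MetricConfig = MetricConfig()) -> float:
    """Normalised RMSE of estimate x against reference y."""
    xa, ya = _pixels(x), _pixels(y)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    denom = float(np.sum(ya * ya))
    if denom == 0.0:
        raise ValueError("NRMSE undefined for an all-zero reference image")
    val = math.sqrt(float(np.sum((xa - ya) ** 2)) / denom)
    return val * 100.0 if cfg.nrmse_percent else val


def psnr(x: ArrayLike, y: ArrayLike, cfg: MetricConfig = MetricConfig()) -> float:
    """Peak signal-to-noise ratio in dB; +inf sentinel for identical images."""
    cfg.validate()
    xa, ya = _pixels(x), _pixels(y)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    mse = float(np.mean((xa - ya) ** 2))
    if cfg.max_convention == "fixed":
        peak = float(cfg.fixed_max)
    else:
        peak = float(ya.max())
    if mse == 0.0:
        return math.inf
    return 20.0 * math.log10(peak / math.sqrt(mse))


def _ssim_window(cfg: MetricConfig) -> np.ndarray:
    w = cfg.ssim_window
    if cfg.ssim_sigma > 0:
        ax = np.arange(w) - (w - 1) / 2.0
        g = np.exp(-(ax ** 2) / (2.0 * cfg.ssim_sigma ** 2))
        kernel = np.outer(g, g)
    else:
        kernel = np.ones((w, w))
    return kernel / kernel.sum()


def ssim(x: ArrayLike, y: ArrayLike, cfg: MetricConfig = MetricConfig()) -> float:
    """Mean local structural similarity between x and y."""
    cfg.validate()
    xa, ya = _pixels(x), _pixels(y)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    w = cfg.ssim_window
    if min(xa.shape) < w:
        raise ValueError(
            f"image {xa.shape} smaller than the {w}x{w} SSIM window"
        )
    kernel = _ssim_window(cfg)
    half = w // 2

    def local_mean(img):
        # correlate then crop to valid window centres
        full = correlate(img, kernel, mode="constant")
        return full[half:img.shape[0] - half, half:img.shape[1] - half]

    mu_x = local_mean(xa)
    mu_y = local_mean(ya)
    xx = local_mean(xa * xa) - mu_x * mu_x
    yy = local_mean(ya * ya) - mu_y * mu_y
    xy = local_mean(xa * ya) - mu_x * mu_y

    L = float(ya.max() - ya.min())
    if L == 0.0:
        L = 1.0  # constant reference: stabilisers keep the statistic defined
    c1 = (cfg.k1 * L) ** 2
    c2 = (cfg.k2 * L) ** 2
    num = (2 * mu_x * mu_y + c1) * (2 * xy + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (xx + yy + c2)
    return float(np.mean(num / den))


@dataclass
class MetricReport:
    """Per-slice metrics plus mean +/- sd, the shape of a results table."""

    nrmse: list[float] = field(default_factory=list)
    psnr: list[float] = field(default_factory=list)
    ssim: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.nrmse)

    @property
    def psnr_inf_count(self) -> int:
        return sum(1 for v in self.psnr if math.isinf(v))

    def summary(self) -> dict:
        def stats(vals):
            arr = np.asarray(vals, dtype=np.float64)
            mean = float(arr.mean()) if arr.size else math.nan
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            return {"mean": mean, "sd": sd}

        out = {
            "nrmse": stats(self.nrmse),
            "psnr_db": stats(self.psnr),
            "ssim": stats(self.ssim),
            "n_slices": self.n,
        }
        if self.psnr_inf_count:
            out["psnr_infinite_slices"] = self.psnr_inf_count
        return out

    def to_json(self, path) -> None:
        payload = {"per_slice": {"nrmse": self.nrmse, "psnr_db": self.psnr,
                                 "ssim": self.ssim},
                   "summary": self.summary()}
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["slice", "nrmse", "psnr_db", "ssim"])
            for i, (a, b, c) in enumerate(zip(self.nrmse, self.psnr, self.ssim)):
                writer.writerow([i, a, b, c])
            s = self.summary()
            writer.writerow(["mean", s["nrmse"]["mean"], s["psnr_db"]["mean"],
                             s["ssim"]["mean"]])
            writer.writerow(["sd", s["nrmse"]["sd"], s["psnr_db"]["sd"],
                             s["ssim"]["sd"]])


def evaluate_pairs(estimates: Sequence[ArrayLike], references: Sequence[ArrayLike],
                   cfg: MetricConfig = MetricConfig()) -> MetricReport:
    """All three metrics for aligned (estimate, reference) sequences."""
    if len(estimates) != len(references):
        raise ValueError(
            f"length mismatch: {len(estimates)} estimates vs "
            f"{len(references)} references"
        )
    report = MetricReport()
    for est, ref in zip(estimates, references):
        report.nrmse.append(nrmse(est, ref, cfg))
        report.psnr.append(psnr(est, ref, cfg))
        report.ssim.append(ssim(est, ref, cfg))
    return report
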