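"""Image-quality assessment: SSIM and PSNR, with Table-style aggregation.

SSIM is the product of three comparison terms — luminance l, contrast c and
structure s —

    SSIM(x, y) = l^a * c^b * s^gamma,
    l = (2 mu_x mu_y + c1) / (mu_x^2 + mu_y^2 + c1)
    c = (2 sig_x sig_y + c2) / (sig_x^2 + sig_y^2 + c2)
    s = (sig_xy + c3) / (sig_x sig_y + c3)

with stabilizing constants c1 = (k1 L)^2, c2 = (k2 L)^2, c3 = c2/2 where L
is the data range.  With a = b = gamma = 1 and c3 = c2/2 the product
collapses to the familiar two-factor form
(2 mu_x mu_y + c1)(2 sig_xy + c2) / ((mu_x^2 + mu_y^2 + c1)(sig_x^2 + sig_y^2 + c2)).

Two windows are offered: ``global`` computes one set of moments over the
whole image (exactly testable against scalar arithmetic) and ``gaussian``
computes a local SSIM map under a Gaussian weighting window and returns its
mean (the common practice for perceptual comparison; the default is an
11x11 window, sigma 1.5).

PSNR = 10 log10(peak^2 / MSE) in dB; identical images yield the +inf
sentinel, which aggregation excludes (with a count) rather than capping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import DimensionMismatchError, InvalidArgumentError
from .phantom_forge import Phantom

__all__ = ["SSIMConfig", "MetricRecord", "AggregateReport", "ssim", "psnr",
           "aggregate", "records_to_csv", "aggregate_to_json"]


@dataclass(frozen=True)
class SSIMConfig:
    a: float = 1.0
    b: float = 1.0
    gamma: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 2.0  # images live in [-1, 1]
    window: str = "gaussian"  # "global" or "gaussian"
    window_size: int = 11
    window_sigma: float = 1.5

    def __post_init__(self):
        if min(self.a, self.b, self.gamma) <= 0:
            raise InvalidArgumentError("SSIM exponents must be positive")
        if self.k1 <= 0 or self.k2 <= 0 or self.data_range <= 0:
            raise InvalidArgumentError("k1, k2 and data_range must be positive")
        if self.window not in ("global", "gaussian"):
            raise InvalidArgumentError("window must be 'global' or 'gaussian'")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


def _arr(x) -> np.ndarray:
    return x.pixels if isinstance(x, Phantom) else np.asarray(x, dtype=np.float64)


def _ssim_terms(mx, my, vx, vy, vxy, cfg: SSIMConfig):
    sx, sy = np.sqrt(np.maximum(vx, 0.0)), np.sqrt(np.maximum(vy, 0.0))
    l = (2 * mx * my + cfg.c1) / (mx**2 + my**2 + cfg.c1)
    c = (2 * sx * sy + cfg.c2) / (vx + vy + cfg.c2)
    s = (vxy + cfg.c3) / (sx * sy + cfg.c3)
    return l, c, s


def _signed_pow(t, e):
    # structure term may be negative; keep its sign under a fractional
    # exponent the way |t|^e * sign(t) does (for e = 1 this is t itself)
    return np.sign(t) * np.abs(t) ** e


def ssim(x, y, cfg: SSIMConfig = SSIMConfig()) -> float:
    """Structural similarity between two equally-shaped images."""
    ax, ay = _arr(x), _arr(y)
    if ax.shape != ay.shape:
        raise DimensionMismatchError(f"shape mismatch {ax.shape} vs {ay.shape}")
    if np.array_equal(ax, ay):
        return 1.0
    if cfg.window == "global":
        mx, my = ax.mean(), ay.mean()
        vx, vy = ax.var(), ay.var()
        vxy = ((ax - mx) * (ay - my)).mean()
        l, c, s = _ssim_terms(mx, my, vx, vy, vxy, cfg)
        return float(l**cfg.a * c**cfg.b * _signed_pow(s, cfg.gamma))
    # Gaussian-windowed local map; truncate chosen so the kernel support
    # matches window_size (radius = (size-1)/2), edge-replicated filtering,
    # and the half-window border excluded from the average — the common
    # convention for windowed SSIM
    radius = (cfg.window_size - 1) // 2
    trunc = radius / cfg.window_sigma
    def g(im):
        return gaussian_filter(im, cfg.window_sigma, mode="nearest", truncate=trunc)
    mx, my = g(ax), g(ay)
    vx = g(ax * ax) - mx * mx
    vy = g(ay * ay) - my * my
    vxy = g(ax * ay) - mx * my
    l, c, s = _ssim_terms(mx, my, vx, vy, vxy, cfg)
    smap = l**cfg.a * c**cfg.b * _signed_pow(s, cfg.gamma)
    if min(smap.shape) > 2 * radius:
        smap = smap[radius:-radius, radius:-radius]
    return float(smap.mean())


def psnr(x, y, peak: float = 2.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images coincide."""
    ax, ay = _arr(x), _arr(y)
    if ax.shape != ay.shape:
        raise DimensionMismatchError(f"shape mismatch {ax.shape} vs {ay.shape}")
    if peak <= 0:
        raise InvalidArgumentError("peak must be positive")
    mse = float(np.mean((ax - ay) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


@dataclass
class MetricRecord:
    image_id: str
    method: str
    undersampling_ratio: float
    ssim: float
    psnr_db: float


@dataclass
class AggregateReport:
    """Per-(method, ratio) mean +/- sample SD of SSIM and PSNR.

    ``groups`` maps (method, ratio) to a dict with mean_ssim, sd_ssim,
    mean_psnr, sd_psnr, n and n_psnr_inf (infinite-PSNR records excluded
    from the PSNR aggregate but counted).
    """

    groups: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"method": m, "undersampling_ratio": r, **stats}
                for (m, r), stats in sorted(self.groups.items())]
        return pd.DataFrame(rows)


def _mean_sd(values: np.ndarray):
    n = len(values)
    if n == 0:
        return float("nan"), 0.0
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    return mean, sd


def aggregate(records: Iterable[MetricRecord]) -> AggregateReport:
    records = list(records)
    if not records:
        raise InvalidArgumentError("no metric records to aggregate")
    report = AggregateReport()
    keys = sorted({(r.method, r.undersampling_ratio) for r in records})
    for key in keys:
        grp = [r for r in records if (r.method, r.undersampling_ratio) == key]
        ssims = np.array([r.ssim for r in grp], dtype=float)
        psnrs = np.array([r.psnr_db for r in grp], dtype=float)
        finite = psnrs[np.isfinite(psnrs)]
        mean_ssim, sd_ssim = _mean_sd(ssims)
        mean_psnr, sd_psnr = _mean_sd(finite)
        report.groups[key] = {
            "mean_ssim": mean_ssim, "sd_ssim": sd_ssim,
            "mean_psnr": mean_psnr, "sd_psnr": sd_psnr,
            "n": len(grp), "n_psnr_inf": int(len(psnrs) - len(finite)),
        }
    return report


def records_to_csv(records: Iterable[MetricRecord], path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records])
    df.to_csv(path, index=False)


def aggregate_to_json(report: AggregateReport, path) -> None:
    import json

    payload = {f"{m}@{r}": stats for (m, r), stats in sorted(report.groups.items())}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
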