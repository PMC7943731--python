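"""Measurement operators for compressive photoacoustic acquisition.

Three matrix families are provided:

* ``gaussian`` — a random M x N^2 matrix with i.i.d. N(0, 1/M) entries.
  The 1/M variance makes E||Kx||^2 ~ ||x||^2, so the empirical restricted
  isometry diagnostic reads on the usual scale.
* ``pat_time`` — the physical delay kernel of a ring-array scanner: row
  (h, s) pairs transducer h with time sample t = s*dt, and a pixel
  contributes 1/(2*pi*c) when its acoustic travel time to the transducer
  falls in the bin [t - dt/2, t + dt/2] (nearest-sample discretization of
  the ideal delta kernel).
* ``pat_freq`` — the same kernel in the frequency domain: entry
  i*c*k_n*exp(-i*k_n*d)/d at wavenumber k_n and pixel-transducer
  distance d.

Vectorized images use row-major (C-order) flattening everywhere.  The
adjoint ("proxy") operation K^T v produces the artifact-laden image the
reconstruction networks take as input; for complex matrices the conjugate
transpose is applied and the real part is returned, since the image to be
recovered is real.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import DimensionMismatchError, InvalidArgumentError, InvalidGeometryError
from .phantom_forge import Phantom

__all__ = [
    "PATGeometry",
    "MeasurementMatrix",
    "MeasurementVector",
    "RIPReport",
    "build_gaussian_matrix",
    "build_pat_matrix_time",
    "build_pat_matrix_freq",
    "measure",
    "proxy",
    "empirical_rip",
    "desk_geometry",
    "save_matrix",
    "load_matrix",
]

#: ring-array defaults mirroring a 512-element, 80-mm-diameter, 5-MHz scanner
FULL_RING_TRANSDUCERS = 512
FULL_RING_RADIUS_MM = 40.0
SOUND_SPEED_MM_PER_US = 1.5
CENTER_FREQ_MHZ = 5.0


@dataclass
class PATGeometry:
    """Ring-array acquisition geometry.

    Units: millimetres for lengths, microseconds for times, so the sound
    speed is in mm/us and wavenumbers in 1/mm.  Transducers sit equally
    spaced on a circle of ``ring_radius``; the square image grid of side
    ``grid_extent`` is centred in the ring and every pixel centre must lie
    strictly inside it.
    """

    num_transducers: int = FULL_RING_TRANSDUCERS
    ring_radius: float = FULL_RING_RADIUS_MM
    sound_speed: float = SOUND_SPEED_MM_PER_US
    grid_side: int = 128
    grid_extent: float = 25.0
    time_samples: int = 64
    dt: float = 0.5
    wavenumbers: tuple = ()

    def __post_init__(self):
        if self.num_transducers < 1 or self.grid_side < 2:
            raise InvalidGeometryError("need at least one transducer and a 2x2 grid")
        half_diag = self.grid_extent / 2.0 * np.sqrt(2.0)
        if half_diag >= self.ring_radius:
            raise InvalidGeometryError(
                f"grid corner at {half_diag:.2f} mm reaches the ring "
                f"(radius {self.ring_radius:.2f} mm); shrink grid_extent")
        if any(k < 0 for k in self.wavenumbers):
            raise InvalidArgumentError("wavenumbers must be non-negative")

    def transducer_positions(self) -> np.ndarray:
        """(p, 2) array of (y, x) positions on the ring."""
        ang = 2.0 * np.pi * np.arange(self.num_transducers) / self.num_transducers
        return self.ring_radius * np.stack([np.sin(ang), np.cos(ang)], axis=1)

    def pixel_positions(self) -> np.ndarray:
        """(N*N, 2) array of (y, x) pixel centres, row-major order."""
        n = self.grid_side
        step = self.grid_extent / n
        coords = -self.grid_extent / 2.0 + step * (np.arange(n) + 0.5)
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        return np.stack([yy.ravel(), xx.ravel()], axis=1)

    def distances(self) -> np.ndarray:
        """(p, N*N) pixel-transducer distance table."""
        t = self.transducer_positions()[:, None, :]
        px = self.pixel_positions()[None, :, :]
        return np.sqrt(((t - px) ** 2).sum(axis=2))

    def default_wavenumbers(self, count: int = 16) -> tuple:
        """Wavenumber grid spanning the scanner passband.

        k = 2*pi*f/c, with f covering (0, 2*f_c] in ``count`` steps — a
        5-MHz centre frequency with >80% fractional bandwidth reaches
        roughly twice the centre frequency.
        """
        freqs = CENTER_FREQ_MHZ * 2.0 * (np.arange(1, count + 1) / count)
        return tuple(2.0 * np.pi * freqs / self.sound_speed)


def desk_geometry(grid_side: int = 16, num_transducers: int = 8,
                  time_samples: int = 40) -> PATGeometry:
    """Small geometry preset for laptop-scale runs and tests.

    Scales the 512-element ring down while keeping the radius, sound speed
    and relative grid extent of the full instrument.
    """
    g = PATGeometry(num_transducers=num_transducers, grid_side=grid_side,
                    time_samples=time_samples, dt=1.0,
                    grid_extent=25.0)
    return g


@dataclass
class MeasurementMatrix:
    entries: np.ndarray
    kind: str  # gaussian | pat_time | pat_freq | custom
    grid_side: int
    undersampling_ratio: float
    geometry: Optional[PATGeometry] = None
    seed: Optional[int] = None

    def __post_init__(self):
        m, n2 = self.entries.shape
        if n2 != self.grid_side**2:
            raise DimensionMismatchError("column count must equal grid_side^2")
        # compressive operators must undersample; the physical ring-array
        # kernel may legitimately be overdetermined (p * q rows > N^2)
        if self.kind == "gaussian" and m > n2:
            raise InvalidArgumentError(
                f"matrix has {m} rows but only {n2} pixels; M <= N^2 is required")
        self.undersampling_ratio = m / n2

    @property
    def num_measurements(self) -> int:
        return self.entries.shape[0]


@dataclass
class MeasurementVector:
    values: np.ndarray
    source_matrix_id: str = ""
    noise_sigma: float = 0.0


@dataclass
class RIPReport:
    sparsity_s: int
    trials: int
    delta_hat: float
    ratio_min: float
    ratio_max: float


def build_gaussian_matrix(grid_side: int, undersampling_ratio: float,
                          seed: int) -> MeasurementMatrix:
    """Random compressive operator: M = round(ratio * N^2) rows, N(0, 1/M)."""
    if not (0.0 < undersampling_ratio <= 1.0):
        raise InvalidArgumentError("undersampling_ratio must lie in (0, 1]")
    n2 = grid_side**2
    m = max(1, int(round(undersampling_ratio * n2)))
    rng = np.random.default_rng(seed)
    entries = rng.normal(0.0, 1.0 / np.sqrt(m), size=(m, n2))
    return MeasurementMatrix(entries=entries, kind="gaussian", grid_side=grid_side,
                             undersampling_ratio=m / n2, seed=seed)


def build_pat_matrix_time(geometry: PATGeometry) -> MeasurementMatrix:
    """Time-domain delay kernel on the ring array.

    Row (h, s) (row index h*q_s + s-1, s = 1..q_s) holds 1/(2*pi*c) at
    pixel (i, j) iff |s*dt - d(h,i,j)/c| <= dt/2, else 0.
    """
    d = geometry.distances()  # (p, N^2)
    c = geometry.sound_speed
    p, n2 = d.shape
    qs = geometry.time_samples
    travel = d / c  # us
    rows = []
    amp = 1.0 / (2.0 * np.pi * c)
    t_grid = geometry.dt * np.arange(1, qs + 1)
    for h in range(p):
        # (qs, n2) indicator of the delta firing in each time bin
        fire = np.abs(t_grid[:, None] - travel[h][None, :]) <= geometry.dt / 2.0
        rows.append(amp * fire.astype(np.float64))
    entries = np.concatenate(rows, axis=0)
    return MeasurementMatrix(entries=entries, kind="pat_time",
                             grid_side=geometry.grid_side,
                             undersampling_ratio=entries.shape[0] / n2,
                             geometry=geometry)


def build_pat_matrix_freq(geometry: PATGeometry) -> MeasurementMatrix:
    """Frequency-domain kernel: entry i*c*k_n*exp(-i*k_n*d)/d at row (h, n)."""
    ks = np.asarray(geometry.wavenumbers if geometry.wavenumbers
                    else geometry.default_wavenumbers(), dtype=np.float64)
    if (ks < 0).any():
        raise InvalidArgumentError("wavenumbers must be non-negative")
    d = geometry.distances()  # (p, N^2)
    if (d <= 0).any():
        raise InvalidGeometryError("zero pixel-transducer distance")
    c = geometry.sound_speed
    # rows ordered h-major: (h, n) -> h*q_n + n
    kd = ks[None, :, None] * d[:, None, :]  # (p, q_n, N^2)
    entries = 1j * c * ks[None, :, None] * np.exp(-1j * kd) / d[:, None, :]
    entries = entries.reshape(-1, d.shape[1])
    return MeasurementMatrix(entries=entries, kind="pat_freq",
                             grid_side=geometry.grid_side,
                             undersampling_ratio=entries.shape[0] / d.shape[1],
                             geometry=geometry)


def _as_image_array(x) -> np.ndarray:
    return x.pixels if isinstance(x, Phantom) else np.asarray(x, dtype=np.float64)


def measure(K: MeasurementMatrix, x, noise_sigma: float = 0.0,
            seed: Optional[int] = None) -> MeasurementVector:
    """Forward measurement v = K vec(x), plus optional white Gaussian noise."""
    arr = _as_image_array(x)
    if arr.size != K.entries.shape[1]:
        raise DimensionMismatchError(
            f"image has {arr.size} pixels, matrix expects {K.entries.shape[1]}")
    v = K.entries @ arr.ravel(order="C")
    if noise_sigma < 0:
        raise InvalidArgumentError("noise_sigma must be >= 0")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sigma, size=v.shape)
        if np.iscomplexobj(v):
            noise = noise + 1j * rng.normal(0.0, noise_sigma, size=v.shape)
        v = v + noise
    return MeasurementVector(values=v, source_matrix_id=K.kind,
                             noise_sigma=noise_sigma)


def proxy(K: MeasurementMatrix, v: MeasurementVector) -> Phantom:
    """Back-projection image proxy V-hat = K^T v (conjugate transpose, real part)."""
    vals = v.values if isinstance(v, MeasurementVector) else np.asarray(v)
    if vals.shape[0] != K.entries.shape[0]:
        raise DimensionMismatchError(
            f"vector length {vals.shape[0]} != matrix rows {K.entries.shape[0]}")
    img = K.entries.conj().T @ vals
    img = np.real(img).reshape(K.grid_side, K.grid_side)
    return Phantom(pixels=img, side_length=K.grid_side, label=f"proxy/{K.kind}")


def empirical_rip(K: MeasurementMatrix, sparsity_s: int, trials: int,
                  seed: int) -> RIPReport:
    """Monte-Carlo restricted-isometry diagnostic.

    Draws ``trials`` random s-sparse unit vectors (support uniform without
    replacement, values standard normal, then normalized), records the
    extreme values of ||K theta||^2 / ||theta||^2, and reports
    delta-hat = max(1 - ratio_min, ratio_max - 1).  A matrix acting as a
    near-isometry on sparse vectors yields a small delta-hat; this is a
    diagnostic, not a certificate (certifying the property exactly is
    combinatorial).
    """
    n2 = K.entries.shape[1]
    if not (1 <= sparsity_s <= n2):
        raise InvalidArgumentError("sparsity_s must lie in [1, N^2]")
    if trials < 1:
        raise InvalidArgumentError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    ratio_min, ratio_max = np.inf, -np.inf
    for _ in range(trials):
        support = rng.choice(n2, size=sparsity_s, replace=False)
        vals = rng.standard_normal(sparsity_s)
        theta = np.zeros(n2)
        theta[support] = vals
        theta /= np.linalg.norm(theta)
        # ratio of explicitly computed norms: an exact isometry gives
        # bitwise-identical numerator and denominator, hence exactly 1
        r = float(np.linalg.norm(K.entries @ theta) ** 2
                  / np.linalg.norm(theta) ** 2)
        ratio_min = min(ratio_min, r)
        ratio_max = max(ratio_max, r)
    delta = max(1.0 - ratio_min, ratio_max - 1.0)
    return RIPReport(sparsity_s=sparsity_s, trials=trials, delta_hat=delta,
                     ratio_min=ratio_min, ratio_max=ratio_max)


def save_matrix(K: MeasurementMatrix, path) -> None:
    """Persist entries as .npz with a JSON sidecar describing provenance."""
    path = Path(path)
    np.savez_compressed(path, entries=K.entries)
    side = {"kind": K.kind, "grid_side": K.grid_side, "seed": K.seed,
            "undersampling_ratio": K.undersampling_ratio}
    if K.geometry is not None:
        g = K.geometry
        side["geometry"] = {
            "num_transducers": g.num_transducers, "ring_radius": g.ring_radius,
            "sound_speed": g.sound_speed, "grid_side": g.grid_side,
            "grid_extent": g.grid_extent, "time_samples": g.time_samples,
            "dt": g.dt, "wavenumbers": list(g.wavenumbers)}
    path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def load_matrix(path) -> MeasurementMatrix:
    path = Path(path)
    entries = np.load(path.with_suffix(".npz"))["entries"]
    side = json.loads(path.with_suffix(".json").read_text())
    geom = None
    if "geometry" in side:
        gd = dict(side["geometry"])
        gd["wavenumbers"] = tuple(gd["wavenumbers"])
        geom = PATGeometry(**gd)
    return MeasurementMatrix(entries=entries, kind=side["kind"],
                             grid_side=side["grid_side"],
                             undersampling_ratio=side["undersampling_ratio"],
                             geometry=geom, seed=side.get("seed"))
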