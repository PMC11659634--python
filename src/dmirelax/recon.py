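"""Image/k-space transforms and Hamming-apodized downsampling.

Conventions: all transforms are unitary with k = 0 at the grid center
(index ``n//2`` along each axis).  High-resolution phantoms are taken
to acquisition resolution by cropping their k-space to the target
matrix, applying the Hamming window of the readout (and, optionally,
the drift weight field of the simulated encoding scheme) and inverse
transforming.  This reproduces the point-spread function and
partial-volume mixing of a Hamming-weighted acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .encoding import WeightField, hamming_filter

__all__ = [
    "ImageSeries",
    "KSpaceSeries",
    "forward_ft",
    "inverse_ft",
    "central_crop",
    "nudft_adjoint",
    "downsample_hamming",
    "downsample_fractions",
]


@dataclass
class ImageSeries:
    """Stack of co-registered volumes, one per TI or TE.

    ``volumes`` has shape ``(n_times,) + shape``; ``times_ms`` holds
    the corresponding inversion or echo times; ``mode`` is "IR" or
    "SE" (or "none" for generic stacks).
    """

    volumes: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    times_ms: tuple[float, ...]
    mode: str = "none"

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes)
        self.times_ms = tuple(float(t) for t in self.times_ms)
        if self.volumes.shape[0] != len(self.times_ms):
            raise ValueError(
                f"{self.volumes.shape[0]} volumes but {len(self.times_ms)} times"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes.shape[1:]

    @property
    def n_times(self) -> int:
        return len(self.times_ms)


@dataclass
class KSpaceSeries:
    """Non-Cartesian k-space samples per timepoint.

    ``samples`` has shape ``(n_times, n_coords)``; ``coords`` has shape
    ``(n_coords, ndim)`` in *grid-index units*: integer coordinates
    coincide with the centered Cartesian grid of ``grid_meta["matrix"]``
    (multiply cycles/mm by the FOV in mm to convert).
    """

    samples: np.ndarray
    coords: np.ndarray
    grid_meta: dict = field(default_factory=dict)
    times_ms: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=complex))
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.samples.shape[1] != self.coords.shape[0]:
            raise ValueError(
                f"{self.samples.shape[1]} samples per timepoint but "
                f"{self.coords.shape[0]} coordinates"
            )


def forward_ft(image: np.ndarray) -> np.ndarray:
    """Unitary DFT of a volume with the zero-frequency sample centered."""
    image = np.asarray(image)
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(image), norm="ortho")
    )


def inverse_ft(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`forward_ft`."""
    kspace = np.asarray(kspace)
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(kspace), norm="ortho")
    )


def central_crop(kspace: np.ndarray, target: tuple[int, ...]) -> np.ndarray:
    """Crop a centered k-space volume to the target matrix.

    For even targets the extra sample sits on the negative-frequency
    side, consistent with the DC index ``n//2``.
    """
    target = tuple(target)
    if len(target) != kspace.ndim:
        raise ValueError("target dimensionality mismatch")
    slices = []
    for n, m in zip(kspace.shape, target):
        if m > n:
            raise ValueError(f"target size {m} exceeds source size {n}")
        start = n // 2 - m // 2
        slices.append(slice(start, start + m))
    return kspace[tuple(slices)]


def nudft_adjoint(
    series: KSpaceSeries,
    grid: tuple[int, ...],
    voxel_size_mm: tuple[float, ...] | None = None,
) -> ImageSeries:
    """Adjoint non-uniform DFT onto a Cartesian grid, *without* density
    compensation.

    ``img[x] = N^{-1/2} sum_j s_j exp(+2i pi sum_d k_{jd} (x_d - c_d) / n_d)``

    with ``c_d = n_d // 2``.  When the coordinates cover the centered
    Cartesian grid exactly once this equals the centered inverse
    unitary FFT.  Duplicated coordinates contribute additively
    (no-density-compensation semantics).  Coordinates outside the
    Nyquist band of the grid trigger a warning but are still used.
    """
    grid = tuple(grid)
    coords = series.coords
    if coords.shape[1] != len(grid):
        raise ValueError("coordinate dimensionality does not match grid")
    for d, n in enumerate(grid):
        if np.any(coords[:, d] < -n / 2 - 1e-9) or np.any(coords[:, d] > n / 2 + 1e-9):
            warnings.warn(
                f"k-space coordinates along axis {d} exceed the Nyquist band "
                f"of the {n}-point grid; samples are used anyway",
                stacklevel=2,
            )
            break
    n_total = int(np.prod(grid))
    # spatial index offsets per axis, flattened voxel list (n_total, ndim)
    mesh = np.meshgrid(*[np.arange(n) - n // 2 for n in grid], indexing="ij")
    x = np.column_stack([m.ravel() for m in mesh]).astype(float)
    # phase matrix (n_total, n_coords)
    phase = x @ (coords / np.asarray(grid, dtype=float)).T
    e = np.exp(2j * np.pi * phase)
    vols = (e @ series.samples.T).T / np.sqrt(n_total)
    vols = vols.reshape((series.samples.shape[0],) + grid)
    times = series.times_ms or tuple(range(series.samples.shape[0]))
    if voxel_size_mm is None:
        fov = series.grid_meta.get("fov_mm")
        if fov is not None:
            voxel_size_mm = tuple(f / n for f, n in zip(np.atleast_1d(fov), grid))
        else:
            voxel_size_mm = (1.0,) * len(grid)
    return ImageSeries(vols, tuple(voxel_size_mm), times, mode=series.grid_meta.get("mode", "none"))


def _zero_unpaired_nyquist(k: np.ndarray) -> np.ndarray:
    """Zero the unpaired -n/2 Nyquist planes of even axes.

    Central cropping to an even matrix keeps the -n/2 frequency plane
    but not its +n/2 partner, which would leave a real object's
    low-resolution image with a spurious imaginary part.  Zeroing the
    unpaired planes restores exact Hermitian symmetry.
    """
    for ax, n in enumerate(k.shape):
        if n % 2 == 0:
            sl = [slice(None)] * k.ndim
            sl[ax] = 0
            k[tuple(sl)] = 0.0
    return k


def _downsample_volume(
    volume: np.ndarray,
    target: tuple[int, ...],
    window: np.ndarray,
    weights_t: np.ndarray | None,
    hermitian: bool = False,
) -> np.ndarray:
    k = forward_ft(volume)
    k = central_crop(k, target)
    k = k * window
    if weights_t is not None:
        k = k * weights_t
    if hermitian:
        k = _zero_unpaired_nyquist(k)
    scale = np.sqrt(np.prod(target) / np.prod(volume.shape))
    return inverse_ft(k) * scale


def downsample_hamming(
    highres: ImageSeries,
    target: tuple[int, ...],
    weights: WeightField | None = None,
    window: str = "radial",
    imag_tol: float = 1e-9,
) -> ImageSeries:
    """Downsample a series to acquisition resolution in k-space.

    Pipeline per timepoint: forward FT, central crop to ``target``,
    multiply by the Hamming window (and the per-timepoint drift
    weights, if given), inverse FT.  DC gain is 1: a constant volume
    keeps its value.  For real input the real part is returned after
    asserting that the imaginary residue is negligible.
    """
    target = tuple(target)
    if weights is not None:
        if tuple(weights.grid) != target:
            raise ValueError(
                f"weight field grid {weights.grid} does not match target {target}"
            )
        if weights.n_times != highres.n_times:
            raise ValueError("weight field timepoints do not match the series")
    win = hamming_filter(target, kind=window)
    real_input = not np.iscomplexobj(highres.volumes)
    out = np.empty((highres.n_times,) + target,
                   dtype=float if real_input else complex)
    for t in range(highres.n_times):
        wt = None if weights is None else weights.weights[..., t]
        low = _downsample_volume(highres.volumes[t], target, win, wt,
                                 hermitian=real_input)
        if real_input:
            scale = np.max(np.abs(low))
            if scale > 0 and np.max(np.abs(low.imag)) > imag_tol * scale:
                raise AssertionError(
                    "imaginary residue after inverse FT exceeds tolerance"
                )
            low = low.real
        out[t] = low
    vox = tuple(
        v * n_hi / n_lo
        for v, n_hi, n_lo in zip(highres.voxel_size_mm, highres.shape, target)
    )
    return ImageSeries(out, vox, highres.times_ms, mode=highres.mode)


def downsample_fractions(
    fractions: dict[str, np.ndarray],
    target: tuple[int, ...],
    voxel_size_mm: tuple[float, ...] = (1.0, 1.0, 1.0),
    window: str = "radial",
) -> dict[str, np.ndarray]:
    """Downsample tissue-fraction maps with the acquisition PSF.

    Same k-space pipeline as :func:`downsample_hamming`.  The
    low-resolution fractions are clipped to [0, 1] and, where Gibbs
    overshoot makes the clipped maps sum above 1, jointly renormalized
    so the total tissue fraction never exceeds 1.
    """
    out = {}
    for name, vol in fractions.items():
        series = ImageSeries(vol[None], voxel_size_mm, (0.0,))
        low = downsample_hamming(series, target, window=window)
        out[name] = np.clip(low.volumes[0], 0.0, 1.0)
    total = sum(out.values())
    excess = total > 1.0
    if np.any(excess):
        for name in out:
            out[name][excess] /= total[excess]
    return out
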