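"""Acquisition-order models for multi-delay MRSI encoding.

A relaxometry MRSI experiment acquires one k-space volume per inversion
time (IR) or echo time (SE).  When metabolite levels drift during the
scan, the order in which (k-point, timepoint) pairs are acquired turns
the drift into a k-space weighting of the data.  Two orderings are
modelled:

``reordered``
    All TI/TEs of one ring are acquired back-to-back before the radius
    increases ("inside-out" concentric-ring reordering).  Every k-point
    then carries the *same* drift weight across all timepoints, so the
    drift acts as a static, spherically symmetric apodization that
    cancels out of any per-voxel relaxation fit.

``consecutive``
    The full k-space is encoded once per TI/TE, timepoint after
    timepoint.  Each timepoint then sees a different global signal
    level, which biases the fitted relaxation times.

Weights are expressed relative to the start-of-scan level: a drift of
magnitude ``m`` scales the last-acquired sample by ``1 ± m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DriftModel",
    "AcquisitionOrder",
    "WeightField",
    "k_radius",
    "radial_rank",
    "acquisition_time_fraction",
    "drift_weights",
    "consecutive_level_vector",
    "scheme_weight_field",
    "hamming_filter",
    "crt_rings",
]


@dataclass(frozen=True)
class DriftModel:
    """Linear global signal-level drift over the experiment.

    ``direction`` is +1 for increasing and -1 for decreasing levels;
    ``magnitude`` is the fractional change reached at the end of the
    scan (default 0.35, i.e. a 35 % change).
    """

    direction: int
    magnitude: float = 0.35
    shape: str = "linear"

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")
        if not 0.0 <= self.magnitude < 1.0:
            raise ValueError(
                f"drift magnitude must lie in [0, 1), got {self.magnitude}"
            )
        if self.shape != "linear":
            raise ValueError(f"only linear drift is supported, got {self.shape!r}")


@dataclass(frozen=True)
class AcquisitionOrder:
    """Which encoding scheme and k-space traversal the scanner uses."""

    scheme: str  # "reordered" | "consecutive"
    traversal: str = "inside_out"
    ties: str = "average"  # radial-rank tie handling: "average" | "lexicographic"

    def __post_init__(self) -> None:
        if self.scheme not in ("reordered", "consecutive"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.traversal != "inside_out":
            raise ValueError(f"only inside_out traversal is supported")
        if self.ties not in ("average", "lexicographic"):
            raise ValueError(f"unknown tie rule {self.ties!r}")


@dataclass
class WeightField:
    """Multiplicative k-space weights, one scalar per (k-point, timepoint).

    ``weights`` has shape ``grid + (n_times,)``.  At zero drift all
    weights are exactly 1.
    """

    weights: np.ndarray
    grid: tuple[int, ...]
    n_times: int
    scheme: str = "none"
    direction: int = 0
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != tuple(self.grid) + (self.n_times,):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"grid {self.grid} x n_times {self.n_times}"
            )
        if np.any(self.weights <= 0):
            raise ValueError("all encoding weights must be positive")


def k_radius(grid: tuple[int, ...]) -> np.ndarray:
    """Normalized k-space radius on a centered Cartesian grid.

    Axis offsets run from ``-(n//2)`` to ``n - n//2 - 1`` (DC at index
    ``n//2``) and are normalized per axis by ``n//2``, so the radius is
    1 at the edge of the inscribed ellipsoid regardless of anisotropy.
    """
    axes = []
    for n in grid:
        if n < 1:
            raise ValueError("grid dimensions must be positive")
        half = max(n // 2, 1)
        axes.append((np.arange(n) - n // 2) / half)
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(a**2 for a in mesh))


def radial_rank(grid: tuple[int, ...], ties: str = "average") -> np.ndarray:
    """Inside-out acquisition rank of every k-point (0 .. N-1).

    Points are ordered by increasing normalized radius.  With
    ``ties="average"`` all points on one radius shell share the mean
    rank of the shell, which makes downstream reordered weight fields
    exactly spherically symmetric.  ``ties="lexicographic"`` breaks
    ties by (k0, k1, k2) offset order instead.
    """
    r = k_radius(grid)
    flat = r.ravel()
    if ties == "average":
        uniq, inverse, counts = np.unique(flat, return_inverse=True, return_counts=True)
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        avg = starts + (counts - 1) / 2.0
        ranks = avg[inverse]
    elif ties == "lexicographic":
        offs = np.meshgrid(*[np.arange(n) - n // 2 for n in grid], indexing="ij")
        keys = [o.ravel() for o in offs[::-1]]  # last key dominates in lexsort
        order = np.lexsort(tuple(keys) + (flat,))
        ranks = np.empty(flat.size)
        ranks[order] = np.arange(flat.size)
    else:
        raise ValueError(f"unknown tie rule {ties!r}")
    return ranks.reshape(grid)


def acquisition_time_fraction(
    grid: tuple[int, ...],
    order: AcquisitionOrder,
    n_times: int,
) -> np.ndarray:
    """Fraction of the experiment elapsed when each sample is acquired.

    Returns ``tau`` of shape ``grid + (n_times,)`` with values in
    [0, 1).  For the reordered scheme all timepoints of one k-point are
    acquired together, so ``tau`` is the radial rank fraction shared
    across timepoints.  For the consecutive scheme the grid is
    traversed inside-out once per timepoint and the timepoint blocks
    are concatenated: ``tau = (block * N + rank) / (n_times * N)``.
    """
    if n_times < 1:
        raise ValueError("n_times must be >= 1")
    rank = radial_rank(grid, ties=order.ties)
    n_points = rank.size
    if order.scheme == "reordered":
        tau = rank / n_points
        return np.repeat(tau[..., None], n_times, axis=-1)
    blocks = np.arange(n_times)
    tau = (blocks * n_points + rank[..., None]) / (n_times * n_points)
    return tau


def drift_weights(tau: np.ndarray, drift: DriftModel, **field_meta) -> WeightField:
    """Turn acquisition-time fractions into multiplicative weights.

    ``w = 1 + direction * magnitude * tau``: the signal level ramps
    linearly from 1 at the start of the scan to ``1 ± magnitude`` at
    its end.
    """
    tau = np.asarray(tau, dtype=float)
    w = 1.0 + drift.direction * drift.magnitude * tau
    meta = dict(
        grid=tuple(tau.shape[:-1]),
        n_times=tau.shape[-1],
        direction=drift.direction,
        magnitude=drift.magnitude,
    )
    meta.update(field_meta)
    return WeightField(weights=w, **meta)


def consecutive_level_vector(n_times: int, drift: DriftModel) -> np.ndarray:
    """Per-timepoint signal levels for block-wise consecutive encoding.

    Each TI/TE block is assigned one scalar level, linear in block
    index and reaching the full ``1 ± magnitude`` at the last
    timepoint.  This models a drift slow enough to be constant within
    one block but spanning the stated fractional change over the
    experiment.
    """
    if n_times < 1:
        raise ValueError("n_times must be >= 1")
    if n_times == 1:
        return np.ones(1)
    tau = np.arange(n_times) / (n_times - 1)
    return 1.0 + drift.direction * drift.magnitude * tau


def scheme_weight_field(
    grid: tuple[int, ...],
    n_times: int,
    scheme: str,
    drift: DriftModel | None,
    consecutive_mode: str = "vector",
    ties: str = "average",
) -> WeightField:
    """Build the full drift weight field for an encoding scheme.

    ``scheme`` is ``"gold_standard"`` (no drift; all weights 1),
    ``"reordered"`` or ``"consecutive"``.  For the consecutive scheme
    two drift models are available: ``consecutive_mode="vector"``
    weights every k-point of timepoint *b* by the same scalar from
    :func:`consecutive_level_vector` (default), while ``"ramp"``
    additionally ramps the weight inside each block following the
    inside-out traversal (:func:`acquisition_time_fraction`).
    """
    grid = tuple(grid)
    if scheme == "gold_standard" or drift is None or drift.magnitude == 0.0:
        w = np.ones(grid + (n_times,))
        return WeightField(w, grid, n_times, scheme="gold_standard")
    order = AcquisitionOrder(
        scheme="reordered" if scheme == "reordered" else "consecutive", ties=ties
    )
    if scheme == "reordered":
        tau = acquisition_time_fraction(grid, order, n_times)
        return drift_weights(tau, drift, scheme="reordered")
    if scheme != "consecutive":
        raise ValueError(f"unknown scheme {scheme!r}")
    if consecutive_mode == "ramp":
        tau = acquisition_time_fraction(grid, order, n_times)
        return drift_weights(tau, drift, scheme="consecutive")
    if consecutive_mode != "vector":
        raise ValueError(f"unknown consecutive_mode {consecutive_mode!r}")
    levels = consecutive_level_vector(n_times, drift)
    w = np.broadcast_to(levels, grid + (n_times,)).copy()
    return WeightField(
        w, grid, n_times, scheme="consecutive",
        direction=drift.direction, magnitude=drift.magnitude,
    )


def hamming_filter(grid: tuple[int, ...], kind: str = "radial") -> np.ndarray:
    """Hamming apodization window on a centered k-space grid.

    ``kind="radial"``: w(r) = 0.54 + 0.46 cos(pi r) for normalized
    radius r <= 1 and 0 beyond, matching the spherical coverage of a
    Hamming-weighted concentric-ring readout.  ``kind="separable"``:
    tensor product of per-axis 1D Hamming windows.  Exactly 1 at k = 0.
    """
    if kind == "radial":
        r = k_radius(grid)
        w = 0.54 + 0.46 * np.cos(np.pi * np.minimum(r, 1.0))
        w[r > 1.0] = 0.0
        return w
    if kind == "separable":
        w = np.ones(grid)
        for ax, n in enumerate(grid):
            half = max(n // 2, 1)
            x = np.abs(np.arange(n) - n // 2) / half
            w1 = 0.54 + 0.46 * np.cos(np.pi * np.minimum(x, 1.0))
            shape = [1] * len(grid)
            shape[ax] = n
            w = w * w1.reshape(shape)
        return w
    raise ValueError(f"unknown window kind {kind!r}")


def crt_rings(matrix: int, fov_mm: float) -> list[np.ndarray]:
    """Concentric-ring k-space trajectory in the kx-ky plane.

    Rings are spaced by the Cartesian grid step ``dk = 1/FOV`` starting
    from the innermost ring, with enough points per ring to satisfy
    Nyquist along the circumference (arc spacing <= dk).  Returns one
    (n_points, 2) array of (kx, ky) in cycles/mm per ring, innermost
    first.
    """
    if matrix < 2:
        raise ValueError("matrix must be >= 2")
    if fov_mm <= 0:
        raise ValueError("fov_mm must be positive")
    dk = 1.0 / fov_mm
    rings = []
    for i in range(matrix // 2):
        radius = (i + 0.5) * dk
        n_pts = max(8, int(np.ceil(2 * np.pi * radius / dk)))
        phi = 2 * np.pi * np.arange(n_pts) / n_pts
        rings.append(np.column_stack([radius * np.cos(phi), radius * np.sin(phi)]))
    return rings
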