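"""Synthetic two-compartment brain phantom for ²H-MRSI relaxometry.

The phantom mimics the standard digital ground truth used to study
acquisition-ordering effects: a high-resolution volume partitioned
into synthetic gray matter (sGM, outer shell) and white matter (sWM,
inner core) with distinct T1/T2, from which noiseless signal series
over a set of inversion or echo times are generated.  Fractions are
binary at full resolution; partial-volume mixing arises only from the
later k-space downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recon import ImageSeries

__all__ = [
    "CompartmentParams",
    "TissuePhantom",
    "RelaxationSchedule",
    "SpectralConfig",
    "SpectralImageSeries",
    "make_two_compartment",
    "signal_series",
    "spectral_series",
    "relaxation_factor",
]

# default compartment parameters of the simulated brain (ms)
SGM = None  # populated below, after CompartmentParams is defined
SWM = None


@dataclass(frozen=True)
class CompartmentParams:
    """Relaxation and signal parameters of one tissue compartment."""

    name: str
    t1_ms: float
    t2_ms: float
    amplitude: float = 1.0
    freq_offset_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError(f"{self.name}: relaxation times must be positive")
        if self.amplitude < 0:
            raise ValueError(f"{self.name}: amplitude must be >= 0")


SGM = CompartmentParams("sGM", t1_ms=350.0, t2_ms=35.0)
SWM = CompartmentParams("sWM", t1_ms=310.0, t2_ms=25.0)


@dataclass
class TissuePhantom:
    """Tissue-fraction volumes plus per-compartment parameters."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    fractions: dict[str, np.ndarray]
    compartments: list[CompartmentParams]

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compartment names")
        if set(names) != set(self.fractions):
            raise ValueError("fraction maps and compartments do not match")
        total = np.zeros(self.shape)
        for name, f in self.fractions.items():
            f = np.asarray(f, dtype=float)
            if f.shape != self.shape:
                raise ValueError(f"fraction map {name!r} has shape {f.shape}, "
                                 f"expected {self.shape}")
            if np.any(f < 0) or np.any(f > 1):
                raise ValueError(f"fraction map {name!r} outside [0, 1]")
            self.fractions[name] = f
            total += f
        if np.any(total > 1.0 + 1e-9):
            raise ValueError("fractions sum to more than 1 at some voxels")

    def compartment(self, name: str) -> CompartmentParams:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    def scaled(self, factor: float) -> "TissuePhantom":
        """Phantom with all compartment amplitudes multiplied by ``factor``."""
        comps = [
            CompartmentParams(c.name, c.t1_ms, c.t2_ms, c.amplitude * factor,
                              c.freq_offset_hz)
            for c in self.compartments
        ]
        return TissuePhantom(self.shape, self.voxel_size_mm,
                             dict(self.fractions), comps)


@dataclass(frozen=True)
class RelaxationSchedule:
    """Experiment design: IR or SE mode and its delay list."""

    mode: str  # "IR" | "SE"
    times_ms: tuple[float, ...]
    tr_ms: float = 500.0
    inversion_efficiency: float = 2.0  # C2 used in simulation; 2 = perfect

    def __post_init__(self) -> None:
        if self.mode not in ("IR", "SE"):
            raise ValueError(f"mode must be 'IR' or 'SE', got {self.mode!r}")
        t = tuple(float(x) for x in self.times_ms)
        if len(t) < 1 or any(x <= 0 for x in t):
            raise ValueError("times_ms must be positive")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times_ms must be strictly increasing")
        object.__setattr__(self, "times_ms", t)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    semiaxes: tuple[float, float, float],
    center: tuple[float, float, float],
) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, a, c in zip(grids, semiaxes, center))
    return q <= 1.0


def make_two_compartment(
    shape: tuple[int, int, int],
    geometry: dict | None = None,
    params: tuple[CompartmentParams, CompartmentParams] = (SGM, SWM),
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TissuePhantom:
    """Build the default concentric-ellipsoid two-compartment phantom.

    ``params`` is (shell compartment, core compartment); by default the
    shell is sGM and the core sWM, reproducing the gray-matter-
    surrounds-white-matter partial-volume structure at the boundary.

    ``geometry`` keys (all optional):

    - ``outer_frac``: outer ellipsoid semi-axes as a fraction of the
      half grid extent per axis (default 0.9);
    - ``core_scale``: core semi-axes relative to the outer (default
      0.7, giving the core ~34 % of the brain volume);
    - ``kind="masks"`` with ``masks=(shell, core)``: explicit boolean
      volumes (must be disjoint).
    """
    shape = tuple(int(n) for n in shape)
    if any(n < 1 for n in shape):
        raise ValueError("shape must be positive")
    geometry = dict(geometry or {})
    shell_params, core_params = params

    if geometry.get("kind") == "masks":
        shell_mask, core_mask = (np.asarray(m, dtype=bool)
                                 for m in geometry["masks"])
        if shell_mask.shape != shape or core_mask.shape != shape:
            raise ValueError("explicit masks do not match shape")
        if np.any(shell_mask & core_mask):
            raise ValueError("compartment regions overlap")
    else:
        outer_frac = geometry.get("outer_frac", 0.9)
        core_scale = geometry.get("core_scale", 0.7)
        if isinstance(outer_frac, (int, float)):
            outer_frac = (outer_frac,) * 3
        center = tuple((n - 1) / 2.0 for n in shape)
        outer_ax = tuple(f * (n - 1) / 2.0 for f, n in zip(outer_frac, shape))
        core_ax = tuple(core_scale * a for a in outer_ax)
        outer = _ellipsoid_mask(shape, outer_ax, center)
        core = _ellipsoid_mask(shape, core_ax, center) if core_scale > 0 \
            else np.zeros(shape, dtype=bool)
        shell_mask = outer & ~core
        core_mask = core

    for mask, p in ((shell_mask, shell_params), (core_mask, core_params)):
        if not mask.any():
            raise ValueError(f"empty compartment {p.name!r} after rasterization")

    fractions = {
        shell_params.name: shell_mask.astype(float),
        core_params.name: core_mask.astype(float),
    }
    return TissuePhantom(shape, tuple(voxel_size_mm), fractions,
                         [shell_params, core_params])


def relaxation_factor(
    params: CompartmentParams, schedule: RelaxationSchedule
) -> np.ndarray:
    """Noiseless relaxation modulation m_c(t) of one compartment.

    IR: ``m(TI) = 1 - C2 exp(-TI/T1)`` (signed recovery after
    inversion with efficiency C2); SE: ``m(TE) = exp(-TE/T2)``.
    """
    t = np.asarray(schedule.times_ms, dtype=float)
    if schedule.mode == "IR":
        return 1.0 - schedule.inversion_efficiency * np.exp(-t / params.t1_ms)
    return np.exp(-t / params.t2_ms)


def signal_series(
    phantom: TissuePhantom, schedule: RelaxationSchedule
) -> ImageSeries:
    """Noiseless high-resolution signal volume per scheduled TI/TE.

    Voxel value at time t: sum over compartments of
    ``fraction * amplitude * m_c(t)``.
    """
    n_t = len(schedule.times_ms)
    out = np.zeros((n_t,) + phantom.shape)
    for comp in phantom.compartments:
        m = relaxation_factor(comp, schedule)
        frac = phantom.fractions[comp.name]
        out += m[:, None, None, None] * (comp.amplitude * frac)[None]
    return ImageSeries(out, phantom.voxel_size_mm, schedule.times_ms,
                       mode=schedule.mode)


@dataclass(frozen=True)
class SpectralConfig:
    """Spectral sampling of the simulated FIDs."""

    points: int = 96
    bandwidth_hz: float = 5000.0
    t2_star_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.points < 2:
            raise ValueError("at least 2 spectral points required")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth must be positive")
        if self.t2_star_ms <= 0:
            raise ValueError("T2* must be positive")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.bandwidth_hz


@dataclass
class SpectralImageSeries:
    """Complex FID per voxel and timepoint: shape (n_times,) + grid + (points,)."""

    fids: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    times_ms: tuple[float, ...]
    mode: str
    spectral: SpectralConfig

    def __post_init__(self) -> None:
        self.fids = np.asarray(self.fids, dtype=complex)
        if self.fids.shape[0] != len(self.times_ms):
            raise ValueError("timepoint count mismatch")
        if self.fids.shape[-1] != self.spectral.points:
            raise ValueError("spectral point count mismatch")


def spectral_series(
    phantom: TissuePhantom,
    schedule: RelaxationSchedule,
    spectral: SpectralConfig,
) -> SpectralImageSeries:
    """Per-voxel FIDs with per-compartment resonance offsets.

    Each compartment contributes
    ``fraction * amplitude * m_c(t) * exp(2i pi f_c tau - tau/T2*)``
    sampled at the spectral dwell time; for a single on-resonance
    compartment the tau = 0 amplitude equals the ``signal_series``
    value.  Memory scales with grid x points - intended for small
    (already downsampled) grids.
    """
    tau = np.arange(spectral.points) * spectral.dwell_s
    n_t = len(schedule.times_ms)
    out = np.zeros((n_t,) + phantom.shape + (spectral.points,), dtype=complex)
    t2s = spectral.t2_star_ms / 1000.0
    for comp in phantom.compartments:
        m = relaxation_factor(comp, schedule)
        decay = np.exp((2j * np.pi * comp.freq_offset_hz - 1.0 / t2s) * tau)
        spatial = comp.amplitude * phantom.fractions[comp.name]
        out += (
            m[:, None, None, None, None]
            * spatial[None, ..., None]
            * decay[None, None, None, None, :]
        )
    return SpectralImageSeries(out, phantom.voxel_size_mm, schedule.times_ms,
                               schedule.mode, spectral)
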