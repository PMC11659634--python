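"""File formats: NIfTI volumes, HDF5 series containers, CSV/JSON tables.

Layout of the HDF5 container:

- ``/images/t{i}``            one volume per timepoint, attrs ``mode``,
                              ``times_ms``, ``voxel_size_mm`` on ``/images``
- ``/encoding/weights``       drift weight field, attrs ``scheme``,
                              ``direction``, ``magnitude``
- ``/encoding/coords``        non-Cartesian k-space coordinates
- ``/spectra/region/{label}`` region-averaged spectra, attrs ``times_ms``,
                              ``n_voxels``
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .encoding import WeightField
from .phantom import CompartmentParams, TissuePhantom
from .recon import ImageSeries, KSpaceSeries
from .spectra import AmplitudeSeries, RegionSpectrumSeries

__all__ = [
    "save_volume_nifti",
    "load_volume_nifti",
    "save_phantom",
    "load_phantom",
    "save_image_series_nifti",
    "save_image_series_h5",
    "load_image_series_h5",
    "save_weight_field_h5",
    "load_weight_field_h5",
    "save_kspace_series_h5",
    "load_kspace_series_h5",
    "save_region_spectra_h5",
    "load_region_spectra_h5",
    "amplitude_series_to_csv",
    "load_config_file",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def save_volume_nifti(volume: np.ndarray, voxel_size_mm, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32),
                          _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_volume_nifti(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), vox


def save_phantom(phantom: TissuePhantom, directory) -> None:
    """One NIfTI per compartment fraction plus a JSON parameter block."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, frac in phantom.fractions.items():
        save_volume_nifti(frac, phantom.voxel_size_mm,
                          directory / f"fraction_{name}.nii.gz")
    params = {
        "shape": list(phantom.shape),
        "voxel_size_mm": list(phantom.voxel_size_mm),
        "compartments": [vars(c) for c in phantom.compartments],
    }
    (directory / "phantom.json").write_text(json.dumps(params, indent=2))


def load_phantom(directory) -> TissuePhantom:
    directory = Path(directory)
    params = json.loads((directory / "phantom.json").read_text())
    comps = [CompartmentParams(**c) for c in params["compartments"]]
    fractions = {}
    for c in comps:
        vol, _ = load_volume_nifti(directory / f"fraction_{c.name}.nii.gz")
        fractions[c.name] = vol
    return TissuePhantom(tuple(params["shape"]),
                         tuple(params["voxel_size_mm"]), fractions, comps)


def save_image_series_nifti(series: ImageSeries, directory, prefix="vol") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(series.n_times):
        save_volume_nifti(series.volumes[i].real, series.voxel_size_mm,
                          directory / f"{prefix}_t{i}.nii.gz")


def save_image_series_h5(series: ImageSeries, path) -> None:
    with h5py.File(str(path), "w") as fh:
        grp = fh.create_group("images")
        grp.attrs["mode"] = series.mode
        grp.attrs["times_ms"] = np.asarray(series.times_ms)
        grp.attrs["voxel_size_mm"] = np.asarray(series.voxel_size_mm)
        for i in range(series.n_times):
            grp.create_dataset(f"t{i}", data=series.volumes[i])


def load_image_series_h5(path) -> ImageSeries:
    with h5py.File(str(path), "r") as fh:
        grp = fh["images"]
        times = tuple(float(t) for t in grp.attrs["times_ms"])
        vox = tuple(float(v) for v in grp.attrs["voxel_size_mm"])
        mode = str(grp.attrs["mode"])
        vols = np.stack([grp[f"t{i}"][()] for i in range(len(times))])
    return ImageSeries(vols, vox, times, mode=mode)


def save_weight_field_h5(field: WeightField, path) -> None:
    with h5py.File(str(path), "a") as fh:
        if "encoding/weights" in fh:
            del fh["encoding/weights"]
        ds = fh.create_dataset("encoding/weights", data=field.weights)
        ds.attrs["scheme"] = field.scheme
        ds.attrs["direction"] = field.direction
        ds.attrs["magnitude"] = field.magnitude


def load_weight_field_h5(path) -> WeightField:
    with h5py.File(str(path), "r") as fh:
        ds = fh["encoding/weights"]
        w = ds[()]
        return WeightField(
            weights=w, grid=w.shape[:-1], n_times=w.shape[-1],
            scheme=str(ds.attrs["scheme"]),
            direction=int(ds.attrs["direction"]),
            magnitude=float(ds.attrs["magnitude"]),
        )


def save_kspace_series_h5(series: KSpaceSeries, path) -> None:
    with h5py.File(str(path), "a") as fh:
        for key in ("encoding/coords", "encoding/samples"):
            if key in fh:
                del fh[key]
        fh.create_dataset("encoding/coords", data=series.coords)
        ds = fh.create_dataset("encoding/samples", data=series.samples)
        ds.attrs["times_ms"] = np.asarray(series.times_ms)
        for k, v in series.grid_meta.items():
            ds.attrs[k] = v


def load_kspace_series_h5(path) -> KSpaceSeries:
    with h5py.File(str(path), "r") as fh:
        coords = fh["encoding/coords"][()]
        ds = fh["encoding/samples"]
        samples = ds[()]
        times = tuple(float(t) for t in ds.attrs.get("times_ms", ()))
        meta = {k: v for k, v in ds.attrs.items() if k != "times_ms"}
    return KSpaceSeries(samples, coords, grid_meta=meta, times_ms=times)


def save_region_spectra_h5(series: RegionSpectrumSeries, path) -> None:
    with h5py.File(str(path), "a") as fh:
        key = f"spectra/region/{series.region}"
        if key in fh:
            del fh[key]
        ds = fh.create_dataset(key, data=series.spectra)
        ds.attrs["times_ms"] = np.asarray(series.times_ms)
        ds.attrs["n_voxels"] = series.n_voxels


def load_region_spectra_h5(path, region: str) -> RegionSpectrumSeries:
    with h5py.File(str(path), "r") as fh:
        ds = fh[f"spectra/region/{region}"]
        return RegionSpectrumSeries(
            region=region,
            times_ms=tuple(float(t) for t in ds.attrs["times_ms"]),
            spectra=ds[()],
            n_voxels=int(ds.attrs["n_voxels"]),
        )


def amplitude_series_to_csv(series_list, path) -> pd.DataFrame:
    """Fitted amplitudes to long-format CSV.

    Columns: region, time_ms, resonance, amplitude, crlb_percent,
    snr, fwhm_hz.
    """
    rows = []
    for series in series_list:
        for name, amps in series.amplitudes.items():
            for i, t in enumerate(series.times_ms):
                rows.append({
                    "region": series.region,
                    "time_ms": t,
                    "resonance": name,
                    "amplitude": amps[i],
                    "crlb_percent": series.crlb_percent[name][i],
                    "snr": (series.snr[i] if series.snr is not None
                            else np.nan),
                    "fwhm_hz": (series.fwhm_hz[name][i]
                                if series.fwhm_hz else np.nan),
                })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def load_config_file(path) -> dict:
    """Read a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
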