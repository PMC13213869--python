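"""File I/O: raw-data HDF5 container, NIfTI volumes, JSON reports.

Raw acquisitions are stored in an ISMRMRD-style HDF5 layout written with
h5py: a ``/dataset`` group holding the complex readouts, per-acquisition
timing and encoding indices (kz partition, rotation angle, navigator
flag), the k-space trajectory of the base spiral, and ECG trigger
annotations; simulation ground truth lives in a ``/ground_truth`` sidecar
group.  Images and deformation fields are written as NIfTI so any viewer
or registration QA tool can read them.
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np

from cineimoco.phantom import RawAcquisition
from cineimoco.trajectory import SamplingSchedule, SpiralReadout

__all__ = ["save_raw", "load_raw", "save_nifti", "load_nifti", "save_report"]


def save_raw(path, raw: RawAcquisition) -> None:
    """Write a :class:`RawAcquisition` to an ISMRMRD-style HDF5 file."""
    with h5py.File(path, "w") as f:
        ds = f.create_group("dataset")
        ds.create_dataset("data", data=raw.readouts.astype(np.complex128),
                          compression="gzip", compression_opts=1)
        ds.create_dataset("timestamps_ms", data=raw.timestamps)
        ds.create_dataset("kz_index", data=raw.schedule.kz_index)
        ds.create_dataset("angle_index", data=raw.schedule.angle_index)
        ds.create_dataset("is_dc_navigator",
                          data=raw.schedule.is_dc_navigator.astype(np.uint8))
        ds.create_dataset("ecg_triggers_ms", data=raw.ecg_triggers)
        ds.attrs.update({
            "tr_ms": raw.schedule.tr,
            "n_partitions": raw.schedule.n_partitions,
            "n_angles": raw.schedule.n_angles,
            "scheme": raw.schedule.scheme,
            "rotation_increment_deg": raw.schedule.rotation_increment_deg,
            "n_channels": raw.n_channels,
            "grid_shape": raw.grid_shape,
            "seed": -1 if raw.seed is None else raw.seed,
        })
        tr = f.create_group("trajectory")
        tr.create_dataset("k_coords", data=raw.spiral.k_coords)
        tr.create_dataset("gradient_waveform", data=raw.spiral.gradient_waveform)
        tr.attrs.update({
            "dwell_time_ms": raw.spiral.dwell_time,
            "readout_duration_ms": raw.spiral.readout_duration,
            "k_max": raw.spiral.k_max,
            "fov_mm": raw.spiral.fov_mm,
            "n_interleaves": raw.spiral.n_interleaves,
        })
        if raw.ground_truth:
            gt = f.create_group("ground_truth")
            for key, val in raw.ground_truth.items():
                gt.create_dataset(key, data=np.asarray(val))


def load_raw(path) -> RawAcquisition:
    """Read a raw acquisition written by :func:`save_raw`."""
    with h5py.File(path, "r") as f:
        ds = f["dataset"]
        data = ds["data"][:].astype(complex)
        times = ds["timestamps_ms"][:]
        schedule = SamplingSchedule(
            times=times,
            kz_index=ds["kz_index"][:].astype(int),
            angle_index=ds["angle_index"][:].astype(int),
            is_dc_navigator=ds["is_dc_navigator"][:].astype(bool),
            tr=float(ds.attrs["tr_ms"]),
            n_partitions=int(ds.attrs["n_partitions"]),
            n_angles=int(ds.attrs["n_angles"]),
            scheme=str(ds.attrs["scheme"]),
            rotation_increment_deg=float(ds.attrs["rotation_increment_deg"]),
        )
        tr = f["trajectory"]
        k = tr["k_coords"][:]
        spiral = SpiralReadout(
            n_samples=k.shape[0],
            dwell_time=float(tr.attrs["dwell_time_ms"]),
            k_coords=k,
            gradient_waveform=tr["gradient_waveform"][:],
            readout_duration=float(tr.attrs["readout_duration_ms"]),
            k_max=float(tr.attrs["k_max"]),
            fov_mm=float(tr.attrs["fov_mm"]),
            n_interleaves=int(tr.attrs["n_interleaves"]),
        )
        gt = {}
        if "ground_truth" in f:
            gt = {key: f["ground_truth"][key][:] for key in f["ground_truth"]}
        seed = int(ds.attrs["seed"])
        return RawAcquisition(
            readouts=data,
            timestamps=times,
            schedule=schedule,
            spiral=spiral,
            ecg_triggers=ds["ecg_triggers_ms"][:],
            n_channels=int(ds.attrs["n_channels"]),
            grid_shape=tuple(int(v) for v in ds.attrs["grid_shape"]),
            ground_truth=gt,
            seed=None if seed < 0 else seed,
        )


def save_nifti(path, volume: np.ndarray, voxel_mm=(1.0, 1.0, 1.0)) -> None:
    """Write a (possibly 4D) volume as NIfTI; complex data saved as magnitude.

    The 4th dimension holds cardiac phases or respiratory states.
    """
    arr = np.asarray(volume)
    if np.iscomplexobj(arr):
        arr = np.abs(arr)
    if arr.ndim == 4:  # (t, x, y, z) -> (x, y, z, t)
        arr = np.moveaxis(arr, 0, -1)
    affine = np.diag(list(voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))


def load_nifti(path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim == 4:
        arr = np.moveaxis(arr, -1, 0)
    return arr


def save_report(path, report: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
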