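"""File formats: HDF5 containers, NIfTI export, YAML phantom specs.

The HDF5 containers are lossless (complex datasets); NIfTI export stores the
magnitude as float32 N x N x 1 x T for interoperability with viewers.
"""

from __future__ import annotations

import h5py
import nibabel as nib
import numpy as np
import yaml

from .encoding import CoilMaps, RadialKSpace, RadialTrajectory
from .phantom import Ellipse, PhantomGeometry, Rectangle, TissueClass

__all__ = [
    "save_series",
    "load_series",
    "save_kspace",
    "load_kspace",
    "series_to_nifti",
    "nifti_to_magnitude",
    "load_phantom_yaml",
    "convert_spoke_major",
]


def save_series(path, series) -> None:
    """Write a DynamicSeries to an HDF5 container (lossless complex)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.asarray(series.data, dtype=np.complex128))
        f.create_dataset("frame_times", data=series.frame_times)
        f.attrs["N"] = series.N


def load_series(path):
    from .phantom import DynamicSeries

    with h5py.File(path, "r") as f:
        return DynamicSeries(data=f["data"][()], frame_times=f["frame_times"][()], N=int(f.attrs["N"]))


def save_kspace(path, y: RadialKSpace, coils: CoilMaps | None = None) -> None:
    """Write a RadialKSpace container: /samples, /angles, /frame_of_spoke, ..."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=np.asarray(y.samples, dtype=np.complex128))
        f.create_dataset("angles", data=y.trajectory.angles)
        f.create_dataset("coords", data=y.trajectory.kcoords)
        f.create_dataset("frame_of_spoke", data=y.frame_of_spoke)
        if y.spoke_times is not None:
            f.create_dataset("spoke_times", data=y.spoke_times)
        if coils is not None:
            f.create_dataset("coilmaps", data=coils.maps)
        f.attrs["n_samples"] = y.trajectory.n_samples
        f.attrs["n_frames"] = y.n_frames
        f.attrs["dense_frames"] = np.asarray(y.dense_frames, dtype=int)


def load_kspace(path) -> tuple[RadialKSpace, CoilMaps | None]:
    with h5py.File(path, "r") as f:
        n_samples = int(f.attrs["n_samples"])
        angles = f["angles"][()]
        coords = f["coords"][()] if "coords" in f else None
        traj = RadialTrajectory(angles, n_samples, coords_override=coords)
        y = RadialKSpace(
            samples=f["samples"][()],
            trajectory=traj,
            frame_of_spoke=f["frame_of_spoke"][()],
            n_frames=int(f.attrs["n_frames"]),
            spoke_times=f["spoke_times"][()] if "spoke_times" in f else None,
            dense_frames=tuple(int(i) for i in f.attrs.get("dense_frames", ())),
        )
        coils = CoilMaps(f["coilmaps"][()]) if "coilmaps" in f else None
    return y, coils


def series_to_nifti(path, series) -> None:
    """Export magnitude images as an N x N x 1 x T float32 NIfTI volume."""
    vol = np.abs(series.frames()).astype(np.float32)[:, :, None, :]
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(np.mean(np.diff(series.frame_times))) if series.n_frames > 1 else 1.0))
    nib.save(img, str(path))


def nifti_to_magnitude(path) -> np.ndarray:
    """Read back an exported magnitude volume as (N, N, T) float32."""
    vol = np.asanyarray(nib.load(str(path)).dataobj)
    return vol[:, :, 0, :]


def convert_spoke_major(kdata: np.ndarray, angles: np.ndarray, spoke_times=None, dense_frames=()) -> RadialKSpace:
    """Ingest spoke-major radial data (n_samples x spokes x coils) at 1 spoke/frame.

    This is the layout used by the public golden-angle radial demo datasets.
    """
    kdata = np.asarray(kdata)
    if kdata.ndim == 2:
        kdata = kdata[:, :, None]
    samples = kdata.transpose(1, 0, 2)  # -> (spokes, n_samples, coils)
    S = samples.shape[0]
    return RadialKSpace(
        samples=samples,
        trajectory=RadialTrajectory(np.asarray(angles) % np.pi, kdata.shape[0]),
        frame_of_spoke=np.arange(S),
        n_frames=S,
        spoke_times=spoke_times,
        dense_frames=tuple(dense_frames),
    )


def _shape_from_dict(d: dict):
    kind = d.get("shape", "ellipse")
    if kind == "ellipse":
        return Ellipse(cx=float(d["cx"]), cy=float(d["cy"]), rx=float(d["rx"]), ry=float(d["ry"]))
    if kind == "rectangle":
        return Rectangle(x0=float(d["x0"]), y0=float(d["y0"]), x1=float(d["x1"]), y1=float(d["y1"]))
    raise ValueError(f"unknown shape kind {kind!r}")


def load_phantom_yaml(path) -> PhantomGeometry:
    """Read a phantom geometry spec.

    Schema::

        N: 64
        background: {T1: 1.0}          # or random_background: true
        classes:
          - label: 1
            T1: 1.4
            Ktrans: 0.2                # 1/min
            ve: 0.3
            vp: 0.05
            M0: 1.0
            geometry: {shape: ellipse, cx: 32, cy: 32, rx: 20, ry: 14}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    regions = []
    for cd in doc.get("classes", []):
        tc = TissueClass(
            label=int(cd["label"]),
            T1=float(cd["T1"]),
            Ktrans=float(cd.get("Ktrans", 0.0)),
            ve=float(cd.get("ve", 0.0)),
            vp=float(cd.get("vp", 0.0)),
            M0=float(cd.get("M0", 1.0)),
        )
        regions.append((_shape_from_dict(cd["geometry"]), tc))
    bg = None
    if isinstance(doc.get("background"), dict):
        bd = doc["background"]
        bg = TissueClass(
            label=int(bd.get("label", 0)),
            T1=float(bd.get("T1", 1.0)),
            Ktrans=float(bd.get("Ktrans", 0.0)),
            ve=float(bd.get("ve", 0.0)),
            vp=float(bd.get("vp", 0.0)),
            M0=float(bd.get("M0", 1.0)),
        )
    return PhantomGeometry(
        N=int(doc["N"]),
        regions=tuple(regions),
        background=bg,
        random_background=bool(doc.get("random_background", False)),
    )
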