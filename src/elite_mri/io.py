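"""File formats: HDF5 phantom/k-space bundles, NIfTI image series, CSV
tables and JSON metric reports.

HDF5 keeps the simulation inputs and raw data self-describing (arrays plus
attributes such as seeds and scan timing); reconstructed series go to NIfTI
with the frame spacing recorded in the header so standard viewers animate
them correctly, with an optional HDF5 sidecar for bases, coefficients and the
objective trace.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .encoding import MultiCoilKSpace, RadialTrajectory, density_compensation
from .metrics import MetricsReport
from .phantom import (
    CoilSensitivities,
    DROPhantom,
    TissueKinetics,
    TissueParams,
)
from .pkm import AIF, PKMParams
from .regions import partition_from_labels
from .series import DynamicImageSeries

__all__ = [
    "save_phantom",
    "load_phantom",
    "save_kspace",
    "load_kspace",
    "save_series_nifti",
    "load_series_nifti",
    "save_recon_sidecar",
    "load_recon_sidecar",
    "save_aif_csv",
    "load_aif_csv",
    "save_bootstrap_csv",
    "save_metrics_json",
    "load_metrics_json",
]


# ---------------------------------------------------------------------------
# phantom bundle
# ---------------------------------------------------------------------------

_TISSUE_FIELDS = ("baseline", "amplitude", "rise_time")
_PKM_FIELDS = ("ve", "vp", "fp", "ps")


def save_phantom(path, phantom: DROPhantom) -> None:
    """Write a phantom bundle: label map, coil maps, time grid, kinetics."""
    part = phantom.partition
    if part.is_blocks:
        raise ValueError("phantom partitions must be label maps")
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=part.label_map.astype(np.int16))
        f.create_dataset("coils", data=phantom.coils.maps.astype(np.complex64))
        f.create_dataset("time_grid", data=phantom.time_grid.astype(np.float64))
        f.attrs["region_names"] = [n.encode() for n in part.region_names]
        f.attrs["seed"] = int(phantom.seed)
        f.attrs["heterogeneity"] = float(phantom.heterogeneity)
        kin = f.create_group("kinetics")
        for name, par in phantom.kinetics.tissues.items():
            g = kin.create_group(name)
            for fld in _TISSUE_FIELDS:
                g.attrs[fld] = float(getattr(par, fld))
            if par.pkm is not None:
                for fld in _PKM_FIELDS:
                    g.attrs[fld] = float(getattr(par.pkm, fld))


def load_phantom(path) -> DROPhantom:
    with h5py.File(path, "r") as f:
        labels = f["labels"][()]
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in f.attrs["region_names"]
        ]
        coils = CoilSensitivities(f["coils"][()].astype(np.complex128))
        time_grid = f["time_grid"][()]
        seed = int(f.attrs["seed"])
        het = float(f.attrs["heterogeneity"])
        tissues = {}
        for name in f["kinetics"]:
            g = f["kinetics"][name]
            pkm = None
            if "ve" in g.attrs:
                pkm = PKMParams(*(float(g.attrs[fld]) for fld in _PKM_FIELDS))
            tissues[name] = TissueParams(
                *(float(g.attrs[fld]) for fld in _TISSUE_FIELDS), pkm=pkm
            )
    return DROPhantom(
        partition=partition_from_labels(labels, names),
        kinetics=TissueKinetics(tissues),
        coils=coils,
        time_grid=time_grid,
        heterogeneity=het,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# k-space bundle
# ---------------------------------------------------------------------------

def save_kspace(path, ksp: MultiCoilKSpace, scan_time: float = None,
                seed: int = None) -> None:
    """Write radial k-space: samples, spoke angles, frame assignment, weights."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=ksp.data.astype(np.complex64))
        f.create_dataset("angles", data=ksp.trajectory.angles.astype(np.float64))
        f.create_dataset("radii", data=ksp.trajectory.radii.astype(np.float64))
        f.create_dataset("frame_of_spoke", data=ksp.frame_of_spoke.astype(np.int32))
        f.create_dataset("weights", data=ksp.density_weights.astype(np.float32))
        if scan_time is not None:
            f.attrs["scan_time_s"] = float(scan_time)
        if seed is not None:
            f.attrs["seed"] = int(seed)


def load_kspace(path) -> tuple:
    """Read a k-space bundle; returns (MultiCoilKSpace, attrs dict).

    If the weights dataset is absent they are recomputed from the trajectory.
    """
    with h5py.File(path, "r") as f:
        data = f["kspace"][()].astype(np.complex128)
        angles = f["angles"][()]
        radii = f["radii"][()]
        frame_of_spoke = f["frame_of_spoke"][()]
        weights = f["weights"][()].astype(np.float64) if "weights" in f else None
        attrs = dict(f.attrs)
    ky = radii[None, :] * np.sin(angles)[:, None]
    kx = radii[None, :] * np.cos(angles)[:, None]
    traj = RadialTrajectory(
        angles=angles, coords=np.stack([ky, kx], axis=-1), radii=radii
    )
    if weights is None:
        weights = density_compensation(traj)
    return (
        MultiCoilKSpace(
            data=data, trajectory=traj, frame_of_spoke=frame_of_spoke,
            density_weights=weights,
        ),
        attrs,
    )


# ---------------------------------------------------------------------------
# image series (NIfTI) and reconstruction sidecar (HDF5)
# ---------------------------------------------------------------------------

def save_series_nifti(path, series: DynamicImageSeries) -> None:
    """Write magnitude frames as a (H, W, 1, T) NIfTI with temporal spacing."""
    vol = np.abs(series.data).astype(np.float32)
    vol = np.transpose(vol, (1, 2, 0))[:, :, None, :]
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    dts = np.diff(series.frame_times)
    dt = float(dts.mean()) if dts.size else 1.0
    img.header.set_zooms((1.0, 1.0, 1.0, dt))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    img.header["toffset"] = float(series.frame_times[0])
    nib.save(img, str(path))


def load_series_nifti(path) -> DynamicImageSeries:
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj).astype(np.float64)
    if vol.ndim != 4 or vol.shape[2] != 1:
        raise ValueError("expected a (H, W, 1, T) series")
    data = np.transpose(vol[:, :, 0, :], (2, 0, 1))
    dt = float(img.header.get_zooms()[3]) or 1.0
    t0 = float(img.header["toffset"])
    times = t0 + dt * np.arange(data.shape[0])
    return DynamicImageSeries(data, times)


def save_recon_sidecar(path, config=None, objective_trace=None, basis=None,
                       coefficients=None, extras: dict = None) -> None:
    """Write reconstruction metadata next to a NIfTI series."""
    with h5py.File(path, "w") as f:
        if config is not None:
            g = f.create_group("config")
            items = config if isinstance(config, dict) else vars(config)
            for key, val in items.items():
                g.attrs[key] = val
        if objective_trace is not None:
            f.create_dataset("objective_trace", data=np.asarray(objective_trace, dtype=np.float64))
        if basis is not None:
            g = f.create_group("basis")
            for i, u in enumerate(basis.bases):
                g.create_dataset(f"U{i}", data=np.asarray(u, dtype=np.complex64))
        if coefficients is not None:
            g = f.create_group("coefficients")
            for i, v in enumerate(coefficients.coeffs):
                g.create_dataset(f"V{i}", data=np.asarray(v, dtype=np.complex64))
        for key, val in (extras or {}).items():
            f.attrs[key] = val


def load_recon_sidecar(path) -> dict:
    out = {"config": {}, "objective_trace": None, "bases": [], "coeffs": [], "extras": {}}
    with h5py.File(path, "r") as f:
        if "config" in f:
            out["config"] = dict(f["config"].attrs)
        if "objective_trace" in f:
            out["objective_trace"] = f["objective_trace"][()]
        for group, key in (("basis", "bases"), ("coefficients", "coeffs")):
            if group in f:
                names = sorted(f[group], key=lambda s: int(s[1:]))
                out[key] = [f[group][n][()].astype(np.complex128) for n in names]
        out["extras"] = dict(f.attrs)
    return out


# ---------------------------------------------------------------------------
# CSV / JSON
# ---------------------------------------------------------------------------

def save_aif_csv(path, aif: AIF) -> None:
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["time_s", "concentration_mM"])
        for t, c in zip(aif.t, aif.ca):
            writer.writerow([f"{t:.6g}", f"{c:.8g}"])


def load_aif_csv(path) -> AIF:
    t, cb = [], []
    with open(path, newline="") as f:
        reader = csv.reader(f)
        header = next(reader)
        if header[:2] != ["time_s", "concentration_mM"]:
            raise ValueError("unrecognized AIF CSV header")
        for row in reader:
            t.append(float(row[0]))
            cb.append(float(row[1]))
    return AIF(np.asarray(t), np.asarray(cb))


def save_bootstrap_csv(path, results: list, summary: dict = None) -> None:
    """Write per-replicate fitted parameters and optional summary rows."""
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["replicate", "ve", "vp", "fp", "ps", "ktrans", "cost"])
        for i, r in enumerate(results):
            p = r.params
            writer.writerow(
                [i] + [f"{v:.8g}" for v in (p.ve, p.vp, p.fp, p.ps, p.ktrans, r.cost)]
            )
        if summary:
            for stat in ("mean", "sd"):
                row = [stat] + [
                    f"{summary[k][stat]:.8g}" for k in ("ve", "vp", "fp", "ps", "ktrans")
                ] + [""]
                writer.writerow(row)


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def save_metrics_json(path, reports: list, fold_table: dict = None,
                      extras: dict = None) -> None:
    doc = {
        "reports": {
            m.method: {"cnr": m.cnr, "noise_sd": m.noise_sd, "curve_scores": m.curve_scores}
            for m in reports
        }
    }
    if fold_table:
        doc["fold_change"] = fold_table
    if extras:
        doc.update(extras)
    Path(path).write_text(json.dumps(_jsonable(doc), indent=2) + "\n")


def load_metrics_json(path) -> dict:
    return json.loads(Path(path).read_text())
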