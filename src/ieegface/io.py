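"""File formats: TSV tables, array containers with JSON sidecars, TCK
streamlines, and NIfTI volumes.

Recordings are stored as a little-endian float ``.npy`` array (channels x
samples) next to a JSON sidecar holding the rate and channel metadata;
epoch sets as ``.npz`` plus trial/site TSVs.  Streamlines use the TCK
format (RAS mm); masks and density volumes NIfTI-1 with an MNI affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import BipolarSite, ContactRecording, EpochSet
from .simulate import SyntheticStreamlineSet
from .tracts import EndpointDensityVolume, GroupEndpointMask, VoxelGrid

# ----------------------------------------------------------------- designs

def save_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def load_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -------------------------------------------------------------- recordings

def save_recording(rec: ContactRecording, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "signal.npy", rec.signal.astype("<f8"))
    rec.contacts.to_csv(out / "contacts.tsv", sep="\t", index=False)
    meta = {"rate": rec.rate, "patient": rec.patient, "stages": rec.stages,
            "n_channels": int(rec.n_channels),
            "n_samples": int(rec.n_samples), "units": "uV",
            "layout": "channels x samples, little-endian float64"}
    (out / "recording.json").write_text(json.dumps(meta, indent=2))


def load_recording(in_dir) -> ContactRecording:
    p = Path(in_dir)
    meta = json.loads((p / "recording.json").read_text())
    return ContactRecording(
        signal=np.load(p / "signal.npy"),
        rate=float(meta["rate"]),
        contacts=pd.read_csv(p / "contacts.tsv", sep="\t"),
        patient=meta.get("patient", "unknown"),
        stages=list(meta.get("stages", [])))


# ------------------------------------------------------------- epoch sets

def _sites_frame(sites) -> pd.DataFrame:
    return pd.DataFrame([{
        "shaft": s.shaft, "deep_index": s.deep_index,
        "shallow_index": s.shallow_index, "x": s.x, "y": s.y, "z": s.z,
        "label": s.label, "roi": s.roi, "hemisphere": s.hemisphere,
        "patient": s.patient} for s in sites])


def sites_from_frame(df: pd.DataFrame) -> list:
    return [BipolarSite(r.shaft, int(r.deep_index), int(r.shallow_index),
                        float(r.x), float(r.y), float(r.z), r.label, r.roi,
                        r.hemisphere, r.patient)
            for r in df.itertuples(index=False)]


def save_epochs(epochs: EpochSet, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "epochs.npz", data=epochs.data, times=epochs.times)
    epochs.trials.to_csv(out / "trials.tsv", sep="\t", index=False)
    _sites_frame(epochs.sites).to_csv(out / "sites.tsv", sep="\t", index=False)
    meta = {"rate": epochs.rate, "lock": epochs.lock, "stages": epochs.stages,
            "units": "z-units", "layout": "trials x time x sites"}
    (out / "epochs.json").write_text(json.dumps(meta, indent=2))


def load_epochs(in_dir) -> EpochSet:
    p = Path(in_dir)
    meta = json.loads((p / "epochs.json").read_text())
    arrs = np.load(p / "epochs.npz")
    return EpochSet(
        data=arrs["data"], times=arrs["times"], rate=float(meta["rate"]),
        lock=meta["lock"],
        trials=pd.read_csv(p / "trials.tsv", sep="\t"),
        sites=sites_from_frame(pd.read_csv(p / "sites.tsv", sep="\t")),
        stages=list(meta.get("stages", [])))


# ------------------------------------------------------------- streamlines

def save_streamlines_tck(sset: SyntheticStreamlineSet, path) -> None:
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in sset.streamlines],
        affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))


def load_streamlines_tck(path, tract_name: str = None,
                         subject_id: str = "unknown") -> SyntheticStreamlineSet:
    tck = nib.streamlines.load(str(path))
    name = tract_name or Path(path).stem
    return SyntheticStreamlineSet(
        name, subject_id, [np.asarray(s, dtype=float)
                           for s in tck.streamlines])


# ------------------------------------------------------------------ nifti

def save_volume_nifti(vol, path) -> None:
    """Save an EndpointDensityVolume or GroupEndpointMask as NIfTI-1."""
    data = vol.data if isinstance(vol, EndpointDensityVolume) else vol.counts
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          vol.grid.affine)
    nib.save(img, str(path))


def load_mask_nifti(path, tract_name: str = None,
                    n_subjects: int = 0) -> GroupEndpointMask:
    img = nib.load(str(path))
    aff = img.affine
    grid = VoxelGrid(origin=tuple(float(v) for v in aff[:3, 3]),
                     shape=tuple(int(v) for v in img.shape))
    return GroupEndpointMask(counts=np.asarray(img.dataobj, dtype=float),
                             grid=grid,
                             tract_name=tract_name or Path(path).stem,
                             n_subjects=n_subjects)


# ----------------------------------------------------------------- overlap

def save_overlap(overlap, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    overlap.table.to_csv(out / "overlap.tsv", sep="\t", index=False)
    (out / "overlap.json").write_text(json.dumps({
        "dropped_columns": overlap.dropped_columns,
        "validity_threshold": overlap.validity_threshold}, indent=2))
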