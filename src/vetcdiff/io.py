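"""NIfTI / CSV / YAML interchange for volumes, masks, maps and cohorts."""
from __future__ import annotations

from pathlib import Path
from typing import Dict, List

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import PatientRecord
from .containers import DwiVolume, ParameterMap, VoiMask
from .exceptions import ConfigError
from .protocol import AcquisitionProtocol, GradientTiming

__all__ = [
    "save_dwi", "load_dwi", "save_mask", "load_mask", "save_parameter_maps",
    "save_protocol", "load_protocol", "save_cohort_csv", "load_cohort_csv",
    "save_decay_csv", "load_decay_csv",
]


def save_decay_csv(b_values, signals, path):
    """Write a single decay as a two-column table (b_s_per_mm2, signal)."""
    pd.DataFrame({"b_s_per_mm2": np.asarray(b_values, float),
                  "signal": np.asarray(signals, float)}).to_csv(path, index=False)


def load_decay_csv(path):
    """Read a (b_s_per_mm2, signal) table; returns (b, signal) arrays."""
    df = pd.read_csv(path)
    if not {"b_s_per_mm2", "signal"} <= set(df.columns):
        raise ConfigError("decay CSV needs b_s_per_mm2 and signal columns")
    return df["b_s_per_mm2"].to_numpy(float), df["signal"].to_numpy(float)

_EYE = np.eye(4)


def save_protocol(protocol: AcquisitionProtocol, path):
    """Write the protocol sidecar (b-values, averages, mono subset, timing)."""
    doc = {
        "b_values": [float(b) for b in protocol.b_values],
        "averages": [int(a) for a in protocol.averages],
        "mono_b_subset": [float(b) for b in protocol.mono_b_subset],
        "timing": {
            "gamma": protocol.timing.gamma,
            "big_delta": protocol.timing.big_delta,
            "small_delta": protocol.timing.small_delta,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_protocol(path) -> AcquisitionProtocol:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    timing = GradientTiming(**doc.get("timing", {}))
    return AcquisitionProtocol(
        b_values=tuple(doc["b_values"]),
        averages=tuple(int(a) for a in doc["averages"]),
        mono_b_subset=tuple(doc.get("mono_b_subset", doc["b_values"][:3])),
        timing=timing,
    )


def save_dwi(dwi: DwiVolume, nifti_path, protocol_path=None):
    nib.save(nib.Nifti1Image(dwi.data.astype(np.float32), _EYE), str(nifti_path))
    if protocol_path is not None:
        save_protocol(dwi.protocol, protocol_path)


def load_dwi(nifti_path, protocol_path) -> DwiVolume:
    img = nib.load(str(nifti_path))
    return DwiVolume(data=np.asarray(img.dataobj, dtype=float),
                     protocol=load_protocol(protocol_path))


def save_mask(mask: VoiMask, path):
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), _EYE), str(path))


def load_mask(path) -> VoiMask:
    img = nib.load(str(path))
    return VoiMask(data=np.asarray(img.dataobj) > 0)


def save_parameter_maps(maps: Dict[str, ParameterMap], out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, pm in maps.items():
        nib.save(nib.Nifti1Image(pm.values.astype(np.float32), _EYE),
                 str(out / f"{name}.nii.gz"))


def save_cohort_csv(records: List[PatientRecord], path):
    from .cohort import cohort_frame

    cohort_frame(records).to_csv(path, index=False)


def load_cohort_csv(path) -> List[PatientRecord]:
    df = pd.read_csv(path)
    required = {"id", "vetc_status"}
    if not required <= set(df.columns):
        raise ConfigError("cohort CSV needs id and vetc_status columns")
    markers = sorted({c[:-3] for c in df.columns if c.endswith("_r1")})
    records = []
    for _, row in df.iterrows():
        records.append(PatientRecord(
            id=str(row["id"]),
            vetc_status=str(row["vetc_status"]),
            markers_rater1={m: float(row[f"{m}_r1"]) for m in markers},
            markers_rater2={m: float(row[f"{m}_r2"]) for m in markers},
        ))
    return records
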