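"""Disk formats: NIfTI volumes with JSON sidecars per study, cohort-level
subgroup CSVs, and run manifests.

Volumes are written one .nii.gz per sequence with an affine encoding the
declared orientation; on read, arrays are reoriented to the internal LPS
canon, optionally resampled in-plane to a target grid (linear) and coarsened
to a minimum slice thickness (mean aggregation).
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .phantoms import MRIStudy, MRIVolume, ReportRecord, SubgroupMetadata

# internal canon: axis i points toward the i-th letter of "LPS"
_AXIS_SIGNS = {"L": ("L", +1), "R": ("L", -1),
               "P": ("P", +1), "A": ("P", -1),
               "S": ("S", +1), "I": ("S", -1)}
_CANON = ("L", "P", "S")


def _orientation_affine(code, spacing):
    """Affine whose columns realize a 3-letter orientation code (flip-only
    codes over the LPS axes) in nibabel's RAS+ world."""
    aff = np.zeros((4, 4))
    aff[3, 3] = 1.0
    for i, letter in enumerate(code):
        axis_letter, sign = _AXIS_SIGNS[letter]
        axis = _CANON.index(axis_letter)
        # nibabel world is RAS+: L->-x, P->-y, S->+z
        world_sign = {"L": -1, "P": -1, "S": +1}[axis_letter] * sign
        aff[axis, i] = world_sign * spacing[i]
    return aff


def write_study(study: MRIStudy, record: ReportRecord,
                meta: SubgroupMetadata | None, out_dir):
    """One .nii.gz per sequence plus a JSON sidecar for the study."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq_files = []
    for i, vol in enumerate(study.sequences):
        aff = _orientation_affine(vol.orientation, vol.spacing)
        img = nib.Nifti1Image(vol.voxels.astype(np.float32), aff)
        fname = f"seq_{i:02d}.nii.gz"
        nib.save(img, out_dir / fname)
        seq_files.append({"file": fname, "sequence_name": vol.sequence_name,
                          "plane": vol.plane, "orientation": vol.orientation,
                          "spacing": list(vol.spacing)})
    sidecar = {
        "study_name": study.study_name,
        "patient_id": study.patient_id,
        "abnormal": study.abnormal,
        "sequences": seq_files,
        "findings": list(record.findings),
        "labels": np.asarray(record.labels).tolist(),
        "acuity": record.acuity,
        "age": record.age,
        "referrals": np.asarray(record.referrals).tolist(),
    }
    if meta is not None:
        sidecar["subgroup"] = dict(meta.attributes)
        sidecar["turnaround_days"] = meta.turnaround_days
    (out_dir / "study.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir / "study.json"


# voxel axes of the LPS canon expressed in nibabel's RAS+ world:
# axis 0 -> -x (Left), axis 1 -> -y (Posterior), axis 2 -> +z (Superior)
_LPS_ORNT = np.array([[0, -1], [1, -1], [2, 1]], dtype=float)


def _to_lps(data, affine):
    current = nib.orientations.io_orientation(affine)
    xform = nib.orientations.ornt_transform(current, _LPS_ORNT)
    return nib.orientations.apply_orientation(data, xform)


def read_study(path, target_inplane=None, min_slice_mm=None):
    """Load a study directory written by write_study.

    Arrays are reoriented to LPS; when `target_inplane` is given, in-plane
    dims are linearly resampled to that size; when `min_slice_mm` is given,
    thinner slices are coarsened by mean aggregation.
    Returns (MRIStudy, ReportRecord, SubgroupMetadata-or-None).
    """
    path = Path(path)
    sidecar_file = path / "study.json" if path.is_dir() else path
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    sc = json.loads(sidecar_file.read_text())
    base = sidecar_file.parent
    sequences = []
    for entry in sc["sequences"]:
        img = nib.load(base / entry["file"])
        data = np.asarray(img.dataobj, dtype=np.float32)
        data = np.ascontiguousarray(_to_lps(data, img.affine))
        spacing = list(entry["spacing"])
        if target_inplane is not None and data.shape[:2] != (target_inplane,
                                                             target_inplane):
            zx = target_inplane / data.shape[0]
            zy = target_inplane / data.shape[1]
            data = ndimage.zoom(data, (zx, zy, 1.0), order=1)
            spacing[0] /= zx
            spacing[1] /= zy
        if min_slice_mm is not None and spacing[2] < min_slice_mm:
            group = int(np.ceil(min_slice_mm / spacing[2]))
            nz = data.shape[2] // group
            if nz >= 1:
                data = data[:, :, :nz * group]
                data = data.reshape(data.shape[0], data.shape[1], nz,
                                    group).mean(axis=3)
                spacing[2] *= group
        sequences.append(MRIVolume(
            voxels=data.astype(np.float32), spacing=tuple(spacing),
            plane=entry["plane"], orientation="LPS",
            sequence_name=entry["sequence_name"]))
    study = MRIStudy(study_name=sc["study_name"], sequences=sequences,
                     patient_id=sc["patient_id"], abnormal=sc["abnormal"])
    record = ReportRecord(findings=sc["findings"],
                          labels=np.asarray(sc["labels"], dtype=np.int64),
                          acuity=sc["acuity"], age=sc["age"],
                          referrals=np.asarray(sc["referrals"], dtype=np.int64))
    meta = None
    if "subgroup" in sc:
        meta = SubgroupMetadata(attributes=sc["subgroup"],
                                turnaround_days=sc["turnaround_days"])
    return study, record, meta


def write_cohort_csv(cohort, path):
    """Subgroup attributes + labels + turnaround per study, one row each."""
    rows = []
    for study, record, meta in cohort:
        row = {"patient_id": study.patient_id, "abnormal": study.abnormal,
               "acuity": record.acuity, "age": record.age,
               "turnaround_days": meta.turnaround_days if meta else np.nan}
        for j, v in enumerate(np.asarray(record.labels)):
            row[f"label_{j}"] = int(v)
        if meta:
            row.update(meta.attributes)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.9g")
    return df


def write_manifest(path, config: dict, seeds: dict, inputs=None):
    """Reproducibility manifest: config, seeds, versions, input hashes."""
    manifest = {
        "config": config,
        "seeds": seeds,
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__},
        "inputs": {},
    }
    for name, p in (inputs or {}).items():
        p = Path(p)
        if p.exists() and p.is_file():
            manifest["inputs"][name] = hashlib.sha256(p.read_bytes()).hexdigest()
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
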