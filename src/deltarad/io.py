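"""Cohort serialization: NIfTI volumes/masks plus a JSON manifest.

The on-disk layout is one directory per cohort containing a
``manifest.json`` and, per patient and fraction, NIfTI files for the image
and the manual / automated / fiducial masks.  Real data in the same layout
can be substituted for generator output.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .longitudinal import FractionationSchedule
from .synthetic import Fraction, PatientCourse
from .types import ROIMask, VolumeImage

_MASK_KEYS = ("manual", "automated", "fiducial")


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


def _save(path: Path, data: np.ndarray, spacing) -> None:
    # store as (x, y, z) per NIfTI convention; our arrays are (z, y, x)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32).T, _affine(spacing)), path)


def _load(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.get_fdata()).T, (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def write_cohort(cohort: list[PatientCourse], out_dir: str | Path) -> Path:
    """Write NIfTI volumes/masks and the manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"patients": []}
    for p in cohort:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        entry = {
            "patient_id": p.patient_id,
            "dose_per_fraction_gy": list(p.schedule.dose_per_fraction_gy),
            "alpha_beta_gy": p.schedule.alpha_beta_gy,
            "outcome_acute": p.outcome_acute,
            "outcome_subacute": p.outcome_subacute,
            "ipss_baseline": p.ipss_baseline,
            "ipss_post": p.ipss_post,
            "fractions": [],
        }
        for i, fx in enumerate(p.fractions, start=1):
            files = {
                "image": f"{p.patient_id}/fx{i:03d}_image.nii.gz",
                "manual": f"{p.patient_id}/fx{i:03d}_manual.nii.gz",
                "automated": f"{p.patient_id}/fx{i:03d}_automated.nii.gz",
                "fiducial": f"{p.patient_id}/fx{i:03d}_fiducial.nii.gz",
            }
            _save(out / files["image"], fx.image.data, fx.image.spacing)
            for key in _MASK_KEYS:
                _save(out / files[key], getattr(fx, key).data.astype(np.uint8), fx.image.spacing)
            entry["fractions"].append(files)
        manifest["patients"].append(entry)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def read_cohort(manifest_path: str | Path) -> list[PatientCourse]:
    """Load a cohort written by :func:`write_cohort` (or real data in that layout)."""
    mpath = Path(manifest_path)
    root = mpath.parent
    manifest = json.loads(mpath.read_text())
    cohort = []
    for entry in manifest["patients"]:
        schedule = FractionationSchedule(
            tuple(entry["dose_per_fraction_gy"]), entry.get("alpha_beta_gy", 3.0)
        )
        fractions = []
        for files in entry["fractions"]:
            img, spacing = _load(root / files["image"])
            masks = {}
            for key in _MASK_KEYS:
                arr, _ = _load(root / files[key])
                masks[key] = ROIMask(arr > 0.5, spacing)
            fractions.append(
                Fraction(
                    image=VolumeImage(img, spacing),
                    manual=masks["manual"],
                    automated=masks["automated"],
                    fiducial=masks["fiducial"],
                )
            )
        cohort.append(
            PatientCourse(
                patient_id=entry["patient_id"],
                schedule=schedule,
                fractions=fractions,
                outcome_acute=int(entry["outcome_acute"]),
                outcome_subacute=int(entry["outcome_subacute"]),
                ipss_baseline=int(entry["ipss_baseline"]),
                ipss_post=int(entry["ipss_post"]),
            )
        )
    return cohort


def validate_manifest(manifest_path: str | Path) -> list[str]:
    """Structural checks on a cohort manifest; returns human-readable problems."""
    mpath = Path(manifest_path)
    problems: list[str] = []
    try:
        manifest = json.loads(mpath.read_text())
    except (OSError, json.JSONDecodeError) as e:
        return [f"unreadable manifest: {e}"]
    root = mpath.parent
    for entry in manifest.get("patients", []):
        pid = entry.get("patient_id", "<missing id>")
        doses = entry.get("dose_per_fraction_gy", [])
        fracs = entry.get("fractions", [])
        if len(doses) != len(fracs):
            problems.append(
                f"{pid}: schedule length {len(doses)} != fraction count {len(fracs)}"
            )
        for key in ("outcome_acute", "outcome_subacute", "ipss_baseline", "ipss_post"):
            if key not in entry:
                problems.append(f"{pid}: missing outcome field {key}")
        ref_shape = None
        for i, files in enumerate(fracs, start=1):
            for key in ("image",) + _MASK_KEYS:
                f = files.get(key)
                if f is None or not (root / f).exists():
                    problems.append(f"{pid} fx{i}: missing {key} file")
                    continue
            if all(files.get(k) and (root / files[k]).exists() for k in ("image",) + _MASK_KEYS):
                img, _ = _load(root / files["image"])
                if ref_shape is None:
                    ref_shape = img.shape
                elif img.shape != ref_shape:
                    problems.append(f"{pid} fx{i}: grid shape {img.shape} != {ref_shape}")
                for key in ("manual", "automated"):
                    arr, _ = _load(root / files[key])
                    if arr.shape != img.shape:
                        problems.append(f"{pid} fx{i}: {key} mask grid mismatch")
                    elif not (arr > 0.5).any():
                        problems.append(f"{pid} fx{i}: {key} mask is empty")
    return problems
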