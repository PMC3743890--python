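"""File formats: NIfTI images and maps, JSON sidecars/specs, CSV tables.

Complex multi-echo data is stored as a pair of 4D NIfTI volumes of shape
(x, y, 1, echo) in either the real/imaginary or magnitude/phase dialect,
with a JSON sidecar recording echo times, field strength and the dialect;
both dialects are auto-detected on read.  All JSON documents carry a
``schema_version`` and readers reject unknown major versions.  Every
written artifact set gets a provenance JSON with input checksums and
parameters.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .recon import FatFractionMap, FieldMap, MultiEchoImage

__all__ = [
    "SCHEMA_VERSION",
    "save_multiecho",
    "load_multiecho",
    "save_map",
    "load_map",
    "save_label_map",
    "load_label_map",
    "save_cohort_csv",
    "load_cohort_csv",
    "write_provenance",
    "sha256_of",
]

SCHEMA_VERSION = "1.0"


def _check_schema(doc: dict, what: str) -> None:
    major = str(doc.get("schema_version", "0")).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise ValueError(
            f"{what}: unsupported schema_version {doc.get('schema_version')!r}"
        )


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1] = voxel_size_mm[0], voxel_size_mm[1]
    return aff


def _to_xyze(data: np.ndarray) -> np.ndarray:
    # (echo, ny, nx) -> (x, y, 1, echo)
    return np.transpose(data, (2, 1, 0))[:, :, None, :]


def _from_xyze(vol: np.ndarray) -> np.ndarray:
    return np.transpose(vol[:, :, 0, :], (2, 1, 0))


def save_multiecho(
    img: MultiEchoImage, base: "str | Path", dialect: str = "realimag"
) -> dict:
    """Write ``<base>_<part>.nii.gz`` pairs plus ``<base>.json`` sidecar.

    ``dialect`` is ``realimag`` (parts real/imag) or ``magphase``
    (parts mag/phase, phase in radians).  Returns the sidecar document.
    """
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "realimag":
        parts = {"real": img.data.real, "imag": img.data.imag}
    elif dialect == "magphase":
        parts = {"mag": np.abs(img.data), "phase": np.angle(img.data)}
    else:
        raise ValueError("dialect must be 'realimag' or 'magphase'")
    aff = _affine(img.voxel_size_mm)
    files = {}
    for part, arr in parts.items():
        path = base.parent / f"{base.name}_{part}.nii.gz"
        nib.save(nib.Nifti1Image(_to_xyze(arr).astype(np.float32), aff), path)
        files[part] = path.name
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "complex_dialect": dialect,
        "files": files,
        "echo_times_s": [float(t) for t in img.echo_times],
        "field_strength_t": img.field_strength_t,
        "voxel_size_mm": list(img.voxel_size_mm),
        "meta": {
            k: v for k, v in img.meta.items() if isinstance(v, (int, float, str, bool))
        },
    }
    (base.parent / f"{base.name}.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar


def load_multiecho(sidecar_path: "str | Path") -> MultiEchoImage:
    """Read a multi-echo image from its JSON sidecar (either dialect)."""
    sidecar_path = Path(sidecar_path)
    doc = json.loads(sidecar_path.read_text())
    _check_schema(doc, f"sidecar {sidecar_path.name}")
    parts = {}
    for part, fname in doc["files"].items():
        vol = np.asanyarray(nib.load(sidecar_path.parent / fname).dataobj)
        parts[part] = _from_xyze(np.asarray(vol, float))
    if doc["complex_dialect"] == "realimag":
        data = parts["real"] + 1j * parts["imag"]
    else:
        data = parts["mag"] * np.exp(1j * parts["phase"])
    return MultiEchoImage(
        data=data,
        echo_times=np.asarray(doc["echo_times_s"], float),
        field_strength_t=doc.get("field_strength_t", 3.0),
        voxel_size_mm=tuple(doc.get("voxel_size_mm", (1.0, 1.0))),
        meta=dict(doc.get("meta", {})),
    )


def save_map(
    arr: "np.ndarray | FatFractionMap | FieldMap",
    path: "str | Path",
    voxel_size_mm=(1.0, 1.0),
) -> None:
    """Write a 2D float map (or map object + validity mask) as NIfTI.

    Map objects additionally produce ``<stem>_valid.nii.gz`` (uint8).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(voxel_size_mm)
    if isinstance(arr, FatFractionMap):
        data, valid = arr.ff, arr.valid
    elif isinstance(arr, FieldMap):
        data, valid = arr.psi_hz, arr.valid
    else:
        data, valid = np.asarray(arr, float), None
    nib.save(nib.Nifti1Image(data.T.astype(np.float32), aff), path)
    if valid is not None:
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        vpath = path.parent / f"{stem}_valid.nii.gz"
        nib.save(nib.Nifti1Image(valid.T.astype(np.uint8), aff), vpath)


def load_map(path: "str | Path") -> np.ndarray:
    vol = np.asanyarray(nib.load(path).dataobj)
    return np.asarray(vol, float).T


def save_label_map(
    label: np.ndarray, names: list[str], base: "str | Path", voxel_size_mm=(1.0, 1.0)
) -> None:
    """Write an integer label image plus a JSON name table."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(label.T.astype(np.int16), _affine(voxel_size_mm)),
        base.parent / f"{base.name}.nii.gz",
    )
    doc = {
        "schema_version": SCHEMA_VERSION,
        "labels": {str(i + 1): n for i, n in enumerate(names)},
    }
    (base.parent / f"{base.name}_labels.json").write_text(json.dumps(doc, indent=2))


def load_label_map(base: "str | Path") -> tuple[np.ndarray, dict[int, str]]:
    base = Path(base)
    label = np.asarray(
        np.asanyarray(nib.load(base.parent / f"{base.name}.nii.gz").dataobj)
    ).T.astype(int)
    doc = json.loads((base.parent / f"{base.name}_labels.json").read_text())
    _check_schema(doc, "label name table")
    return label, {int(k): v for k, v in doc["labels"].items()}


def save_cohort_csv(table: pd.DataFrame, path: "str | Path") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def load_cohort_csv(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "muscle", "visit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns: {sorted(missing)}")
    if "grade" in df.columns:
        df["grade"] = df["grade"].astype(str)
    return df


def sha256_of(path: "str | Path") -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(
    out_path: "str | Path",
    *,
    stage: str,
    parameters: dict,
    inputs: "list[str | Path]" = (),
    seed: int | None = None,
) -> None:
    """Record how an artifact set was produced (inputs' checksums, params)."""
    from . import __version__

    doc = {
        "schema_version": SCHEMA_VERSION,
        "stage": stage,
        "software": {"name": "dixonquant", "version": __version__},
        "seed": seed,
        "parameters": parameters,
        "inputs": {str(p): sha256_of(p) for p in inputs},
    }
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(doc, indent=2))
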