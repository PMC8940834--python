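"""File formats: the .sproj projection container, NIfTI volumes, manifests.

The ``.sproj`` container is a plain-text header of ``key: value`` lines
terminated by an ``end_header`` line, followed by a little-endian binary
payload in view-major, row-major order.  Header keys: ``matrix_rows``,
``matrix_cols``, ``n_views``, ``pixel_mm``, ``dose_fraction``, ``gate``,
``n_gates``, ``seed``, ``scaling``, ``payload``.  Measured counts are stored
as 32-bit unsigned integers (bit-exact round trip); GAN predictions are
real-valued, so ``payload: float32`` marks a float payload holding the
predicted expectation.  ``scaling`` is a multiplicative constant applied on
read (1 by default).

Reconstructed volumes are written as NIfTI-1 with an isotropic affine; the
cardiac orientation tag (transaxial/SA/VLA/HLA) travels in the NIfTI
``descrip`` field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import AcquisitionGeometry, ProjectionSet
from .recon import ReconVolume

__all__ = [
    "write_sproj",
    "read_sproj",
    "write_volume",
    "read_volume",
    "CohortManifest",
]

_HEADER_END = "end_header"
_REQUIRED_KEYS = ("matrix_rows", "matrix_cols", "n_views", "pixel_mm", "dose_fraction")

RISK_GROUPS = ("healthy", "low", "intermediate", "severe")


def write_sproj(proj: ProjectionSet, path: str | os.PathLike) -> None:
    """Write a projection set to the ``.sproj`` container."""
    geom = proj.geometry
    if proj.counts is not None:
        payload = np.ascontiguousarray(proj.counts, dtype="<u4")
        payload_kind = "uint32"
    elif proj.expected is not None:
        payload = np.ascontiguousarray(proj.expected, dtype="<f4")
        payload_kind = "float32"
    else:
        raise ValueError("projection set has neither counts nor expected values")
    header = {
        "matrix_rows": geom.detector_rows,
        "matrix_cols": geom.detector_cols,
        "n_views": geom.n_views,
        "pixel_mm": geom.pixel_mm,
        "dose_fraction": proj.dose_fraction,
        "gate": -1 if proj.gate is None else proj.gate,
        "n_gates": -1 if proj.n_gates is None else proj.n_gates,
        "seed": proj.provenance.get("seed", -1),
        "scaling": 1.0,
        "payload": payload_kind,
    }
    with open(path, "wb") as fh:
        for key, value in header.items():
            fh.write(f"{key}: {value}\n".encode("ascii"))
        fh.write(f"{_HEADER_END}\n".encode("ascii"))
        fh.write(payload.tobytes())


def read_sproj(path: str | os.PathLike) -> ProjectionSet:
    """Read a ``.sproj`` file back into a :class:`ProjectionSet`."""
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: header not terminated by '{_HEADER_END}'")
            text = line.decode("ascii", errors="replace").strip()
            if text == _HEADER_END:
                break
            if ":" not in text:
                raise ValueError(f"{path}: malformed header line {text!r}")
            key, _, value = text.partition(":")
            header[key.strip()] = value.strip()
        blob = fh.read()
    for key in _REQUIRED_KEYS:
        if key not in header:
            raise ValueError(f"{path}: missing required header key '{key}'")
    rows = int(header["matrix_rows"])
    cols = int(header["matrix_cols"])
    n_views = int(header["n_views"])
    payload_kind = header.get("payload", "uint32")
    dtype = {"uint32": "<u4", "float32": "<f4"}.get(payload_kind)
    if dtype is None:
        raise ValueError(f"{path}: unknown payload kind '{payload_kind}'")
    expect_bytes = n_views * rows * cols * 4
    if len(blob) != expect_bytes:
        raise ValueError(
            f"{path}: truncated payload, expected {expect_bytes} bytes, found {len(blob)}"
        )
    data = np.frombuffer(blob, dtype=dtype).reshape(n_views, rows, cols)
    scaling = float(header.get("scaling", 1.0))
    geom = AcquisitionGeometry(
        n_views=n_views, detector_rows=rows, detector_cols=cols,
        pixel_mm=float(header["pixel_mm"]),
    )
    gate = int(header.get("gate", -1))
    n_gates = int(header.get("n_gates", -1))
    prov = {"seed": int(float(header.get("seed", -1))), "path": str(path)}
    if payload_kind == "uint32":
        counts = data.astype(np.int64)
        if scaling != 1.0:
            counts = np.round(counts * scaling).astype(np.int64)
        return ProjectionSet(
            geometry=geom, counts=counts,
            dose_fraction=float(header["dose_fraction"]),
            gate=None if gate < 0 else gate,
            n_gates=None if n_gates < 0 else n_gates,
            provenance=prov,
        )
    return ProjectionSet(
        geometry=geom, expected=data.astype(float) * scaling,
        dose_fraction=float(header["dose_fraction"]),
        gate=None if gate < 0 else gate,
        n_gates=None if n_gates < 0 else n_gates,
        provenance=prov,
    )


def write_volume(vol: ReconVolume, path: str | os.PathLike) -> None:
    """Write a reconstructed volume as NIfTI-1 (float32, isotropic voxels)."""
    affine = np.diag([vol.voxel_mm, vol.voxel_mm, vol.voxel_mm, 1.0])
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
    img.header["descrip"] = f"orientation={vol.orientation}".encode("ascii")
    nib.save(img, str(path))


def read_volume(path: str | os.PathLike) -> ReconVolume:
    img = nib.load(str(path))
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode("ascii")
    orientation = "transaxial"
    if descrip.startswith("orientation="):
        orientation = descrip.split("=", 1)[1]
    voxel_mm = float(img.header.get_zooms()[0])
    return ReconVolume(
        values=np.asarray(img.dataobj, dtype=float),
        voxel_mm=voxel_mm,
        orientation=orientation,
    )


@dataclass
class CohortManifest:
    """Table of study arms: patient id, risk group, per-arm file paths, seeds."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"patient_id", "risk_group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        ids = self.table["patient_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValueError(f"duplicate patient ids in manifest: {dupes}")
        bad = set(self.table["risk_group"]) - set(RISK_GROUPS)
        if bad:
            raise ValueError(f"unknown risk groups {sorted(bad)}; expected {RISK_GROUPS}")

    def validate_files(self) -> None:
        path_cols = [c for c in self.table.columns if c.endswith("_path")]
        for col in path_cols:
            for p in self.table[col].dropna():
                if not os.path.exists(p):
                    raise FileNotFoundError(f"manifest references missing file: {p}")

    @classmethod
    def read_csv(cls, path: str | os.PathLike) -> "CohortManifest":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, index=False)
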