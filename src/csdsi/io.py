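"""Readers and writers: FSL gradient tables, NIfTI volumes, manifests."""

from __future__ import annotations

import hashlib
import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .qspace import ProtocolMeta, SamplingScheme, SchemeEntry

__all__ = [
    "Dataset",
    "read_fsl_gradients",
    "write_fsl_gradients",
    "read_volume",
    "write_volume",
    "write_manifest",
]


def read_fsl_gradients(bval_path, bvec_path,
                       meta: ProtocolMeta | None = None) -> SamplingScheme:
    """Parse an FSL-dialect bval/bvec pair into a sampling scheme.

    bvals: one whitespace-separated row; bvecs: three rows (x, y, z), one
    column per volume.  Non-unit vectors at b > 0 are normalized with a
    warning; a zero vector at b > 0 is an error.
    """
    bvals = np.loadtxt(bval_path, ndmin=2)
    if bvals.shape[0] != 1:
        raise ValueError(f"bval file must be a single row, got {bvals.shape[0]}")
    bvals = bvals[0]
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must have exactly 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != len(bvals):
        raise ValueError(
            f"gradient table mismatch: {len(bvals)} b-values vs "
            f"{bvecs.shape[1]} b-vectors")
    entries = []
    for b, v in zip(bvals, bvecs.T):
        if b == 0:
            entries.append(SchemeEntry(direction=np.zeros(3), bval=0.0))
            continue
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("zero b-vector at a nonzero b-value")
        if abs(n - 1.0) > 1e-6:
            warnings.warn("non-unit b-vector normalized", stacklevel=2)
            v = v / n
        entries.append(SchemeEntry(direction=v, bval=float(b)))
    if meta is None:
        meta = ProtocolMeta(n_b0=int(np.sum(bvals == 0)))
    return SamplingScheme(entries=entries, protocol_id=Path(str(bval_path)).stem,
                          meta=meta)


def write_fsl_gradients(scheme: SamplingScheme, prefix) -> tuple[Path, Path]:
    """Write scheme as FSL ``<prefix>.bval`` / ``<prefix>.bvec``."""
    prefix = Path(prefix)
    bval_path = prefix.with_suffix(".bval")
    bvec_path = prefix.with_suffix(".bvec")
    bvals = scheme.bvals
    bvecs = scheme.bvecs.T  # 3 rows
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in bvecs:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    return bval_path, bvec_path


@dataclass
class Dataset:
    """4D diffusion volume bound to its sampling scheme."""

    data: np.ndarray
    scheme: SamplingScheme
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("diffusion data must be 4-D")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"volume count {self.data.shape[3]} does not match scheme "
                f"length {len(self.scheme)}")


def read_volume(nifti_path, scheme: SamplingScheme,
                mask_path=None) -> Dataset:
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return Dataset(data=data, scheme=scheme, affine=img.affine, mask=mask)


def write_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(path, command: str, params: dict,
                   inputs: list | None = None) -> None:
    """Provenance manifest: command line, parameters, input hashes."""
    manifest = {
        "command": command,
        "argv": sys.argv,
        "params": {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                       else str(v)) for k, v in params.items()},
        "inputs": {str(p): _hash_file(p) for p in (inputs or [])
                   if Path(str(p)).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
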