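"""NIfTI / bval file I/O.

b-values are stored FSL-style: a single whitespace-separated line. No
bvec file is read or written — the bi-exponential IVIM model here is
direction-independent, so unlike most DWI tooling there is no gradient
direction table anywhere in this package.

Output parameter maps are stored float32; the diagnostics volume is a
uint8 bitmask (bit table in :mod:`topoivim.topopro`). Every fit writes a
JSON sidecar recording the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .ivim import AcquisitionScheme, ConfigurationError
from .phantom import PhantomOutput
from .topopro import ParameterMaps, TopoProConfig

__all__ = [
    "read_bvals",
    "write_bvals",
    "read_dwi",
    "write_maps",
    "read_maps",
    "write_phantom",
]


def read_bvals(path) -> np.ndarray:
    """Parse an FSL-style .bval file (whitespace-separated numbers)."""
    path = Path(path)
    values = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        for col, token in enumerate(line.split(), start=1):
            try:
                values.append(float(token))
            except ValueError as err:
                raise ConfigurationError(
                    f"{path}: unreadable b-value {token!r} at line {lineno}, "
                    f"field {col}") from err
    if not values:
        raise ConfigurationError(f"{path}: no b-values found")
    return np.asarray(values)


def write_bvals(bvalues, path) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in np.asarray(bvalues)) + "\n")


def read_dwi(nifti_path, bval_path):
    """Load a 4-D DWI volume and its b-values.

    Returns (data, AcquisitionScheme, affine, header). The affine and
    header are passed through untouched so outputs can be written back
    into the same space.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ConfigurationError(
            f"{nifti_path}: expected a 4-D DWI volume, got {data.ndim}-D")
    bvals = read_bvals(bval_path)
    if data.shape[3] != bvals.size:
        raise ConfigurationError(
            f"volume has {data.shape[3]} volumes but bval file has {bvals.size} entries")
    return data, AcquisitionScheme(bvals), img.affine, img.header


def _save(arr, affine, path, dtype=np.float32):
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine), str(path))


def write_maps(maps: ParameterMaps, affine, outdir, seed=None) -> dict:
    """Write fitted parameter maps plus diagnostics and a JSON sidecar.

    Creates f.nii.gz, D.nii.gz, Dstar.nii.gz, residual.nii.gz,
    flags.nii.gz (uint8 bitmask) and sidecar.json in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, arr in (("f", maps.f), ("D", maps.D), ("Dstar", maps.Dstar),
                      ("residual", maps.residual)):
        p = outdir / f"{name}.nii.gz"
        _save(arr, affine, p)
        files[name] = p
    p = outdir / "flags.nii.gz"
    _save(maps.flags, affine, p, dtype=np.uint8)
    files["flags"] = p
    config = maps.config or TopoProConfig()
    sidecar = {
        "config": dataclasses.asdict(config),
        "seed": int(seed if seed is not None else config.seed),
        "bvalues": [float(b) for b in maps.scheme.bvalues] if maps.scheme else None,
        "flag_bits": {
            "degenerate": 1, "clipped_negative_signal": 2, "bad_s0": 4,
            "level2_no_improvement": 8, "not_converged": 16, "empty_voxel": 32,
        },
    }
    p = outdir / "sidecar.json"
    p.write_text(json.dumps(sidecar, indent=2))
    files["sidecar"] = p
    return files


def read_maps(outdir):
    """Re-read maps written by :func:`write_maps` as a dict of arrays."""
    outdir = Path(outdir)
    out = {}
    for name in ("f", "D", "Dstar", "residual", "flags"):
        p = outdir / f"{name}.nii.gz"
        if p.exists():
            out[name] = np.asarray(nib.load(str(p)).dataobj)
    return out


def write_phantom(phantom: PhantomOutput, outdir, affine=None) -> dict:
    """Write a simulated phantom: DWI + labels + ground-truth maps + bvals + metadata."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    files = {}
    _save(phantom.dwi, affine, outdir / "dwi.nii.gz")
    _save(phantom.labels, affine, outdir / "labels.nii.gz", dtype=np.int16)
    for name, arr in (("gt_f", phantom.gt_f), ("gt_D", phantom.gt_D),
                      ("gt_Dstar", phantom.gt_Dstar)):
        _save(arr, affine, outdir / f"{name}.nii.gz")
    write_bvals(phantom.spec.bvalues, outdir / "dwi.bval")
    spec = phantom.spec
    meta = {
        "shape": list(spec.shape),
        "tissue_table": {k: list(map(float, v)) for k, v in spec.tissue_table.items()},
        "bvalues": [float(b) for b in spec.bvalues],
        "snr_per_slice": [float(s) for s in spec.snr_per_slice],
        "n_coils": int(spec.n_coils),
        "s0": float(spec.s0),
        "seed": int(spec.seed),
        "noise_sigma_per_slice": [float(s) for s in phantom.noise_sigma_per_slice],
    }
    (outdir / "phantom.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    for name in ("dwi", "labels", "gt_f", "gt_D", "gt_Dstar"):
        files[name] = outdir / f"{name}.nii.gz"
    files["bval"] = outdir / "dwi.bval"
    files["metadata"] = outdir / "phantom.yaml"
    return files
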