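"""Model/Results front-end.

:class:`IVIMModel` wraps a 4-D volume (or a bag of voxel curves) plus
its acquisition scheme; :meth:`IVIMModel.fit` dispatches to one of the
fitting methods and returns an :class:`IVIMResults` carrying the
parameter maps, diagnostics, and a summary table.

    >>> model = IVIMModel(data, scheme, mask=mask)
    >>> res = model.fit(method="topopro")
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baselines import BaselineConfig
from .evaluation import fit_slice_with_method
from .ivim import AcquisitionScheme, ConfigurationError
from .topopro import ParameterMaps, TopoProConfig, fit_volume

__all__ = ["IVIMModel", "IVIMResults"]

METHODS = ("topopro", "segmented", "bayesian", "nls", "shgo")


class IVIMModel:
    """Bi-exponential IVIM model bound to a data volume.

    Parameters
    ----------
    data : ndarray
        4-D array (nx, ny, nz, m) of raw (unnormalized) signal.
    scheme : AcquisitionScheme
        The b-values; the last data axis must match.
    mask : ndarray, optional
        Boolean 3-D mask of voxels to fit. Default: voxels whose mean
        b=0 signal is positive.
    """

    def __init__(self, data, scheme: AcquisitionScheme, mask=None):
        data = np.asarray(data, dtype=float)
        if data.ndim == 2:  # (n_voxels, m) bag of curves
            data = data[:, None, None, :]
        if data.ndim != 4:
            raise ConfigurationError(f"data must be 4-D, got shape {data.shape}")
        if data.shape[-1] != scheme.m:
            raise ConfigurationError(
                f"last axis {data.shape[-1]} != scheme length {scheme.m}")
        self.data = data
        self.scheme = scheme
        if mask is None:
            mask = data[..., scheme.b0_indices].mean(axis=-1) > 0
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != data.shape[:3]:
            raise ConfigurationError("mask shape does not match data")

    @classmethod
    def from_nifti(cls, dwi_path, bval_path, mask_path=None) -> "IVIMModel":
        from . import io as tio
        import nibabel as nib

        data, scheme, affine, header = tio.read_dwi(dwi_path, bval_path)
        mask = None
        if mask_path is not None:
            mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        model = cls(data, scheme, mask=mask)
        model.affine, model.header = affine, header
        return model

    def fit(self, method: str = "topopro", config: TopoProConfig = None,
            baseline_config: BaselineConfig = None, seed: int = None) -> "IVIMResults":
        """Fit every masked voxel; returns an :class:`IVIMResults`."""
        if method not in METHODS:
            raise ConfigurationError(
                f"unknown method {method!r}; choose from {METHODS}")
        config = config or TopoProConfig()
        if seed is not None:
            import dataclasses
            config = dataclasses.replace(config, seed=int(seed))
        if method == "topopro":
            maps = fit_volume(self.data, self.scheme, self.mask, config)
        else:
            nz = self.data.shape[2]
            f = np.zeros(self.data.shape[:3])
            D = np.zeros_like(f)
            Dstar = np.zeros_like(f)
            flags = np.zeros(self.data.shape[:3], dtype=np.uint8)
            for z in range(nz):
                out = fit_slice_with_method(
                    self.data[:, :, z, :], self.scheme, self.mask[:, :, z],
                    method, topo_config=config, base_config=baseline_config,
                    seed=config.seed)
                f[:, :, z], D[:, :, z], Dstar[:, :, z] = out["f"], out["D"], out["Dstar"]
                flags[:, :, z] = out["flags"]
            maps = ParameterMaps(f=f, D=D, Dstar=Dstar,
                                 residual=np.zeros_like(f),
                                 n_minima=np.zeros(f.shape, dtype=np.uint8),
                                 flags=flags, config=config, scheme=self.scheme)
        return IVIMResults(self, maps, method)


class IVIMResults:
    """Fitted parameter maps with diagnostics and a summary table."""

    def __init__(self, model: IVIMModel, maps: ParameterMaps, method: str):
        self.model = model
        self.maps = maps
        self.method = method

    @property
    def f(self) -> np.ndarray:
        return self.maps.f

    @property
    def D(self) -> np.ndarray:
        return self.maps.D

    @property
    def Dstar(self) -> np.ndarray:
        return self.maps.Dstar

    def to_dataframe(self) -> pd.DataFrame:
        """One row per fitted voxel: indices, parameters, diagnostics."""
        idx = np.argwhere(self.model.mask)
        rows = {
            "i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2],
            "f": self.maps.f[self.model.mask],
            "D": self.maps.D[self.model.mask],
            "Dstar": self.maps.Dstar[self.model.mask],
            "residual": self.maps.residual[self.model.mask],
            "flags": self.maps.flags[self.model.mask],
        }
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model.mask
        n = int(m.sum())
        quality_bits = 1 | 2 | 4 | 32  # degenerate, clipped, bad S0, empty voxel
        lines = [
            "IVIM fit results",
            "================",
            f"method:          {self.method}",
            f"voxels fitted:   {n}",
            f"b-values:        {self.model.scheme.m} "
            f"(max {self.model.scheme.bvalues.max():g} s/mm2)",
            f"flagged voxels:  {int(((self.maps.flags[m] & quality_bits) != 0).sum())}",
            "",
            f"{'parameter':<10}{'mean':>12}{'median':>12}{'min':>12}{'max':>12}",
        ]
        for name, arr in (("f", self.maps.f), ("D", self.maps.D),
                          ("Dstar", self.maps.Dstar)):
            v = arr[m]
            lines.append(f"{name:<10}{v.mean():>12.5g}{np.median(v):>12.5g}"
                         f"{v.min():>12.5g}{v.max():>12.5g}")
        return "\n".join(lines)

    def save(self, outdir, affine=None):
        from . import io as tio

        if affine is None:
            affine = getattr(self.model, "affine", np.eye(4))
        return tio.write_maps(self.maps, affine, outdir)
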