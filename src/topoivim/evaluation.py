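"""Quantitative comparison harness.

Normalized RMSE per parameter and slice against phantom ground truth,
method-to-method RMSE ratios, the alternating-b-value test-retest split,
and Pearson reliability between half-fits.

Normalized RMSE divides the root-mean-square error over the evaluation
mask by the ground-truth *range* over that mask (switchable to
mean-normalization); the normalization used is recorded in every report.
The evaluation mask is the tissue region (label != background);
background behaviour is reported separately as the mean absolute
estimate over background voxels.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import BaselineConfig, fit_bayesian, fit_nls, fit_segmented, fit_shgo_full
from .ivim import AcquisitionScheme, ConfigurationError
from .phantom import PhantomOutput
from .topopro import (
    FLAG_BAD_S0,
    TopoProConfig,
    fit_volume,
    normalize_signal,
    voxel_seed,
)

__all__ = [
    "MethodReport",
    "normalized_rmse",
    "rmse_ratio",
    "test_retest_split",
    "pearson_r",
    "fit_slice_with_method",
    "run_benchmark",
]

PARAMETERS = ("f", "D", "Dstar")


@dataclass
class MethodReport:
    """Per-parameter, per-slice normalized RMSE for one fitting method."""

    method: str
    table: pd.DataFrame  # columns: slice, snr, parameter, nrmse, background_mean_abs
    normalization: str = "range"
    runtime_s: float = 0.0

    def rmse(self, parameter: str, slice_index=None) -> float:
        t = self.table[self.table.parameter == parameter]
        if slice_index is not None:
            t = t[t["slice"] == slice_index]
        return float(t.nrmse.mean())

    @property
    def average_rmse(self) -> float:
        """Arithmetic mean of the per-parameter normalized RMSEs."""
        return float(np.mean([self.rmse(p) for p in PARAMETERS]))


def normalized_rmse(est, gt, mask, normalization: str = "range") -> float:
    """RMSE over the mask, normalized by the ground-truth range (or mean).

    A constant ground truth has zero range; the fallback divides by
    max(|gt|, eps) instead.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("evaluation mask is empty")
    e = np.asarray(est)[mask]
    g = np.asarray(gt)[mask]
    rmse = float(np.sqrt(np.mean((e - g) ** 2)))
    if normalization == "range":
        denom = float(g.max() - g.min())
    elif normalization == "mean":
        denom = float(abs(g.mean()))
    else:
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    if denom == 0.0:
        denom = max(float(np.max(np.abs(g))), np.finfo(float).eps)
    return rmse / denom


def rmse_ratio(report_a: MethodReport, report_b: MethodReport, parameter: str) -> float:
    """report_a's RMSE divided by report_b's, for one parameter (inf if b is 0)."""
    a, b = report_a.rmse(parameter), report_b.rmse(parameter)
    if b == 0.0:
        return float("inf")
    return a / b


def test_retest_split(data: np.ndarray, scheme: AcquisitionScheme):
    """Split along b-values into alternating halves (sorted ascending first).

    Even-ranked b-values go to half A, odd-ranked to half B. Each half
    must contain a b=0 entry; if one half lacks it (single-b0 schemes),
    the b=0 measurement is duplicated into that half and flagged.
    Returns ((data_a, scheme_a), (data_b, scheme_b), reassigned_flag).
    """
    data = np.asarray(data)
    if scheme.m < 8:
        raise ConfigurationError("need at least 8 b-values to split")
    order = np.argsort(scheme.bvalues, kind="stable")
    idx_a, idx_b = order[0::2], order[1::2]
    flag = False
    b = scheme.bvalues
    if not np.any(b[idx_b] == 0):
        idx_b = np.concatenate([[order[0]], idx_b])
        flag = True
    if not np.any(b[idx_a] == 0):  # cannot happen with ascending sort, kept for symmetry
        idx_a = np.concatenate([[order[0]], idx_a])
        flag = True
    half_a = (data[..., idx_a], AcquisitionScheme(b[idx_a]))
    half_b = (data[..., idx_b], AcquisitionScheme(b[idx_b]))
    return half_a, half_b, flag


def pearson_r(map_a, map_b, mask) -> float:
    """Product-moment correlation of two parameter maps over a mask."""
    mask = np.asarray(mask, dtype=bool)
    a = np.asarray(map_a)[mask]
    b = np.asarray(map_b)[mask]
    if a.size < 3:
        raise ConfigurationError("need at least 3 voxels to correlate")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def fit_slice_with_method(dwi_slice: np.ndarray, scheme: AcquisitionScheme,
                          mask2d: np.ndarray, method: str,
                          topo_config: TopoProConfig = None,
                          base_config: BaselineConfig = None,
                          seed: int = 0):
    """Fit one 2-D slice with a named method; returns dict of parameter maps.

    Methods: ``topopro`` (two-level pipeline), ``segmented``, ``bayesian``
    (initialized from segmented), ``nls`` (initialized from segmented),
    ``shgo`` (global optimizer on the full 3-D functional, no VarPro /
    penalty). A voxel that fails is left at zero; failures never abort
    the rest of the slice.
    """
    topo_config = topo_config or TopoProConfig(seed=seed)
    base_config = base_config or BaselineConfig(seed=seed)
    mask2d = np.asarray(mask2d, dtype=bool)
    shape = dwi_slice.shape[:2]
    if method == "topopro":
        maps = fit_volume(dwi_slice[:, :, None, :], scheme,
                          mask2d[:, :, None], topo_config)
        return {"f": maps.f[:, :, 0], "D": maps.D[:, :, 0],
                "Dstar": maps.Dstar[:, :, 0], "flags": maps.flags[:, :, 0]}
    out = {p: np.zeros(shape) for p in PARAMETERS}
    out["flags"] = np.zeros(shape, dtype=np.uint8)
    for i, j in np.argwhere(mask2d):
        raw = dwi_slice[i, j, :]
        if not np.any(raw):
            continue
        y, norm_flags = normalize_signal(raw, scheme)
        if norm_flags & FLAG_BAD_S0:
            continue
        vseed = voxel_seed(seed, int(np.ravel_multi_index((i, j), shape)))
        try:
            if method == "segmented":
                params, _ = fit_segmented(y, base_config)
            elif method == "bayesian":
                init, _ = fit_segmented(y, base_config)
                params, _, _ = fit_bayesian(y, init, replace(base_config, seed=vseed))
            elif method == "nls":
                init, _ = fit_segmented(y, base_config)
                params, _ = fit_nls(y, init, base_config.bounds)
            elif method == "shgo":
                params, _ = fit_shgo_full(y, replace(topo_config, seed=vseed))
            else:
                raise ConfigurationError(f"unknown method {method!r}")
        except ConfigurationError:
            raise
        except Exception:
            out["flags"][i, j] = 1
            continue
        out["f"][i, j], out["D"][i, j], out["Dstar"][i, j] = params.f, params.D, params.Dstar
    return out


def run_benchmark(phantom: PhantomOutput, methods, topo_config: TopoProConfig = None,
                  base_config: BaselineConfig = None, seed: int = 0,
                  normalization: str = "range"):
    """Fit every method on every phantom slice and tabulate normalized RMSE.

    Returns a list of :class:`MethodReport`; one method failing does not
    abort the others. The concatenated tables have one row per
    (method, slice, parameter).
    """
    gt = {"f": phantom.gt_f, "D": phantom.gt_D, "Dstar": phantom.gt_Dstar}
    nz = phantom.dwi.shape[2]
    reports = []
    for method in methods:
        rows = []
        t0 = time.perf_counter()
        for z in range(nz):
            mask2d = phantom.tissue_mask[:, :, z]
            bg2d = ~phantom.tissue_mask[:, :, z]
            maps = fit_slice_with_method(
                phantom.dwi[:, :, z, :], phantom.scheme, mask2d, method,
                topo_config=topo_config, base_config=base_config, seed=seed)
            for p in PARAMETERS:
                rows.append({
                    "slice": z,
                    "snr": phantom.spec.snr_per_slice[z],
                    "parameter": p,
                    "nrmse": normalized_rmse(maps[p], gt[p][:, :, z], mask2d,
                                             normalization),
                    "background_mean_abs": float(np.mean(np.abs(maps[p][bg2d])))
                    if bg2d.any() else 0.0,
                })
        reports.append(MethodReport(method=method, table=pd.DataFrame(rows),
                                    normalization=normalization,
                                    runtime_s=time.perf_counter() - t0))
    return reports
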