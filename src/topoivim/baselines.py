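"""Reference IVIM fitters: segmented two-stage, Bayesian MCMC, bounded NLS, plain SHGO.

These are the conventional estimators the topological fitter is compared
against. They share the conventional narrow bounds (f in [0, 0.9],
D in [0, 0.004], Dstar in [0, 0.1] mm2/s) and the b = 200 s/mm2
threshold separating the perfusion-sensitive low-b regime from the
diffusion-dominated high-b regime.

Rather than discarding out-of-bounds voxels and interpolating from
neighbors, every fitter here clips to bounds and raises a flag, so that
per-voxel comparisons stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from . import homotopt
from .ivim import (
    ConfigurationError,
    IVIMParams,
    VoxelSignal,
    canonicalize,
    full_residual,
    ivim_signal,
)
from .topopro import TopoProConfig

__all__ = [
    "BaselineConfig",
    "fit_segmented",
    "fit_bayesian",
    "fit_nls",
    "fit_shgo_full",
]


@dataclass(frozen=True)
class BaselineConfig:
    """Shared configuration of the conventional fitters."""

    b_threshold: float = 200.0  # s/mm2
    bounds_f: tuple = (0.0, 0.9)
    bounds_D: tuple = (0.0, 0.004)  # mm2/s
    bounds_Dstar: tuple = (0.0, 0.1)  # mm2/s
    burn_in: int = 1000
    n_samples: int = 5000
    proposal_scales: tuple = None  # default: 2% of each bound's width (f, D, Dstar)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_samples:
            raise ConfigurationError("burn_in must be smaller than n_samples")
        if self.proposal_scales is None:
            scales = tuple(0.02 * (hi - lo) for lo, hi in
                           (self.bounds_f, self.bounds_D, self.bounds_Dstar))
            object.__setattr__(self, "proposal_scales", scales)

    @property
    def bounds(self):
        return (self.bounds_f, self.bounds_D, self.bounds_Dstar)


def _clip(v, bounds):
    return float(np.clip(v, bounds[0], bounds[1]))


def fit_segmented(y: VoxelSignal, config: BaselineConfig = None):
    """Two-stage segmented fit. Returns (IVIMParams, degenerate_flag).

    Stage 1: ordinary least squares of log(y) against b restricted to
    b >= threshold; D is minus the slope and f = 1 - exp(intercept)
    (the perfusion compartment has decayed away at high b, so the
    intercept extrapolates the diffusion compartment back to b = 0).
    Stage 2: with f and D fixed, 1-D bounded minimization of the full
    squared misfit over Dstar on all points. Values are clipped to the
    configured bounds.
    """
    config = config or BaselineConfig()
    b = y.scheme.bvalues
    thr = config.b_threshold
    if not (b.min() < thr < b.max()):
        raise ConfigurationError(
            f"b_threshold {thr} must lie strictly inside the b range [{b.min()}, {b.max()}]")
    high = (b >= thr) & (y.y > 0)
    degenerate = False
    if high.sum() >= 2:
        slope, intercept = np.polyfit(b[high], np.log(y.y[high]), 1)
        D = _clip(-slope, config.bounds_D)
        f = _clip(1.0 - np.exp(intercept), config.bounds_f)
    else:
        # too few usable high-b points: mono-exponential fit on whatever is positive
        degenerate = True
        pos = y.y > 0
        if pos.sum() >= 2:
            slope = np.polyfit(b[pos], np.log(y.y[pos]), 1)[0]
            D = _clip(-slope, config.bounds_D)
        else:
            D = config.bounds_D[0]
        f = 0.0

    def stage2(Dstar):
        p = IVIMParams(f=f, D=D, Dstar=float(Dstar))
        return full_residual(p, y)

    lo, hi = config.bounds_Dstar
    res = minimize_scalar(stage2, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    Dstar = _clip(res.x, config.bounds_Dstar)
    params = IVIMParams(f=f, D=D, Dstar=Dstar)
    if Dstar < D:
        # canonical form swaps the compartments; flag if it leaves the bounds
        params = canonicalize(params)
        if not (config.bounds_D[0] <= params.D <= config.bounds_D[1]
                and config.bounds_Dstar[0] <= params.Dstar <= config.bounds_Dstar[1]):
            degenerate = True
    return params, degenerate


def _log_likelihood(x: np.ndarray, y: VoxelSignal) -> float:
    """Gaussian log-likelihood with the noise scale profiled out.

    sigma^2 is set to SSR/m at the current parameters, which collapses
    the likelihood to -m/2 * log(SSR) up to constants and keeps the
    chain three-dimensional.
    """
    p = IVIMParams(f=float(x[0]), D=float(x[1]), Dstar=float(x[2]))
    ssr = full_residual(p, y)
    m = y.scheme.m
    return -0.5 * m * np.log(max(ssr, 1e-300))


def fit_bayesian(y: VoxelSignal, init: IVIMParams, config: BaselineConfig = None):
    """Random-walk Metropolis with a flat prior on the configured bounds.

    Returns (posterior-mean IVIMParams, acceptance_rate, poor_mixing_flag).
    Proposals outside the bounds have zero prior mass and are always
    rejected. The first ``burn_in`` samples are discarded.
    """
    config = config or BaselineConfig()
    lo = np.array([config.bounds_f[0], config.bounds_D[0], config.bounds_Dstar[0]])
    hi = np.array([config.bounds_f[1], config.bounds_D[1], config.bounds_Dstar[1]])
    x = np.clip(init.as_array(), lo, hi)
    rng = np.random.default_rng(config.seed)
    scales = np.asarray(config.proposal_scales, dtype=float)
    ll = _log_likelihood(x, y)
    chain = np.empty((config.n_samples, 3))
    accepted = 0
    for i in range(config.n_samples):
        prop = x + rng.normal(size=3) * scales
        if np.all(prop >= lo) & np.all(prop <= hi):
            ll_prop = _log_likelihood(prop, y)
            if np.log(rng.uniform()) < ll_prop - ll:
                x, ll = prop, ll_prop
                accepted += 1
        chain[i] = x
    rate = accepted / config.n_samples
    mean = chain[config.burn_in:].mean(axis=0)
    params = IVIMParams(f=float(mean[0]), D=float(mean[1]), Dstar=float(mean[2]))
    return canonicalize(params), rate, rate < 0.01


def fit_nls(y: VoxelSignal, init: IVIMParams, bounds=None):
    """Bounded trust-region nonlinear least squares from ``init``.

    Returns (canonical IVIMParams, converged_flag). This is the
    conventional local solver; started in the wrong valley of a bimodal
    objective it converges to a spurious minimum.
    """
    if bounds is None:
        cfg = BaselineConfig()
        bounds = cfg.bounds
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x0 = np.clip(init.as_array(), lo, hi)

    def residuals(x):
        p = IVIMParams(f=float(np.clip(x[0], 0, 1)), D=float(x[1]), Dstar=float(x[2]))
        return ivim_signal(p, y.scheme) - y.y

    res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    params = IVIMParams(f=float(np.clip(res.x[0], 0, 1)),
                        D=float(res.x[1]), Dstar=float(res.x[2]))
    return canonicalize(params), bool(res.success)


def fit_shgo_full(y: VoxelSignal, config: TopoProConfig = None, seed=None):
    """Simplicial-homology global optimization of the full 3-D functional.

    No VarPro reduction, no penalty — the optimizer alone, applied
    directly to (f, D, Dstar). Serves as the ablation of the two-level
    pipeline.
    """
    config = config or TopoProConfig()
    seed = config.seed if seed is None else seed
    bounds = [config.bounds_f, config.bounds_D, config.bounds_Dstar]
    b = y.scheme.bvalues

    def batch(X):
        X = np.asarray(X, dtype=float)
        f = X[:, 0]
        sig = f[:, None] * np.exp(-np.outer(X[:, 2], b)) \
            + (1.0 - f[:, None]) * np.exp(-np.outer(X[:, 1], b))
        r = y.y[None, :] - sig
        return np.einsum("ij,ij->i", r, r)

    res = homotopt.shgo_minimize(lambda x: float(batch(np.asarray(x)[None, :])[0]),
                                 bounds, n_points=config.n_points_level1,
                                 seed=seed, batch=batch)
    params = IVIMParams(f=float(np.clip(res.x[0], 0, 1)),
                        D=float(res.x[1]), Dstar=float(res.x[2]))
    return canonicalize(params), res
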