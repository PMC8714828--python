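"""Two-level topological IVIM fitting (TopoPro).

Level 1 minimizes the VarPro *reduced* functional — the misfit after the
perfusion fraction has been projected out — over the 2-D box of rates
(D, Dstar) with the simplicial-homology global optimizer. The reduced
surface is better conditioned than the full 3-D problem and its minima
are better defined, so the optimizer can enumerate all plausible rate
pairs (typically the two valleys the compartment-swap symmetry creates).

Level 2 refines the best Level-1 candidate on the full 3-D functional
(f, D, Dstar), restricted to a box around the Level-1 point, with an
additive penalty active in the low-perfusion sub-domain::

    penalty = lambda * Dstar**2   when f <= f_threshold (default 0.2)

At small f the signal barely depends on Dstar — the objective has a flat
valley of equally good Dstar values — and the penalty selects the
physically meaningful end of that valley instead of an arbitrary point.
The reported residual never includes the penalty term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import homotopt
from .ivim import (
    RANK_TOL,
    AcquisitionScheme,
    ConfigurationError,
    IVIMParams,
    VoxelSignal,
    design_matrix,
    full_residual,
    project_linear,
    reduced_residual,
    reduced_residual_batch,
)

__all__ = [
    "TopoProConfig",
    "VoxelFitResult",
    "Level1Result",
    "ParameterMaps",
    "penalty",
    "physical_form",
    "normalize_signal",
    "fit_voxel_level1",
    "fit_voxel_level2",
    "fit_voxel",
    "fit_volume",
    "FLAG_DEGENERATE",
    "FLAG_CLIPPED",
    "FLAG_BAD_S0",
    "FLAG_LEVEL2_NO_IMPROVE",
    "FLAG_NOT_CONVERGED",
    "FLAG_EMPTY_VOXEL",
]

# diagnostics bitmask (stored as uint8 in ParameterMaps.flags)
FLAG_DEGENERATE = 1  # rank-deficient projection / optimizer fallback
FLAG_CLIPPED = 2  # negative raw values clipped during normalization
FLAG_BAD_S0 = 4  # non-positive b=0 reference
FLAG_LEVEL2_NO_IMPROVE = 8  # Level-2 did not beat Level-1; Level-1 kept
FLAG_NOT_CONVERGED = 16  # local refinement hit its iteration cap
FLAG_EMPTY_VOXEL = 32  # all-zero voxel inside the mask


@dataclass(frozen=True)
class TopoProConfig:
    """Configuration of the two-level fit.

    Bounds are deliberately wide (much wider than the conventional
    baseline bounds) — the global optimizer only needs a compact box,
    not a tight prior.
    """

    bounds_D: tuple = (1e-5, 0.02)  # mm2/s
    bounds_Dstar: tuple = (1e-5, 0.2)  # mm2/s
    bounds_f: tuple = (0.0, 1.0)
    n_points_level1: int = 64
    n_points_level2: int = 32
    # largest power of ten for which the penalty's worst-case noiseless bias
    # in the well-posed regime (f >= 0.05, Dstar <= 0.04, 54-point scheme)
    # stays below the 0.5% recovery floor; see the methods note
    penalty_weight: float = 0.001
    # noise-adaptive part: the effective weight grows with the voxel's
    # Level-1 misfit so that the penalty at the Dstar upper bound equals
    # penalty_scale times that misfit — strong in noisy flat valleys,
    # negligible on noiseless well-posed voxels
    penalty_scale: float = 0.5
    penalty_f_threshold: float = 0.2
    level2_box_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("bounds_D", self.bounds_D),
                               ("bounds_Dstar", self.bounds_Dstar),
                               ("bounds_f", self.bounds_f)):
            if not (0 <= lo < hi):
                raise ConfigurationError(f"{name} must satisfy 0 <= lo < hi, got {(lo, hi)}")
        if not (0.0 <= self.bounds_f[0] and self.bounds_f[1] <= 1.0):
            raise ConfigurationError("bounds_f must lie within [0, 1]")
        if not 0.0 < self.penalty_f_threshold < 1.0:
            raise ConfigurationError("penalty_f_threshold must be in (0, 1)")
        if self.penalty_weight < 0 or self.penalty_scale < 0:
            raise ConfigurationError("penalty weights must be >= 0")


@dataclass
class Level1Result:
    s_hat: tuple  # (D, Dstar) at the best reduced-functional minimum
    f_hat: float
    minima: list  # all deduplicated refined ((D, Dstar), value)
    reduced_value: float
    degenerate: bool = False


@dataclass
class VoxelFitResult:
    params: IVIMParams  # canonical
    residual: float  # unpenalized ||y - model||^2
    n_minima_level1: int
    degenerate_flag: bool = False
    converged_flag: bool = True
    flags: int = 0


@dataclass
class ParameterMaps:
    """Per-voxel fitted parameter volumes plus fit diagnostics."""

    f: np.ndarray
    D: np.ndarray
    Dstar: np.ndarray
    residual: np.ndarray
    n_minima: np.ndarray  # uint8
    flags: np.ndarray  # uint8 bitmask, see FLAG_* constants
    config: TopoProConfig = None
    scheme: AcquisitionScheme = None


def penalty(params: IVIMParams, config: TopoProConfig) -> float:
    """Low-perfusion penalty: lambda * Dstar^2 when f <= threshold, else 0.

    Inside the fit this is evaluated on the physical (minority-perfusion)
    representative of the swap symmetry — see :func:`physical_form` — so
    the optimizer cannot dodge it by mirroring into f -> 1 - f.
    """
    if params.f <= config.penalty_f_threshold:
        return config.penalty_weight * params.Dstar ** 2
    return 0.0


#: relative rate difference below which (D, Dstar) counts as the symmetry axis;
#: compartments with a rate ratio this close are not resolvable by an IVIM
#: acquisition, and the misfit across the band is below refinement tolerance
AXIS_RTOL = 0.05


def physical_form(params: IVIMParams) -> IVIMParams:
    """The minority-perfusion representative of the swap symmetry (f <= 1/2).

    The perfusion compartment is the minority compartment in tissue, so
    of the two signal-equivalent representations (f, D, Dstar) and
    (1-f, Dstar, D) the one with f <= 1/2 is the physical reading. In
    the well-posed regime it coincides with the Dstar >= D canonical
    form; they differ only at the degenerate boundary (f near 0 or 1)
    where one rate is unidentifiable and the low-perfusion penalty pins
    the pseudo-diffusion rate toward zero.

    On and near the symmetry axis D == Dstar the fraction is
    unidentifiable (the signal is mono-exponential for every f, up to a
    rate difference no acquisition resolves); the representative there
    is f = 0.
    """
    if abs(params.Dstar - params.D) <= AXIS_RTOL * max(params.D, params.Dstar):
        return IVIMParams(f=0.0, D=params.D, Dstar=params.Dstar)
    if params.f > 0.5 or (params.f == 0.5 and params.Dstar < params.D):
        return params.swapped()
    return params


def normalize_signal(raw, scheme: AcquisitionScheme):
    """Normalize a raw decay curve by the mean of its b=0 entries.

    Negative normalized values are clipped to zero (they are noise
    excursions below the floor of a magnitude signal). Returns
    (VoxelSignal, flags bitmask); a non-positive S0 yields an all-zero
    signal with FLAG_BAD_S0.
    """
    raw = np.asarray(raw, dtype=float)
    b0_idx = scheme.b0_indices
    if b0_idx.size == 0:  # defensive; AcquisitionScheme already requires one
        raise ConfigurationError("scheme has no b=0 entry to normalize by")
    if raw.size != scheme.m:
        raise ConfigurationError(f"signal length {raw.size} != scheme length {scheme.m}")
    flags = 0
    s0 = float(np.mean(raw[b0_idx]))
    if s0 <= 0:
        return VoxelSignal(np.zeros(scheme.m), scheme), flags | FLAG_BAD_S0
    y = raw / s0
    if np.any(y < 0):
        flags |= FLAG_CLIPPED
        y = np.clip(y, 0.0, None)
    return VoxelSignal(y, scheme), flags


def _require_fittable(y: VoxelSignal) -> None:
    if y.scheme.m < 4:
        raise ConfigurationError("need at least 4 b-values to fit 3 parameters")
    b0_mean = float(np.mean(y.y[y.scheme.b0_indices]))
    if abs(b0_mean - 1.0) > 1e-3:
        raise ConfigurationError(
            f"signal is not normalized (mean b=0 value {b0_mean:.4f} != 1); "
            "run normalize_signal first"
        )


def _mono_exponential_fallback(y: VoxelSignal, config: TopoProConfig):
    """Log-linear single-compartment fit (f = 0) used when the optimizer fails."""
    b = y.scheme.bvalues
    pos = y.y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(b[pos], np.log(y.y[pos]), 1)[0]
        D = float(np.clip(-slope, *config.bounds_D))
    else:
        D = config.bounds_D[0]
    return (D, max(D, config.bounds_Dstar[0])), 0.0


def _make_reduced_objective(y: VoxelSignal):
    """Fast scalar closure for the reduced functional (hot path of refinement)."""
    b = y.scheme.bvalues
    yv = y.y

    def objective(s):
        phi1 = np.exp(-b * s[1])
        phi2 = np.exp(-b * s[0])
        d = phi1 - phi2
        den = d @ d
        f = 0.0 if den <= RANK_TOL else min(max((d @ (yv - phi2)) / den, 0.0), 1.0)
        r = yv - (f * phi1 + (1.0 - f) * phi2)
        return r @ r

    return objective


def fit_voxel_level1(y: VoxelSignal, config: TopoProConfig, seed=None) -> Level1Result:
    """Global minimization of the reduced functional over the (D, Dstar) box."""
    _require_fittable(y)
    seed = config.seed if seed is None else seed
    bounds = [config.bounds_D, config.bounds_Dstar]
    try:
        res = homotopt.shgo_minimize(
            _make_reduced_objective(y), bounds,
            n_points=config.n_points_level1, seed=seed,
            batch=lambda S: reduced_residual_batch(S, y),
        )
    except ConfigurationError:
        s_hat, f_hat = _mono_exponential_fallback(y, config)
        return Level1Result(s_hat=s_hat, f_hat=f_hat, minima=[],
                            reduced_value=reduced_residual(s_hat, y), degenerate=True)
    s_hat = tuple(res.x)
    f_hat = project_linear(design_matrix(s_hat, y.scheme), y)
    if f_hat > 0.5:  # mirror branch of the swap symmetry; report the physical one
        s_hat = (s_hat[1], s_hat[0])
        f_hat = 1.0 - f_hat
    return Level1Result(s_hat=s_hat, f_hat=f_hat, minima=res.minima,
                        reduced_value=res.fun)


def effective_penalty_weight(config: TopoProConfig, level1_residual: float) -> float:
    """Per-voxel penalty weight, adapted to the voxel's noise level.

    The flat Dstar valleys that make low-perfusion voxels unstable are
    only 'flat' relative to the misfit the noise allows; the penalty is
    therefore scaled so that its value at the Dstar upper bound is
    ``penalty_scale`` times the Level-1 misfit, plus the constant floor
    ``penalty_weight`` that pins exactly degenerate (noiseless) valleys.
    """
    hi = config.bounds_Dstar[1]
    return config.penalty_weight + config.penalty_scale * max(level1_residual, 0.0) / hi ** 2


def _unit_penalty(params: IVIMParams, config: TopoProConfig) -> float:
    """Unit-weight penalty of the physical representative (pseudo-rate^2 or 0)."""
    p = physical_form(params)
    if p.f <= config.penalty_f_threshold:
        return p.Dstar ** 2
    return 0.0


def _penalized_batch(X: np.ndarray, y: VoxelSignal, config: TopoProConfig,
                     lam: float) -> np.ndarray:
    """Vectorized full residual + penalty over an (N, 3) array of (f, D, Dstar) rows."""
    X = np.asarray(X, dtype=float)
    b = y.scheme.bvalues
    f = X[:, 0]
    sig = f[:, None] * np.exp(-np.outer(X[:, 2], b)) \
        + (1.0 - f[:, None]) * np.exp(-np.outer(X[:, 1], b))
    r = y.y[None, :] - sig
    ssr = np.einsum("ij,ij->i", r, r)
    # penalty on the minority-perfusion representative (swap-invariant);
    # points on the symmetry axis D == Dstar count as f = 0
    D, Ds = X[:, 1], X[:, 2]
    mirrored = f > 0.5
    f_low = np.where(mirrored, 1.0 - f, f)
    on_axis = np.abs(Ds - D) <= AXIS_RTOL * np.maximum(D, Ds)
    f_low = np.where(on_axis, 0.0, f_low)
    pseudo_rate = np.where(mirrored & ~on_axis, D, Ds)
    pen = np.where(f_low <= config.penalty_f_threshold, lam * pseudo_rate ** 2, 0.0)
    return ssr + pen


def fit_voxel_level2(y: VoxelSignal, init, config: TopoProConfig, seed=None,
                     n_minima_level1: int = 0, extra_flags: int = 0) -> VoxelFitResult:
    """Penalized full-functional refinement inside a box around the Level-1 point.

    The box half-width per dimension is ``level2_box_fraction`` times the
    global bound width, intersected with the global bounds. If the
    refinement does not improve the unpenalized misfit, the Level-1
    solution is kept and flagged.
    """
    seed = config.seed if seed is None else seed
    f0, (D0, Ds0) = float(init[0]), (float(init[1][0]), float(init[1][1]))
    flags = int(extra_flags)

    global_bounds = [config.bounds_f, config.bounds_D, config.bounds_Dstar]
    center = [f0, D0, Ds0]
    box = []
    for c, (lo, hi) in zip(center, global_bounds):
        half = config.level2_box_fraction * (hi - lo)
        box.append((max(lo, c - half), min(hi, c + half)))

    level1_params = physical_form(IVIMParams(f=np.clip(f0, 0.0, 1.0), D=D0, Dstar=Ds0))
    level1_resid = full_residual(level1_params, y)
    lam = effective_penalty_weight(config, level1_resid)

    b = y.scheme.bvalues
    yv = y.y
    thr = config.penalty_f_threshold

    def objective(x):
        f, D, Ds = x[0], x[1], x[2]
        r = yv - (f * np.exp(-b * Ds) + (1.0 - f) * np.exp(-b * D))
        ssr = r @ r
        if abs(Ds - D) <= AXIS_RTOL * max(D, Ds):
            f_low, rate = 0.0, Ds
        elif f > 0.5:
            f_low, rate = 1.0 - f, D
        else:
            f_low, rate = f, Ds
        if f_low <= thr:
            ssr += lam * rate * rate
        return ssr

    try:
        res = homotopt.shgo_minimize(
            objective, box, n_points=config.n_points_level2, seed=seed,
            batch=lambda X: _penalized_batch(X, y, config, lam),
        )
    except ConfigurationError:
        return VoxelFitResult(params=level1_params, residual=level1_resid,
                              n_minima_level1=n_minima_level1, degenerate_flag=True,
                              converged_flag=False, flags=flags | FLAG_DEGENERATE)

    cand = physical_form(IVIMParams(f=float(np.clip(res.x[0], 0.0, 1.0)),
                                    D=float(res.x[1]), Dstar=float(res.x[2])))
    cand_resid = full_residual(cand, y)
    if cand_resid <= level1_resid:
        params, resid = cand, cand_resid
    else:
        params, resid = level1_params, level1_resid
        flags |= FLAG_LEVEL2_NO_IMPROVE
    return VoxelFitResult(params=params, residual=resid,
                          n_minima_level1=n_minima_level1,
                          degenerate_flag=bool(flags & FLAG_DEGENERATE),
                          converged_flag=not flags & FLAG_LEVEL2_NO_IMPROVE,
                          flags=flags)


def fit_voxel(y: VoxelSignal, config: TopoProConfig, seed=None,
              extra_flags: int = 0) -> VoxelFitResult:
    """Full per-voxel TopoPro pipeline: Level-1 then Level-2.

    When Level-1 retains several reduced-functional minima, the one with
    the lowest *penalized* full residual seeds Level-2; the rest are kept
    in the diagnostics count.
    """
    lvl1 = fit_voxel_level1(y, config, seed=seed)
    flags = int(extra_flags) | (FLAG_DEGENERATE if lvl1.degenerate else 0)

    # pick the Level-1 candidate whose (projected-f, s) has the lowest penalized score
    candidates = lvl1.minima if lvl1.minima else [(np.asarray(lvl1.s_hat), lvl1.reduced_value)]
    scored = []
    for s_cand, _ in candidates:
        s_cand = tuple(np.atleast_1d(s_cand))
        f_cand = project_linear(design_matrix(s_cand, y.scheme), y)
        p = physical_form(IVIMParams(f=f_cand, D=s_cand[0], Dstar=s_cand[1]))
        scored.append(((f_cand, s_cand), full_residual(p, y), _unit_penalty(p, config)))
    lam = effective_penalty_weight(config, min(r for _, r, _ in scored))
    best_init = min(scored, key=lambda t: t[1] + lam * t[2])[0]
    return fit_voxel_level2(y, best_init, config,
                            seed=None if seed is None else seed + 1,
                            n_minima_level1=len(candidates), extra_flags=flags)


def voxel_seed(base_seed: int, flat_index: int) -> int:
    """Deterministic per-voxel seed; kept below 2**31 for portability."""
    return int((int(base_seed) + int(flat_index)) % 2_147_483_647)


def fit_volume(data: np.ndarray, scheme: AcquisitionScheme, mask=None,
               config: TopoProConfig = None, progress=False) -> ParameterMaps:
    """Fit every masked voxel of a 4-D volume: normalize -> Level-1 -> Level-2.

    Voxels outside the mask are zero in every output map. Per-voxel seeds
    are derived from ``config.seed`` plus the flat voxel index, so runs
    are reproducible and order-independent.
    """
    config = config or TopoProConfig()
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ConfigurationError(f"expected a 4-D volume, got shape {data.shape}")
    if data.shape[-1] != scheme.m:
        raise ConfigurationError(
            f"4th dimension {data.shape[-1]} != number of b-values {scheme.m}")
    spatial = data.shape[:3]
    if mask is None:
        mask = data[..., scheme.b0_indices].mean(axis=-1) > 0
    mask = np.asarray(mask).astype(bool)
    if mask.shape != spatial:
        raise ConfigurationError(f"mask shape {mask.shape} != spatial shape {spatial}")

    out = ParameterMaps(
        f=np.zeros(spatial), D=np.zeros(spatial), Dstar=np.zeros(spatial),
        residual=np.zeros(spatial), n_minima=np.zeros(spatial, dtype=np.uint8),
        flags=np.zeros(spatial, dtype=np.uint8), config=config, scheme=scheme,
    )
    it = np.argwhere(mask)
    for idx in it:
        i, j, k = (int(v) for v in idx)
        raw = data[i, j, k, :]
        flat = int(np.ravel_multi_index((i, j, k), spatial))
        if not np.any(raw):
            out.flags[i, j, k] = FLAG_EMPTY_VOXEL
            continue
        y, norm_flags = normalize_signal(raw, scheme)
        if norm_flags & FLAG_BAD_S0:
            out.flags[i, j, k] = norm_flags
            continue
        fit = fit_voxel(y, config, seed=voxel_seed(config.seed, flat),
                        extra_flags=norm_flags)
        out.f[i, j, k] = fit.params.f
        out.D[i, j, k] = fit.params.D
        out.Dstar[i, j, k] = fit.params.Dstar
        out.residual[i, j, k] = fit.residual
        out.n_minima[i, j, k] = min(fit.n_minima_level1, 255)
        out.flags[i, j, k] = fit.flags & 0xFF
    return out
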