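"""Bi-exponential IVIM signal model and its variable-projection reduction.

The intravoxel incoherent motion (IVIM) model decomposes the normalized
diffusion-MRI signal of a voxel into a tissue-water diffusion compartment
and a capillary pseudo-diffusion (perfusion) compartment::

    S(b) / S0 = f * exp(-b * Dstar) + (1 - f) * exp(-b * D)

where ``b`` is the diffusion weighting in s/mm2, ``f`` the perfusion
(volume) fraction, ``D`` the tissue diffusion coefficient and ``Dstar``
the pseudo-diffusion coefficient, both in mm2/s so that ``b * D`` is
dimensionless.

The model is separable: for fixed rates ``s = (D, Dstar)`` the signal is
linear in the compartment fractions. Variable projection (VarPro)
eliminates the linear fraction by orthogonal projection, leaving a
*reduced* residual functional over the two rates only. Because the
fractions sum to one, the projection here is a scalar least-squares
problem: writing ``phi1 = exp(-b*Dstar)`` and ``phi2 = exp(-b*D)``,

    y - phi2 = (phi1 - phi2) * f

is solved for ``f`` in closed form and clipped to [0, 1].

The bi-exponential form is symmetric under swapping compartments,
``(f, D, Dstar) -> (1 - f, Dstar, D)``; the canonical representative has
``Dstar >= D``. This swap symmetry is the root cause of the bimodal
objective surfaces the global optimizer has to deal with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "IVIMParams",
    "VoxelSignal",
    "DesignMatrix",
    "InvalidParameterError",
    "ConfigurationError",
    "ivim_signal",
    "design_matrix",
    "project_linear",
    "reduced_residual",
    "reduced_residual_batch",
    "full_residual",
    "canonicalize",
]

#: singular values (relative to the largest) below this are treated as zero
RANK_TOL = 1e-12


class InvalidParameterError(ValueError):
    """A model parameter violates its domain (non-finite, negative rate, f outside [0, 1])."""


class ConfigurationError(ValueError):
    """A configuration value is inconsistent (bad bounds, missing b=0, unknown key...)."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """The b-value vector of a diffusion acquisition.

    Parameters
    ----------
    bvalues : array-like
        Diffusion weightings in s/mm2. All entries must be non-negative
        and at least one must equal zero (the normalization reference).
    """

    bvalues: np.ndarray

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        if b.ndim != 1:
            raise ConfigurationError("bvalues must be a 1-D vector")
        if not np.all(np.isfinite(b)):
            raise ConfigurationError("bvalues must be finite")
        if np.any(b < 0):
            raise ConfigurationError("bvalues must be non-negative")
        if not np.any(b == 0):
            raise ConfigurationError("scheme must contain at least one b=0 entry")
        b.setflags(write=False)
        object.__setattr__(self, "bvalues", b)

    @property
    def m(self) -> int:
        """Number of measurements."""
        return self.bvalues.size

    @property
    def b0_indices(self) -> np.ndarray:
        """Indices of the b=0 entries."""
        return np.flatnonzero(self.bvalues == 0)


@dataclass(frozen=True)
class IVIMParams:
    """One voxel's parameter triple (f, D, Dstar).

    f is the dimensionless perfusion fraction in [0, 1]; D and Dstar are
    non-negative rates in mm2/s. The canonical form has ``Dstar >= D``.
    """

    f: float
    D: float
    Dstar: float

    def __post_init__(self) -> None:
        for name, v in (("f", self.f), ("D", self.D), ("Dstar", self.Dstar)):
            if not np.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        if not 0.0 <= self.f <= 1.0:
            raise InvalidParameterError(f"f must be in [0, 1], got {self.f}")
        if self.D < 0 or self.Dstar < 0:
            raise InvalidParameterError(
                f"rates must be non-negative, got D={self.D}, Dstar={self.Dstar}"
            )

    @property
    def is_canonical(self) -> bool:
        return self.Dstar >= self.D

    def swapped(self) -> "IVIMParams":
        """The symmetry partner (1 - f, Dstar <-> D); same predicted signal."""
        return IVIMParams(f=1.0 - self.f, D=self.Dstar, Dstar=self.D)

    def as_array(self) -> np.ndarray:
        return np.array([self.f, self.D, self.Dstar], dtype=float)


def canonicalize(params: IVIMParams) -> IVIMParams:
    """Resolve the compartment-swap symmetry: return the representative with Dstar >= D.

    ``ivim_signal`` is invariant under this map.
    """
    if params.Dstar < params.D:
        return params.swapped()
    return params


@dataclass(frozen=True)
class VoxelSignal:
    """A normalized (S/S0) signal vector together with its acquisition scheme."""

    y: np.ndarray
    scheme: AcquisitionScheme

    def __post_init__(self) -> None:
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if y.size != self.scheme.m:
            raise ConfigurationError(
                f"signal length {y.size} != number of b-values {self.scheme.m}"
            )
        if not np.all(np.isfinite(y)):
            raise InvalidParameterError("signal contains non-finite entries")
        if np.any(y < 0):
            raise InvalidParameterError("normalized signal must be non-negative")
        y.setflags(write=False)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class DesignMatrix:
    """m x 2 basis evaluation phi(s): columns exp(-b*Dstar), exp(-b*D)."""

    phi: np.ndarray
    s: tuple  # (D, Dstar) the matrix was built from

    @property
    def perfusion_column(self) -> np.ndarray:
        return self.phi[:, 0]

    @property
    def diffusion_column(self) -> np.ndarray:
        return self.phi[:, 1]

    @property
    def is_degenerate(self) -> bool:
        """True when the two columns are numerically indistinguishable (D == Dstar)."""
        d = self.phi[:, 0] - self.phi[:, 1]
        return float(d @ d) <= RANK_TOL


def ivim_signal(params: IVIMParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Evaluate the bi-exponential IVIM model on a scheme.

    Returns the dimensionless signal f*exp(-b*Dstar) + (1-f)*exp(-b*D);
    exactly 1 at b = 0.
    """
    b = scheme.bvalues
    return params.f * np.exp(-b * params.Dstar) + (1.0 - params.f) * np.exp(-b * params.D)


def design_matrix(s, scheme: AcquisitionScheme) -> DesignMatrix:
    """Build the VarPro design matrix phi(s) for rates s = (D, Dstar).

    Column 0 is the perfusion basis exp(-b*Dstar), column 1 the diffusion
    basis exp(-b*D). D == Dstar gives a rank-1 matrix; this is permitted
    (the point lies on the swap-symmetry axis) and flagged downstream.
    """
    D, Dstar = float(s[0]), float(s[1])
    if not (np.isfinite(D) and np.isfinite(Dstar)):
        raise InvalidParameterError(f"rates must be finite, got {s!r}")
    if D < 0 or Dstar < 0:
        raise InvalidParameterError(f"rates must be non-negative, got {s!r}")
    b = scheme.bvalues
    phi = np.column_stack([np.exp(-b * Dstar), np.exp(-b * D)])
    return DesignMatrix(phi=phi, s=(D, Dstar))


def _project_f(phi1: np.ndarray, phi2: np.ndarray, y: np.ndarray):
    """Closed-form sum-to-one projection. Returns (f, degenerate_flag)."""
    d = phi1 - phi2
    den = float(d @ d)
    if den <= RANK_TOL:
        # on the symmetry axis f is unidentifiable; report the canonical f = 0
        return 0.0, True
    f = float(d @ (y - phi2)) / den
    return min(max(f, 0.0), 1.0), False


def project_linear(phi: DesignMatrix, y) -> float:
    """Perfusion fraction implied by the least-squares projection of y onto phi.

    Solves y - phi2 = (phi1 - phi2) * f for scalar f (the sum-to-one
    parameterization of the linear fractions) and clips to [0, 1]. On the
    degenerate axis D == Dstar the fraction is unidentifiable and 0 is
    returned (see :class:`DesignMatrix`).
    """
    yv = y.y if isinstance(y, VoxelSignal) else np.asarray(y, dtype=float)
    f, _ = _project_f(phi.phi[:, 0], phi.phi[:, 1], yv)
    return f


def full_residual(params: IVIMParams, y: VoxelSignal) -> float:
    """Squared l2 misfit ||y - ivim_signal(params)||^2."""
    r = y.y - ivim_signal(params, y.scheme)
    return float(r @ r)


def reduced_residual(s, y: VoxelSignal) -> float:
    """VarPro reduced functional: misfit after projecting out the fraction.

    Equals min over f in [0, 1] of ``full_residual((f, s), y)`` — the
    1-D problem in f is quadratic, so the clipped closed-form solution is
    its exact constrained minimizer.
    """
    phi = design_matrix(s, y.scheme)
    f, _ = _project_f(phi.phi[:, 0], phi.phi[:, 1], y.y)
    r = y.y - (f * phi.phi[:, 0] + (1.0 - f) * phi.phi[:, 1])
    return float(r @ r)


def reduced_residual_batch(S: np.ndarray, y: VoxelSignal) -> np.ndarray:
    """Vectorized :func:`reduced_residual` over an (N, 2) array of (D, Dstar) rows.

    Used by the global optimizer to evaluate a whole sampling set at once.
    """
    S = np.asarray(S, dtype=float)
    b = y.scheme.bvalues
    phi1 = np.exp(-np.outer(S[:, 1], b))  # (N, m) perfusion basis
    phi2 = np.exp(-np.outer(S[:, 0], b))
    d = phi1 - phi2
    den = np.einsum("ij,ij->i", d, d)
    num = np.einsum("ij,ij->i", d, y.y[None, :] - phi2)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(den > RANK_TOL, num / np.maximum(den, RANK_TOL), 0.0)
    f = np.clip(f, 0.0, 1.0)
    resid = y.y[None, :] - (f[:, None] * phi1 + (1.0 - f[:, None]) * phi2)
    return np.einsum("ij,ij->i", resid, resid)
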