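"""Shepp-Logan IVIM digital phantom with multi-coil noise.

The phantom rasterizes the classic ten-ellipse Shepp-Logan head geometry
and bins it into six tissue classes, assigns each class a ground-truth
(f, D, Dstar) triple, simulates the bi-exponential decay over a b-value
scheme, and corrupts the data with the noise of a multi-channel
acquisition: complex Gaussian noise added per coil (after weighting by a
smooth complex coil-sensitivity map) followed by sum-of-squares
combination, which makes the background magnitude chi-distributed with
2 * n_coils degrees of freedom.

Binning of the Shepp-Logan ellipses to classes (later entries override
earlier ones where ellipses overlap):

====================  =========================================
class                 ellipses
====================  =========================================
cavity                rim between the outer two ellipses (skull)
normal tissue         interior of the second ellipse (brain)
CSF                   the two rotated ventricle ellipses
high-perfused tumor   the large upper blob
infiltrating tumor    the two mid-line small blobs
low-perfused tumor    the three small bottom blobs
====================  =========================================

SNR is defined per slice as the mean b=0 magnitude over the
normal-tissue region divided by the per-channel Gaussian sigma; sigma is
held constant across b-values within a slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ivim import AcquisitionScheme, ConfigurationError

__all__ = [
    "PhantomSpec",
    "PhantomOutput",
    "CLASS_NAMES",
    "DEFAULT_TISSUE_TABLE",
    "ivim_bvalues",
    "shepp_logan_labels",
    "ellipse_contains",
    "assign_params",
    "simulate_dwi_noiseless",
    "coil_sensitivity",
    "add_noise_sos",
    "make_phantom",
]

# (half-axis a, half-axis b, center x0, center y0, angle degrees) in [-1, 1]^2 coords
SHEPP_LOGAN_ELLIPSES = (
    (0.6900, 0.9200, 0.00, 0.0000, 0.0),   # outer skull
    (0.6624, 0.8740, 0.00, -0.0184, 0.0),  # brain
    (0.1100, 0.3100, 0.22, 0.0000, -18.0),  # right ventricle
    (0.1600, 0.4100, -0.22, 0.0000, 18.0),  # left ventricle
    (0.2100, 0.2500, 0.00, 0.3500, 0.0),   # large upper blob
    (0.0460, 0.0460, 0.00, 0.1000, 0.0),   # mid-line blob
    (0.0460, 0.0460, 0.00, -0.1000, 0.0),  # mid-line blob
    (0.0460, 0.0230, -0.08, -0.6050, 0.0),  # bottom blob
    (0.0230, 0.0230, 0.00, -0.6060, 0.0),  # bottom blob
    (0.0230, 0.0460, 0.06, -0.6050, 0.0),  # bottom blob
)

CLASS_NAMES = (
    "normal",
    "infiltrating_tumor",
    "low_perfused_tumor",
    "high_perfused_tumor",
    "cavity",
    "csf",
)
LABELS = {name: i + 1 for i, name in enumerate(CLASS_NAMES)}  # 0 = background

#: ground-truth (f, D mm2/s, Dstar mm2/s) per class; literature-plausible defaults,
#: fully configurable through PhantomSpec.tissue_table
DEFAULT_TISSUE_TABLE = {
    "normal": (0.10, 0.0008, 0.010),
    "infiltrating_tumor": (0.15, 0.0010, 0.015),
    "low_perfused_tumor": (0.05, 0.0012, 0.008),
    "high_perfused_tumor": (0.30, 0.0012, 0.030),
    "cavity": (0.00, 0.0030, 0.000),
    "csf": (0.00, 0.0030, 0.000),
}


def ivim_bvalues(n: int = 54, n_b0: int = 2, b_low_max: float = 90.0,
                 b_max: float = 1000.0) -> np.ndarray:
    """IVIM b-value placement: repeated b0s, a perfusion-sensitive low-b
    segment up to ``b_low_max``, and a linear high-b segment up to ``b_max``.

    The default (n=54) gives 2 x b0 + 9 values 10..90 + 43 values
    100..1000 s/mm2. The low:high proportion is preserved for other n.
    """
    if n < n_b0 + 5:
        raise ConfigurationError(f"need at least {n_b0 + 5} b-values, got {n}")
    n_low = max(3, round((n - n_b0) * 9 / 52))
    n_high = n - n_b0 - n_low
    low = np.linspace(b_low_max / n_low, b_low_max, n_low)
    high = np.linspace(100.0, b_max, n_high)
    return np.concatenate([np.zeros(n_b0), low, high])


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue table, acquisition and noise model of the phantom.

    Defaults reproduce a 256 x 256 x 5 volume at 54 b-values with one
    SNR per slice (2, 5, 10, 20, 50) and an 8-channel coil.
    """

    shape: tuple = (256, 256, 5)
    tissue_table: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_TABLE))
    bvalues: np.ndarray = field(default_factory=ivim_bvalues)
    snr_per_slice: tuple = (2.0, 5.0, 10.0, 20.0, 50.0)
    n_coils: int = 8
    s0: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ConfigurationError("shape must be (nx, ny, nslices)")
        if len(self.snr_per_slice) != self.shape[2]:
            raise ConfigurationError(
                f"snr_per_slice has {len(self.snr_per_slice)} entries for "
                f"{self.shape[2]} slices")
        if any(s <= 0 for s in self.snr_per_slice):
            raise ConfigurationError("all SNR values must be positive")
        missing = set(CLASS_NAMES) - set(self.tissue_table)
        if missing:
            raise ConfigurationError(f"tissue_table is missing classes: {sorted(missing)}")
        if self.tissue_table["cavity"][0] != 0.0:
            raise ConfigurationError("the cavity class must have f = 0")
        object.__setattr__(self, "bvalues", np.asarray(self.bvalues, dtype=float))

    @property
    def scheme(self) -> AcquisitionScheme:
        return AcquisitionScheme(self.bvalues)


@dataclass
class PhantomOutput:
    """Noisy magnitude data plus the generating ground truth."""

    dwi: np.ndarray  # (nx, ny, nslices, m) magnitude
    gt_f: np.ndarray
    gt_D: np.ndarray
    gt_Dstar: np.ndarray
    labels: np.ndarray  # int class map, 0 = background
    noise_sigma_per_slice: np.ndarray
    spec: PhantomSpec

    @property
    def scheme(self) -> AcquisitionScheme:
        return self.spec.scheme

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels > 0


def ellipse_contains(x, y, ellipse) -> np.ndarray:
    """Analytic point-in-ellipse test in the phantom's [-1, 1]^2 coordinates."""
    a, b, x0, y0, angle = ellipse
    t = np.deg2rad(angle)
    dx, dy = np.asarray(x) - x0, np.asarray(y) - y0
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def shepp_logan_labels(shape) -> np.ndarray:
    """Rasterize the ten-ellipse geometry into the six-class label map.

    Identical across slices; returns a 2-D int map for a (nx, ny) shape.
    """
    nx, ny = shape[0], shape[1]
    if nx < 32 or ny < 32:
        raise ConfigurationError(f"phantom grid must be at least 32 x 32, got {nx} x {ny}")
    # pixel centers on [-1, 1]; y axis points up so the blobs land as in the classic image
    xs = (np.arange(nx) + 0.5) / nx * 2.0 - 1.0
    ys = 1.0 - (np.arange(ny) + 0.5) / ny * 2.0
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    e = SHEPP_LOGAN_ELLIPSES
    labels = np.zeros((nx, ny), dtype=np.int16)
    labels[ellipse_contains(X, Y, e[0])] = LABELS["cavity"]       # skull rim...
    labels[ellipse_contains(X, Y, e[1])] = LABELS["normal"]       # ...overridden by brain
    for k in (2, 3):
        labels[ellipse_contains(X, Y, e[k])] = LABELS["csf"]
    labels[ellipse_contains(X, Y, e[4])] = LABELS["high_perfused_tumor"]
    for k in (5, 6):
        labels[ellipse_contains(X, Y, e[k])] = LABELS["infiltrating_tumor"]
    for k in (7, 8, 9):
        labels[ellipse_contains(X, Y, e[k])] = LABELS["low_perfused_tumor"]
    return labels


def assign_params(labels: np.ndarray, tissue_table: dict):
    """Piecewise-constant ground-truth maps (gt_f, gt_D, gt_Dstar) from the label map."""
    present = set(int(v) for v in np.unique(labels)) - {0}
    known = set(LABELS.values())
    if not present <= known:
        raise ConfigurationError(f"label map contains unknown labels {sorted(present - known)}")
    missing = [name for name in CLASS_NAMES
               if LABELS[name] in present and name not in tissue_table]
    if missing:
        raise ConfigurationError(f"tissue_table is missing classes: {missing}")
    gt_f = np.zeros(labels.shape)
    gt_D = np.zeros(labels.shape)
    gt_Dstar = np.zeros(labels.shape)
    for name, lab in LABELS.items():
        if lab not in present:
            continue
        f, D, Dstar = tissue_table[name]
        where = labels == lab
        gt_f[where], gt_D[where], gt_Dstar[where] = f, D, Dstar
    return gt_f, gt_D, gt_Dstar


def simulate_dwi_noiseless(gt_f, gt_D, gt_Dstar, scheme: AcquisitionScheme,
                           s0_map) -> np.ndarray:
    """Voxelwise bi-exponential decay: s0 * (f e^{-b Dstar} + (1-f) e^{-b D})."""
    b = scheme.bvalues
    f = np.asarray(gt_f)[..., None]
    sig = f * np.exp(-np.asarray(gt_Dstar)[..., None] * b) \
        + (1.0 - f) * np.exp(-np.asarray(gt_D)[..., None] * b)
    return np.asarray(s0_map)[..., None] * sig


def coil_sensitivity(shape, n_coils: int, seed: int = 0) -> np.ndarray:
    """Smooth complex coil maps, (n_coils, nx, ny), normalized to unit sum-of-squares.

    Coil centers sit at equally spaced angles just outside the FOV with a
    Gaussian magnitude profile and a coil-specific linear phase; the seed
    jitters the angular positions slightly.
    """
    if n_coils < 1:
        raise ConfigurationError("need at least one coil")
    nx, ny = shape[0], shape[1]
    xs = np.linspace(-1, 1, nx)
    ys = np.linspace(-1, 1, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    rng = np.random.default_rng(seed)
    angles = 2 * np.pi * np.arange(n_coils) / n_coils + rng.uniform(-0.1, 0.1, n_coils)
    maps = np.empty((n_coils, nx, ny), dtype=complex)
    for c in range(n_coils):
        cx, cy = 1.3 * np.cos(angles[c]), 1.3 * np.sin(angles[c])
        mag = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * 0.75 ** 2))
        phase = 0.5 * (np.cos(angles[c]) * X + np.sin(angles[c]) * Y)
        maps[c] = mag * np.exp(1j * phase)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return maps / sos[None, :, :]


def add_noise_sos(noiseless: np.ndarray, sens: np.ndarray, snr_per_slice,
                  labels: np.ndarray, scheme: AcquisitionScheme, seed: int = 0):
    """Per-coil complex Gaussian noise followed by sum-of-squares combination.

    For each slice, sigma is chosen so that the mean b=0 signal over the
    normal-tissue region divided by sigma equals the slice's target SNR;
    sigma is constant across b-values. An infinite SNR leaves the slice
    noiseless. Returns (noisy magnitude 4-D array, sigma per slice).
    """
    noiseless = np.asarray(noiseless, dtype=float)
    nx, ny, nz, m = noiseless.shape
    rng = np.random.default_rng(seed)
    normal = np.asarray(labels) == LABELS["normal"]
    b0 = scheme.b0_indices
    sigmas = np.zeros(nz)
    out = np.zeros_like(noiseless)
    for z, snr in enumerate(snr_per_slice):
        norm_z = normal[:, :, z] if normal.ndim == 3 else normal
        if not norm_z.any():
            raise ConfigurationError(f"slice {z} has no normal-tissue voxels to define SNR")
        mean_b0 = float(noiseless[:, :, z, :][norm_z][:, b0].mean())
        if np.isinf(snr):
            out[:, :, z, :] = noiseless[:, :, z, :]
            continue
        sigma = mean_b0 / float(snr)
        sigmas[z] = sigma
        sos = np.zeros((nx, ny, m))
        for c in range(sens.shape[0]):
            coil = noiseless[:, :, z, :] * sens[c][:, :, None]
            noise = rng.normal(scale=sigma, size=(nx, ny, m)) \
                + 1j * rng.normal(scale=sigma, size=(nx, ny, m))
            sos += np.abs(coil + noise) ** 2
        out[:, :, z, :] = np.sqrt(sos)
    return out, sigmas


def make_phantom(spec: PhantomSpec = None) -> PhantomOutput:
    """Compose geometry, ground truth, decay simulation and noise into one phantom."""
    spec = spec or PhantomSpec()
    nx, ny, nz = spec.shape
    labels2d = shepp_logan_labels((nx, ny))
    labels = np.repeat(labels2d[:, :, None], nz, axis=2)
    gt_f2, gt_D2, gt_Ds2 = assign_params(labels2d, spec.tissue_table)
    gt_f = np.repeat(gt_f2[:, :, None], nz, axis=2)
    gt_D = np.repeat(gt_D2[:, :, None], nz, axis=2)
    gt_Dstar = np.repeat(gt_Ds2[:, :, None], nz, axis=2)
    s0_map = np.where(labels > 0, spec.s0, 0.0)
    scheme = spec.scheme
    clean = simulate_dwi_noiseless(gt_f, gt_D, gt_Dstar, scheme, s0_map)
    sens = coil_sensitivity((nx, ny), spec.n_coils, seed=spec.seed)
    noisy, sigmas = add_noise_sos(clean, sens, spec.snr_per_slice, labels,
                                  scheme, seed=spec.seed + 1)
    return PhantomOutput(dwi=noisy, gt_f=gt_f, gt_D=gt_D, gt_Dstar=gt_Dstar,
                         labels=labels, noise_sigma_per_slice=sigmas, spec=spec)
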