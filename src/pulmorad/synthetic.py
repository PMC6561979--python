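"""Synthetic CT-like pulmonary-nodule cohorts.

Generates 3D Hounsfield-unit volumes containing a single segmented nodule
per subject, together with class labels, test-retest replicate pairs and
reconstruction-kernel variant pairs.  The generator emulates the structure
a screening-cohort analysis assumes — two nodule classes differing in size,
boundary irregularity, internal heterogeneity and airspace content — without
attempting photorealistic CT simulation.

A nodule is rendered as a randomly oriented ellipsoid whose radius is
perturbed by a smooth random angular field (spiculation), filled with
``core_hu`` plus spatially correlated Gaussian heterogeneity, optionally
punctured by low-attenuation spherical airspace pockets, and blended into a
lung-parenchyma background by a small partial-volume blur.  All randomness
is driven by a single integer seed; every output is a pure function of
(config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

HU_MIN = -1024.0
HU_MAX = 3071.0
#: HU below which a voxel is counted as airspace (emphysema-like convention)
AIRSPACE_HU = -910.0
#: HU value assigned to rendered airspace pockets
AIRSPACE_FILL_HU = -950.0
#: floor for solid-tissue voxels so airspace-free nodules stay above AIRSPACE_HU
SOLID_FLOOR_HU = -900.0


class InvalidConfigError(ValueError):
    """Raised when a cohort or nodule configuration is out of range."""


@dataclass(frozen=True)
class NoduleParams:
    """Generating parameters for one synthetic nodule.

    Parameters
    ----------
    class_label : str
        ``"malignant"`` or ``"benign"``.
    equiv_diameter : float
        Nominal longest-axis diameter (mm) of the unperturbed ellipsoid,
        matching the clinical longest-diameter sizing convention; 4-30 mm.
    axis_ratios : tuple of float
        Two ratios in (0, 1] shaping the ellipsoid's second and third axes.
    spiculation_amplitude : float
        Relative amplitude of the smooth radial boundary perturbation (>= 0).
    core_hu : float
        Mean attenuation of the solid component.
    heterogeneity_sd : float
        SD (HU) of the spatially correlated internal texture (>= 0).
    texture_corr_length : float
        Correlation length (mm) of the internal texture (> 0).
    airspace_fraction : float
        Target fraction of mask volume occupied by airspace pockets, [0, 1).
    rng_seed : int
        Per-nodule seed; renders are reproducible from it.
    """

    class_label: str
    equiv_diameter: float
    axis_ratios: tuple[float, float] = (0.85, 0.75)
    spiculation_amplitude: float = 0.1
    core_hu: float = -60.0
    heterogeneity_sd: float = 40.0
    texture_corr_length: float = 2.0
    airspace_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in ("malignant", "benign"):
            raise InvalidConfigError(f"unknown class label {self.class_label!r}")
        vals = [self.equiv_diameter, *self.axis_ratios, self.spiculation_amplitude,
                self.core_hu, self.heterogeneity_sd, self.texture_corr_length,
                self.airspace_fraction]
        if not all(math.isfinite(v) for v in vals):
            raise InvalidConfigError("non-finite nodule parameter")
        if self.equiv_diameter <= 0:
            raise InvalidConfigError("equiv_diameter must be positive")
        if not all(0 < r <= 1 for r in self.axis_ratios):
            raise InvalidConfigError("axis_ratios must lie in (0, 1]")
        if self.spiculation_amplitude < 0 or self.heterogeneity_sd < 0:
            raise InvalidConfigError("amplitudes must be non-negative")
        if self.texture_corr_length <= 0:
            raise InvalidConfigError("texture_corr_length must be positive")
        if not 0 <= self.airspace_fraction < 1:
            raise InvalidConfigError("airspace_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticVolume:
    """A rendered volume: HU grid, voxel spacing (mm), nodule mask, params."""

    hu_grid: np.ndarray
    spacing_mm: tuple[float, float, float]
    mask: np.ndarray
    params: NoduleParams

    def __post_init__(self) -> None:
        if self.hu_grid.ndim != 3 or self.mask.shape != self.hu_grid.shape:
            raise InvalidConfigError("grid and mask must be 3D with equal shapes")
        if not all(s > 0 for s in self.spacing_mm):
            raise InvalidConfigError("spacing must be positive")
        if not self.mask.any():
            raise InvalidConfigError("mask is empty")


@dataclass(frozen=True)
class ClassDistribution:
    """Class-conditional means and dispersions over NoduleParams."""

    diameter_mean: float
    diameter_sd: float
    spiculation_mean: float = 0.1
    spiculation_sd: float = 0.03
    core_hu_mean: float = -60.0
    core_hu_sd: float = 30.0
    heterogeneity_sd_mean: float = 40.0
    heterogeneity_sd_sd: float = 10.0
    texture_corr_length: float = 2.0
    airspace_fraction_mean: float = 0.02
    airspace_fraction_sd: float = 0.02

    def __post_init__(self) -> None:
        for v in (self.diameter_sd, self.spiculation_sd, self.core_hu_sd,
                  self.heterogeneity_sd_sd, self.airspace_fraction_sd):
            if v < 0:
                raise InvalidConfigError("dispersions must be non-negative")


def _default_malignant() -> ClassDistribution:
    return ClassDistribution(diameter_mean=14.0, diameter_sd=4.0,
                             spiculation_mean=0.16, spiculation_sd=0.04,
                             core_hu_mean=-40.0, core_hu_sd=30.0,
                             heterogeneity_sd_mean=60.0, heterogeneity_sd_sd=12.0,
                             airspace_fraction_mean=0.06, airspace_fraction_sd=0.03)


def _default_benign() -> ClassDistribution:
    return ClassDistribution(diameter_mean=7.0, diameter_sd=2.0,
                             spiculation_mean=0.06, spiculation_sd=0.02,
                             core_hu_mean=-90.0, core_hu_sd=30.0,
                             heterogeneity_sd_mean=35.0, heterogeneity_sd_sd=8.0,
                             airspace_fraction_mean=0.01, airspace_fraction_sd=0.01)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings.

    ``kernel_variants`` holds the reconstruction-kernel emulation parameters:
    ``smooth_sigma_mm`` (Gaussian blur) and ``sharp_gain``/``sharp_sigma_mm``
    (unsharp mask).  ``retest_shift_mm`` bounds the random sub-voxel
    repositioning applied to the second member of a test-retest pair.
    """

    n_per_class: int = 50
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = -800.0
    noise_sd: float = 20.0
    retest_noise_sd: float = 10.0
    retest_shift_mm: float = 0.5
    malignant: ClassDistribution = field(default_factory=_default_malignant)
    benign: ClassDistribution = field(default_factory=_default_benign)
    diameter_range: tuple[float, float] = (4.0, 30.0)
    kernel_variants: dict = field(default_factory=lambda: {
        "smooth_sigma_mm": 1.0, "sharp_gain": 1.0, "sharp_sigma_mm": 1.0})

    def __post_init__(self) -> None:
        if self.n_per_class <= 0:
            raise InvalidConfigError("n_per_class must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise InvalidConfigError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidConfigError("spacing must be positive")
        if self.noise_sd < 0 or self.retest_noise_sd < 0 or self.retest_shift_mm < 0:
            raise InvalidConfigError("noise levels must be non-negative")


# ---------------------------------------------------------------------------
# rendering


def _sample_params(dist: ClassDistribution, label: str, cfg: CohortConfig,
                   rng: np.random.Generator) -> NoduleParams:
    lo, hi = cfg.diameter_range
    d = float(np.clip(rng.normal(dist.diameter_mean, dist.diameter_sd), lo, hi))
    ratios = (float(rng.uniform(0.7, 1.0)), float(rng.uniform(0.6, 0.95)))
    return NoduleParams(
        class_label=label,
        equiv_diameter=d,
        axis_ratios=ratios,
        spiculation_amplitude=max(0.0, float(rng.normal(dist.spiculation_mean,
                                                        dist.spiculation_sd))),
        core_hu=float(rng.normal(dist.core_hu_mean, dist.core_hu_sd)),
        heterogeneity_sd=max(0.0, float(rng.normal(dist.heterogeneity_sd_mean,
                                                   dist.heterogeneity_sd_sd))),
        texture_corr_length=dist.texture_corr_length,
        airspace_fraction=min(0.95, max(0.0, float(
            rng.normal(dist.airspace_fraction_mean, dist.airspace_fraction_sd)))),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _correlated_field(shape: tuple[int, int, int], sigma_vox: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian random field with correlation length sigma (voxels)."""
    w = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


from functools import lru_cache


@lru_cache(maxsize=4)
def _mm_grid(shape: tuple[int, int, int],
             spacing: tuple[float, float, float]) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def _render(params: NoduleParams, cfg: CohortConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Render the noiseless volume and mask for one nodule."""
    shape = cfg.grid_shape
    spacing = np.asarray(cfg.spacing_mm, dtype=float)

    # mm coordinates of voxel centers relative to the (jittered) nodule center
    center = (np.asarray(shape) - 1) / 2.0 * spacing + rng.uniform(-2, 2, size=3)
    grid = _mm_grid(tuple(shape), tuple(cfg.spacing_mm))
    xx, yy, zz = grid[0], grid[1], grid[2]
    rel = grid - center[:, None, None, None]

    q1, q2 = params.axis_ratios
    # the size parameter sets the longest axis, matching the clinical
    # longest-diameter convention used for nodule sizing
    a = params.equiv_diameter / 2.0
    semi = np.array([a, a * q1, a * q2])
    rot = _random_rotation(rng)
    body = np.einsum("ij,jxyz->ixyz", rot.T, rel)
    # normalized ellipsoidal radius: 1 on the unperturbed surface
    r_ell = np.sqrt(((body / semi[:, None, None, None]) ** 2).sum(axis=0))

    if params.spiculation_amplitude > 0:
        sig = max(1.0, 3.0 / spacing.mean())
        bump = _correlated_field(shape, np.full(3, sig), rng)
        surface = 1.0 + params.spiculation_amplitude * bump
    else:
        surface = 1.0
    mask = r_ell <= surface
    if not mask.any():  # degenerate tiny nodule: keep the closest voxel
        mask = r_ell == r_ell.min()

    hu = np.full(shape, cfg.background_hu, dtype=float)
    tissue = np.full(shape, params.core_hu, dtype=float)
    if params.heterogeneity_sd > 0:
        sig = params.texture_corr_length / spacing
        tissue += params.heterogeneity_sd * _correlated_field(shape, sig, rng)
    # solid tissue never dips into the airspace HU regime
    tissue = np.maximum(tissue, SOLID_FLOOR_HU)

    hu[mask] = tissue[mask]
    # partial-volume blend at the boundary
    hu = ndimage.gaussian_filter(hu, sigma=0.6 / spacing)
    hu[mask] = np.maximum(hu[mask], SOLID_FLOOR_HU)

    # airspace pockets are carved after the blend so small pockets keep
    # their low attenuation instead of being averaged away
    if params.airspace_fraction > 0:
        air = np.zeros(shape, dtype=bool)
        target = params.airspace_fraction * int(mask.sum())
        coords = np.argwhere(mask)
        r_mean = params.equiv_diameter / 2.0
        for _ in range(300):
            if air.sum() >= target:
                break
            c = coords[rng.integers(len(coords))] * spacing
            pr = rng.uniform(0.10, 0.30) * r_mean
            d2 = ((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2)
            air |= (d2 <= pr**2) & mask
        hu[air] = AIRSPACE_FILL_HU
    return np.clip(hu, HU_MIN, HU_MAX), mask


def render_nodule(params: NoduleParams, config: CohortConfig) -> SyntheticVolume:
    """Render a single noiseless nodule volume from its parameters."""
    rng = np.random.default_rng(params.rng_seed)
    hu, mask = _render(params, config, rng)
    return SyntheticVolume(hu, config.spacing_mm, mask, params)


def _with_noise(hu: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd > 0:
        hu = hu + rng.normal(0.0, sd, size=hu.shape)
    return np.clip(hu, HU_MIN, HU_MAX)


def generate_cohort(config: CohortConfig, seed: int
                    ) -> list[tuple[SyntheticVolume, int]]:
    """Generate a balanced two-class cohort.

    Returns a list of ``2 * n_per_class`` pairs ``(volume, label)`` with
    label 1 = malignant, 0 = benign, in interleaved subject order.  The
    output is a pure function of ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[SyntheticVolume, int]] = []
    for _ in range(config.n_per_class):
        for label, dist in ((1, config.malignant), (0, config.benign)):
            name = "malignant" if label else "benign"
            params = _sample_params(dist, name, config, rng)
            prng = np.random.default_rng(params.rng_seed)
            hu, mask = _render(params, config, prng)
            hu = _with_noise(hu, config.noise_sd, prng)
            out.append((SyntheticVolume(hu, config.spacing_mm, mask, params), label))
    return out


def generate_retest_pair(params: NoduleParams, config: CohortConfig, seed: int
                         ) -> tuple[SyntheticVolume, SyntheticVolume]:
    """Render the same nodule twice, emulating a short-interval repeat scan.

    Both members share the underlying noiseless rendering; each receives an
    independent additive noise draw of SD ``retest_noise_sd`` and the second
    is additionally repositioned by a random sub-voxel shift (trilinear
    resampling, bounded by ``retest_shift_mm``).  With zero noise and zero
    shift the two volumes are identical.
    """
    rng = np.random.default_rng(seed)
    render_rng = np.random.default_rng(params.rng_seed)
    hu, mask = _render(params, config, render_rng)

    first = _with_noise(hu, config.retest_noise_sd, rng)
    hu2 = hu
    if config.retest_shift_mm > 0:
        shift_mm = rng.uniform(-config.retest_shift_mm, config.retest_shift_mm, 3)
        shift_vox = shift_mm / np.asarray(config.spacing_mm)
        hu2 = ndimage.shift(hu, shift_vox, order=1, mode="nearest")
    second = _with_noise(hu2, config.retest_noise_sd, rng)
    vol1 = SyntheticVolume(first, config.spacing_mm, mask, params)
    vol2 = SyntheticVolume(second, config.spacing_mm, mask, params)
    return vol1, vol2


def apply_kernel_variant(vol: SyntheticVolume, variant: str,
                         config: CohortConfig | None = None) -> SyntheticVolume:
    """Emulate a reconstruction-kernel change.

    ``smooth`` applies a Gaussian blur of ``smooth_sigma_mm``; ``sharp``
    applies an unsharp mask ``v + gain * (v - G_sigma(v))``.  The mask is
    unchanged.
    """
    cfg = config or CohortConfig()
    kv = cfg.kernel_variants
    spacing = np.asarray(vol.spacing_mm)
    if variant == "smooth":
        sigma = kv["smooth_sigma_mm"] / spacing
        hu = ndimage.gaussian_filter(vol.hu_grid, sigma=sigma) if kv[
            "smooth_sigma_mm"] > 0 else vol.hu_grid.copy()
    elif variant == "sharp":
        sigma = kv["sharp_sigma_mm"] / spacing
        blurred = ndimage.gaussian_filter(vol.hu_grid, sigma=sigma)
        hu = vol.hu_grid + kv["sharp_gain"] * (vol.hu_grid - blurred)
    else:
        raise InvalidConfigError(f"unknown kernel variant {variant!r}")
    hu = np.clip(hu, HU_MIN, HU_MAX)
    return SyntheticVolume(hu, vol.spacing_mm, vol.mask.copy(), vol.params)


# ---------------------------------------------------------------------------
# parametric feature tables (fast fixtures for the statistics-only path)


def generate_feature_table_direct(
    n0: int,
    n1: int,
    p_noise: int,
    planted: list[tuple[float, int]] | None = None,
    redundancy_blocks: list[tuple[int, float]] | None = None,
    retest_ccc_targets: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Class-conditional Gaussian feature tables with planted structure.

    Parameters
    ----------
    n0, n1 : int
        Control / case sample sizes.
    p_noise : int
        Number of pure-noise features (standardized mean difference 0).
    planted : list of (d, count)
        Adds ``count`` independent features per entry whose class-1 mean is
        shifted by ``d`` standard deviations (population AUROC Φ(d/√2)).
    redundancy_blocks : list of (size, r2)
        For each entry, appends ``size - 1`` affine copies of a fresh base
        feature whose pairwise squared correlation with it is ``r2``.
    retest_ccc_targets : dict name -> ccc
        Retest columns are attenuated copies achieving approximately the
        requested concordance; unlisted features replicate exactly.
    seed : int
        Seed for all draws.

    Returns
    -------
    (test table, retest table, labels) with labels 0/1.
    """
    if planted is None:
        planted = []
    if any(d < 0 or c < 0 for d, c in planted):
        raise InvalidConfigError("planted effect sizes and counts must be >= 0")
    rng = np.random.default_rng(seed)
    n = n0 + n1
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])

    cols: dict[str, np.ndarray] = {}
    for j in range(p_noise):
        cols[f"noise_{j:03d}"] = rng.standard_normal(n)
    k = 0
    for d, count in planted:
        for _ in range(count):
            x = rng.standard_normal(n)
            x[y == 1] += d
            cols[f"planted_{k:03d}"] = x
            k += 1
    for b, (size, r2) in enumerate(redundancy_blocks or []):
        base = rng.standard_normal(n)
        cols[f"block{b}_base"] = base
        rho = math.sqrt(min(max(r2, 0.0), 1.0))
        for m in range(1, size):
            eps = rng.standard_normal(n)
            slope = rng.uniform(0.5, 2.0)
            copy = slope * (rho * base + math.sqrt(max(0.0, 1 - rho**2)) * eps)
            cols[f"block{b}_copy{m}"] = copy + rng.uniform(-1, 1)

    test = pd.DataFrame(cols, index=[f"S{i:04d}" for i in range(n)])
    retest = test.copy()
    for name, ccc in (retest_ccc_targets or {}).items():
        x = test[name].to_numpy()
        sd = x.std()
        rho = min(max(ccc, 0.0), 1.0)
        noise = rng.standard_normal(n) * sd
        retest[name] = x.mean() + rho * (x - x.mean()) + math.sqrt(
            max(0.0, 1 - rho**2)) * noise
    return test, retest, y


def subject_table(cohort: list[tuple[SyntheticVolume, int]], seed: int = 0
                  ) -> pd.DataFrame:
    """Subject metadata table (id, label, clinical covariates).

    Clinical covariates are drawn independently of the label, emulating the
    epidemiologically matched case-control design in which demographics are
    balanced between arms.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "label": [lab for _, lab in cohort],
        "age": rng.normal(64, 5, n).round(1),
        "sex": rng.integers(0, 2, n),
        "pack_years": np.clip(rng.normal(63, 25, n), 30, None).round(1),
        "smoke_status": rng.integers(0, 2, n),
    }).set_index("subject_id")
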