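"""Synthetic PET tumour and cohort generation.

Patient scans backing the nodal-metastasis analysis are not publicly
available, so this module generates cohorts with the statistical structure
the analysis assumes: lesions on a 2.73 x 2.73 x 3.27 mm voxel grid whose
heterogeneity (necrotic cores widening the SUV range) and boundary
irregularity (lobulation lowering solidity) are linked to the nodal label,
plus a visual-detection label generator with configurable sensitivity and
specificity.

A tumour is a (possibly lobulated) ellipsoid of uniform uptake, optionally
carved with a central necrotic sub-ellipsoid and decorated with Gaussian
hot spots, blurred with a Gaussian point-spread function (reconstruction
smoothing) and then corrupted with additive Gaussian noise clipped at zero.
The mask is the pre-blur lobulated ellipsoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .io import Cohort, PatientRecord, PETVolume, STRUCT_26, VOIMask, write_mask, write_volume

#: reconstruction grid of the emulated scanners (mm)
DEFAULT_SPACING = (2.73, 2.73, 3.27)
#: soft-tissue background uptake, as a fraction of the lesion base SUV
BACKGROUND_FRACTION = 0.05


@dataclass
class NecroticCore:
    """Central low-uptake sub-ellipsoid: `fraction` of the lesion volume at
    `suv_ratio` times the base uptake."""

    fraction: float = 0.3
    suv_ratio: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError(f"core fraction must be in (0,1), got {self.fraction}")
        if not 0 <= self.suv_ratio < 1:
            raise ValueError(f"core suv_ratio must be in [0,1), got {self.suv_ratio}")


@dataclass
class HotSpots:
    """Gaussian high-uptake bumps added inside the lesion."""

    count: int = 1
    peak_suv_ratio: float = 1.5
    radius_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.count < 0 or self.peak_suv_ratio <= 1 or self.radius_mm <= 0:
            raise ValueError("hot spots need count >= 0, peak_suv_ratio > 1, radius > 0")


@dataclass
class TumourParams:
    base_suv: float
    radius_mm: tuple[float, float, float]
    necrotic_core: NecroticCore | None = None
    hot_spots: HotSpots | None = None
    lobulation: float = 0.0
    noise_sd: float = 0.0
    psf_fwhm_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.base_suv <= 0:
            raise ValueError(f"base_suv must be > 0, got {self.base_suv}")
        self.radius_mm = tuple(float(r) for r in self.radius_mm)
        if len(self.radius_mm) != 3 or any(r <= 0 for r in self.radius_mm):
            raise ValueError(f"degenerate radii {self.radius_mm}")
        if not 0 <= self.lobulation < 1:
            raise ValueError(f"lobulation must be in [0,1), got {self.lobulation}")
        if self.noise_sd < 0 or self.psf_fwhm_mm < 0:
            raise ValueError("noise_sd and psf_fwhm_mm must be >= 0")


def _lobulation_field(ux, uy, uz, rng: np.random.Generator) -> np.ndarray:
    """Smooth random radial perturbation from low-order (l = 2, 3) real
    spherical-harmonic polynomials of the unit direction, normalized to
    max |f| = 1."""
    basis = [
        0.5 * (3 * uz**2 - 1),
        ux * uy,
        ux * uz,
        uy * uz,
        ux**2 - uy**2,
        0.5 * uz * (5 * uz**2 - 3),
        ux * (ux**2 - 3 * uy**2),
        uy * (3 * ux**2 - uy**2),
        uz * (ux**2 - uy**2),
        ux * uy * uz,
    ]
    coef = rng.normal(size=len(basis))
    f = sum(c * b for c, b in zip(coef, basis))
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def generate_tumour(
    params: TumourParams,
    grid_spacing: tuple[float, float, float] = DEFAULT_SPACING,
    seed: int = 0,
    grid_shape: tuple[int, int, int] | None = None,
) -> tuple[PETVolume, VOIMask]:
    """Simulate one lesion; deterministic given ``seed``.

    Returns the SUV volume (background at 5% of base SUV) and the binary
    lesion mask.  The grid is auto-sized to hold the lobulated ellipsoid
    plus a 3-voxel margin and the blur support, unless ``grid_shape`` is
    given (too-small explicit grids are rejected).
    """
    rng = np.random.default_rng(seed)
    spacing = np.asarray(grid_spacing, dtype=float)
    radii = np.asarray(params.radius_mm, dtype=float)
    rmax = radii.max() * (1.0 + params.lobulation)
    sigma_mm = params.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    need = np.ceil((rmax + 2 * sigma_mm) / spacing).astype(int) + 3
    auto_shape = tuple(int(2 * n + 1) for n in need)
    if grid_shape is None:
        grid_shape = auto_shape
    elif any(g < a for g, a in zip(grid_shape, auto_shape)):
        raise ValueError(
            f"grid too small: {grid_shape} cannot hold the lesion (needs {auto_shape})"
        )

    center = (np.asarray(grid_shape) - 1) / 2.0
    idx = np.indices(grid_shape, dtype=np.float64)
    phys = [(idx[a] - center[a]) * spacing[a] for a in range(3)]
    scaled = [phys[a] / radii[a] for a in range(3)]
    rho = np.sqrt(scaled[0] ** 2 + scaled[1] ** 2 + scaled[2] ** 2)

    if params.lobulation > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            u = [np.where(rho > 0, s / rho, 0.0) for s in scaled]
        f = _lobulation_field(u[0], u[1], u[2], rng)
        mask = rho <= 1.0 + params.lobulation * f
    else:
        mask = rho <= 1.0

    # the lobulated boundary is star-shaped, but guard connectivity anyway
    labels, n_comp = ndimage.label(mask, structure=STRUCT_26)
    if n_comp > 1:
        keep = labels[tuple(center.astype(int))]
        if keep == 0:
            keep = np.argmax(np.bincount(labels[labels > 0])) + 1
        mask = labels == keep

    values = np.full(grid_shape, BACKGROUND_FRACTION * params.base_suv)
    values[mask] = params.base_suv

    core = np.zeros(grid_shape, dtype=bool)
    if params.necrotic_core is not None:
        core_radii = radii * params.necrotic_core.fraction ** (1.0 / 3.0)
        rho_core = np.sqrt(sum((phys[a] / core_radii[a]) ** 2 for a in range(3)))
        core = (rho_core <= 1.0) & mask
        values[core] = params.base_suv * params.necrotic_core.suv_ratio

    if params.hot_spots is not None and params.hot_spots.count > 0:
        # spots sit in viable (non-necrotic) tissue
        viable = mask & ~core
        in_mask = np.argwhere(viable if viable.any() else mask)
        sigma_spot = params.hot_spots.radius_mm
        for _ in range(params.hot_spots.count):
            c = in_mask[rng.integers(len(in_mask))]
            d2 = sum(((idx[a] - c[a]) * spacing[a]) ** 2 for a in range(3))
            values += (
                params.base_suv
                * (params.hot_spots.peak_suv_ratio - 1.0)
                * np.exp(-d2 / (2.0 * sigma_spot**2))
            )

    if params.psf_fwhm_mm > 0:
        values = ndimage.gaussian_filter(values, sigma=sigma_mm / spacing)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=grid_shape)
    np.clip(values, 0.0, None, out=values)

    spacing_t = tuple(float(s) for s in spacing)
    return PETVolume(values, spacing_t), VOIMask(mask, spacing_t)


# ---------------------------------------------------------------------------
# Cohort generation


def _draw(rng: np.random.Generator, value, log: bool = False) -> float:
    """A config field is either a fixed scalar or a (low, high) uniform range."""
    if np.isscalar(value):
        return float(value)
    lo, hi = value
    if log:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


@dataclass
class TumourSampler:
    """Distribution over tumour parameters for one label class.

    Lesion size is drawn log-uniformly in mL and converted to ellipsoid
    semi-axes with a mild per-axis anisotropy; noise scales with base SUV so
    the signal-to-noise regime is size- and uptake-independent.
    """

    base_suv: float | tuple[float, float] = (6.0, 18.0)
    volume_ml: float | tuple[float, float] = (3.0, 40.0)
    axis_ratio: float | tuple[float, float] = (0.85, 1.15)
    core_probability: float = 0.0
    core_fraction: float | tuple[float, float] = 0.3
    core_suv_ratio: float | tuple[float, float] = 0.1
    #: hot spots travel with the necrotic core by default (one heterogeneity
    #: draw decides both); give spot_probability to decouple them
    n_hot_spots: int = 0
    hot_spot_peak_ratio: float | tuple[float, float] = 1.5
    hot_spot_radius_mm: float | tuple[float, float] = 5.0
    spot_probability: float | None = None
    lobulation: float | tuple[float, float] = 0.05
    noise_fraction: float | tuple[float, float] = 0.05
    psf_fwhm_mm: float = 5.0

    def sample(self, rng: np.random.Generator) -> TumourParams:
        base = _draw(rng, self.base_suv)
        vol_mm3 = _draw(rng, self.volume_ml, log=True) * 1000.0
        r0 = (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
        ratios = np.array([_draw(rng, self.axis_ratio) for _ in range(3)])
        ratios /= np.prod(ratios) ** (1.0 / 3.0)  # preserve the drawn volume
        heterogeneous = rng.random() < self.core_probability
        core = None
        if heterogeneous:
            core = NecroticCore(
                _draw(rng, self.core_fraction), _draw(rng, self.core_suv_ratio)
            )
        spots = None
        if self.n_hot_spots > 0:
            with_spots = (
                heterogeneous
                if self.spot_probability is None
                else rng.random() < self.spot_probability
            )
            if with_spots:
                spots = HotSpots(
                    self.n_hot_spots,
                    _draw(rng, self.hot_spot_peak_ratio),
                    _draw(rng, self.hot_spot_radius_mm),
                )
        return TumourParams(
            base_suv=base,
            radius_mm=tuple(r0 * ratios),
            necrotic_core=core,
            hot_spots=spots,
            lobulation=_draw(rng, self.lobulation),
            noise_sd=_draw(rng, self.noise_fraction) * base,
            psf_fwhm_mm=self.psf_fwhm_mm,
        )


@dataclass
class CohortConfig:
    n_patients: int = 86
    n_positive: int = 16
    params_positive: TumourSampler = field(default_factory=TumourSampler)
    params_negative: TumourSampler = field(default_factory=TumourSampler)
    visual_sensitivity: float = 0.5
    visual_specificity: float = 0.99
    grid_spacing: tuple[float, float, float] = DEFAULT_SPACING
    scanners: tuple[str, ...] = ("scanner_A", "scanner_B")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_positive < self.n_patients:
            raise ValueError(
                f"need 0 < n_positive < n_patients, got {self.n_positive}/{self.n_patients}"
            )
        for name in ("visual_sensitivity", "visual_specificity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("params_positive", "params_negative"):
            if key in raw:
                raw[key] = TumourSampler(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in raw[key].items()
                    }
                )
        if "grid_spacing" in raw:
            raw["grid_spacing"] = tuple(raw["grid_spacing"])
        if "scanners" in raw:
            raw["scanners"] = tuple(raw["scanners"])
        return cls(**raw)


def sample_visual_labels(
    ln_histology: np.ndarray,
    sensitivity: float,
    specificity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli visual-detection labels: P(1 | LN+) = sensitivity,
    P(1 | LN-) = 1 - specificity."""
    ln = np.asarray(ln_histology, dtype=int)
    u = rng.random(len(ln))
    return np.where(ln == 1, (u < sensitivity), (u < 1.0 - specificity)).astype(int)


def generate_cohort(
    config: CohortConfig, out_dir=None
) -> tuple[Cohort, dict[str, tuple[PETVolume, VOIMask]]]:
    """Generate a full cohort: exactly ``n_positive`` LN-positive patients,
    per-patient tumours drawn from the class-specific samplers, visual labels,
    and round-robin scanner assignment.  Reproducible from ``config.seed``.

    If ``out_dir`` is given, per-patient NIfTI volumes/masks and the cohort
    CSV are also written there.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ln = np.zeros(n, dtype=int)
    ln[: config.n_positive] = 1
    rng.shuffle(ln)
    visual = sample_visual_labels(
        ln, config.visual_sensitivity, config.visual_specificity, rng
    )
    tumour_seeds = rng.integers(0, 2**31 - 1, size=n)

    records, images = [], {}
    for i in range(n):
        pid = f"p{i + 1:03d}"
        sampler = config.params_positive if ln[i] == 1 else config.params_negative
        params = sampler.sample(rng)
        vol, msk = generate_tumour(
            params, config.grid_spacing, seed=int(tumour_seeds[i])
        )
        images[pid] = (vol, msk)
        records.append(
            PatientRecord(
                pid,
                int(ln[i]),
                int(visual[i]),
                config.scanners[i % len(config.scanners)],
            )
        )
    cohort = Cohort(records)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid, (vol, msk) in images.items():
            write_volume(vol, out_dir / f"{pid}_suv.nii.gz")
            write_mask(msk, out_dir / f"{pid}_mask.nii.gz")
        cohort.to_csv(out_dir / "cohort.csv")
    return cohort, images


def extract_cohort_features(
    cohort: Cohort,
    images: dict[str, tuple[PETVolume, VOIMask]],
    n_levels: int = 64,
) -> Cohort:
    """Attach the 44-feature vector to every record."""
    from .features import extract_features

    rows = {}
    for rec in cohort:
        vol, msk = images[rec.patient_id]
        rows[rec.patient_id] = extract_features(vol, msk, n_levels)
    import pandas as pd

    return cohort.with_features(pd.DataFrame.from_dict(rows, orient="index"))
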