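"""Synthetic EDI-OCT choroid phantoms and cohorts with known ground truth.

No public image set accompanies population CVI studies, so validation runs
on phantoms: a choroid band between two smooth boundary curves, filled with
dark elliptical vessel lumens arranged in the three anatomical layers —
small-calibre choriocapillaris innermost, medium Sattler vessels in the
middle, large Haller vessels outermost — over a brighter stromal matrix,
with depth attenuation and multiplicative speckle on top. The lumen mask is
recorded *before* noise, so every pipeline stage can be scored against an
exact ground truth.

Synthetic cohorts draw covariates from stated normal/Bernoulli marginals
(parameterized to a healthy elderly population) and generate the imaging
outcomes from user-specified linear models plus Gaussian noise, giving a
known regression structure for parameter-recovery tests.

Phantoms are statistical stand-ins: speckle is modelled as Gamma
multiplicative noise and attenuation as a single exponential; no physical
light-propagation model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binarize import BinaryMask, BScan, PixelScale
from .choroid_metrics import BoundaryTrace, ROIPolygon, pixel_centers_in_polygon, subfoveal_window

__all__ = [
    "VesselBand",
    "PhantomSpec",
    "SyntheticScan",
    "generate_scan",
    "true_cvi",
    "TABLE_MARGINALS",
    "DEFAULT_EFFECTS",
    "generate_cohort",
]


@dataclass(frozen=True)
class VesselBand:
    """One choroidal vessel layer.

    ``depth_range`` gives the band's extent as fractions of local choroid
    thickness (0 = Bruch's membrane, 1 = choroid–scleral interface);
    ``count_range`` the inclusive range of lumen counts to draw; and
    ``radius_um_range`` the lumen radius range in *micrometres*. Physical
    radii convert to pixel semi-axes through the (anisotropic) pixel scale,
    with an extra lateral elongation factor for vessels sectioned obliquely
    along their course.
    """

    depth_range: tuple[float, float]
    count_range: tuple[int, int]
    radius_um_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.depth_range
        if not (0 <= lo < hi <= 1):
            raise ValueError(f"depth_range must satisfy 0 <= lo < hi <= 1, got {self.depth_range}")
        if self.count_range[0] > self.count_range[1] or self.count_range[0] < 0:
            raise ValueError(f"bad count_range {self.count_range}")
        if not (0 < self.radius_um_range[0] <= self.radius_um_range[1]):
            raise ValueError(f"bad radius_um_range {self.radius_um_range}")


def _default_bands() -> tuple[VesselBand, ...]:
    # Inner -> outer with increasing lumen calibre, at anatomical sizes:
    # choriocapillaris ~10-25 µm lumens, Sattler ~30-80 µm, Haller up to
    # ~170 µm diameter. Counts are sized so the ellipse union fills roughly
    # two-thirds of the choroid, the vascularity of a healthy subfoveal
    # choroid.
    return (
        VesselBand(depth_range=(0.00, 0.10), count_range=(240, 300), radius_um_range=(5.0, 12.0)),
        VesselBand(depth_range=(0.10, 0.50), count_range=(200, 260), radius_um_range=(18.0, 42.0)),
        VesselBand(depth_range=(0.50, 1.00), count_range=(65, 85), radius_um_range=(48.0, 80.0)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic B-scan.

    Default geometry mimics a 8.9 mm Spectralis line scan downsampled to
    768 columns (11.6 µm/px lateral, 3.87 µm/px axial) with a ~350 µm-thick
    choroid. ``stroma_mean`` and ``lumen_mean`` are the pre-noise
    intensities of the two tissue classes; ``speckle_sd`` the standard
    deviation of the unit-mean multiplicative Gamma speckle; and
    ``attenuation_per_px`` the exponential signal decay per pixel of depth
    below Bruch's membrane.
    """

    height_px: int = 384
    width_px: int = 768
    scale: PixelScale = field(default_factory=lambda: PixelScale(11.6, 3.87))
    upper_mean_row: float = 120.0
    thickness_mean_px: float = 90.0
    thickness_amplitude_px: float = 10.0
    bands: tuple[VesselBand, ...] = field(default_factory=_default_bands)
    lateral_elongation: tuple[float, float] = (1.5, 3.0)
    wall_um: float = 5.0
    stroma_mean: float = 0.65
    lumen_mean: float = 0.18
    retina_mean: float = 0.55
    sclera_mean: float = 0.70
    speckle_sd: float = 0.05
    attenuation_per_px: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 2 or self.width_px < 2:
            raise ValueError("phantom must be at least 2x2 px")
        if not (0 <= self.lumen_mean < self.stroma_mean <= 1):
            raise ValueError("need 0 <= lumen_mean < stroma_mean <= 1")
        if self.speckle_sd < 0 or self.attenuation_per_px < 0:
            raise ValueError("speckle_sd and attenuation_per_px must be non-negative")
        if self.upper_mean_row + self.thickness_mean_px + self.thickness_amplitude_px >= self.height_px:
            raise ValueError("choroid band does not fit in the image")
        for band in self.bands:
            band_px = (band.depth_range[1] - band.depth_range[0]) * self.thickness_mean_px
            max_axial_px = band.radius_um_range[1] / self.scale.axial_um_per_px
            if max_axial_px > band_px:
                raise ValueError(
                    f"lumen radius up to {band.radius_um_range[1]} µm "
                    f"({max_axial_px:.1f} px axial) exceeds band thickness "
                    f"{band_px:.1f} px for band {band.depth_range}"
                )


@dataclass(frozen=True)
class SyntheticScan:
    """Phantom image plus its ground truth."""

    image: BScan
    trace: BoundaryTrace
    lumen_mask: BinaryMask
    true_fraction: float  # luminal fraction within the default 1.5 mm window

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_fraction <= 1.0):
            raise ValueError("true_fraction must lie in [0, 1]")


def _smooth_curve(rng: np.random.Generator, width: int, amplitude: float,
                  n_harmonics: int = 3) -> np.ndarray:
    """Sum of low-frequency sinusoids with random phase, peak ~amplitude."""
    x = np.arange(width) / width
    curve = np.zeros(width)
    for h in range(1, n_harmonics + 1):
        phase = rng.uniform(0, 2 * np.pi)
        curve += rng.uniform(0.3, 1.0) / h * np.sin(2 * np.pi * h * x + phase)
    peak = np.abs(curve).max()
    return curve * (amplitude / peak) if peak > 0 else curve


def generate_scan(spec: PhantomSpec, window_mm: float = 1.5) -> SyntheticScan:
    """Render one phantom scan; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px
    cols = np.arange(W)

    upper = spec.upper_mean_row + _smooth_curve(rng, W, spec.thickness_amplitude_px)
    thickness = spec.thickness_mean_px + _smooth_curve(rng, W, spec.thickness_amplitude_px)
    thickness = np.maximum(thickness, 2.0)
    lower = upper + thickness

    rr, cc = np.mgrid[0:H, 0:W]
    band_mask = (rr >= upper[None, :]) & (rr < lower[None, :])

    lumen = np.zeros((H, W), dtype=bool)
    wall = np.zeros((H, W), dtype=bool)  # stromal vessel walls: keep-out for later lumens

    def _ellipse(r0: float, c0: float, ry: float, rx: float) -> tuple[slice, slice, np.ndarray]:
        r_lo = max(int(r0 - ry) - 1, 0)
        r_hi = min(int(r0 + ry) + 2, H)
        c_lo = max(int(c0 - rx) - 1, 0)
        c_hi = min(int(c0 + rx) + 2, W)
        sub_r, sub_c = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        inside = ((sub_r - r0) / ry) ** 2 + ((sub_c - c0) / rx) ** 2 <= 1.0
        return slice(r_lo, r_hi), slice(c_lo, c_hi), inside

    for band in spec.bands:
        count = int(rng.integers(band.count_range[0], band.count_range[1] + 1))
        if count == 0:
            continue
        # Vessels pack quasi-regularly along the choroid rather than as a
        # pure Poisson scatter: stratify lateral positions (one vessel per
        # equal-width slot, jittered), which keeps the local vascular
        # density as homeostatically tight as in real tissue.
        slots = (np.arange(count) + rng.uniform(0.05, 0.95, size=count)) * (W / count)
        for c0 in slots:
            frac = rng.uniform(*band.depth_range)
            ci = int(np.clip(round(c0), 0, W - 1))
            r0 = upper[ci] + frac * thickness[ci]
            r_um = rng.uniform(*band.radius_um_range)
            elong = rng.uniform(*spec.lateral_elongation)
            ry = r_um / spec.scale.axial_um_per_px
            rx = r_um / spec.scale.lateral_um_per_px * elong
            rs, cs, inner = _ellipse(r0, c0, ry, rx)
            # The wall (bright stromal rim around each lumen) blocks later
            # lumens, so adjacent vessels stay separated by septa instead of
            # merging into one dark blob.
            wy = ry + spec.wall_um / spec.scale.axial_um_per_px
            wx = rx + spec.wall_um / spec.scale.lateral_um_per_px * elong
            rs_w, cs_w, outer = _ellipse(r0, c0, wy, wx)
            lumen[rs, cs] |= inner & ~wall[rs, cs]
            wall[rs_w, cs_w] |= outer
            wall &= ~lumen
    lumen &= band_mask  # ground truth confined to the choroid band

    img = np.full((H, W), spec.retina_mean)
    img[rr >= lower[None, :]] = spec.sclera_mean
    img[band_mask] = spec.stroma_mean
    img[lumen] = spec.lumen_mean

    # Exponential depth attenuation below Bruch's membrane.
    depth_below = np.maximum(rr - upper[None, :], 0.0)
    img *= np.exp(-spec.attenuation_per_px * depth_below)

    # Unit-mean multiplicative Gamma speckle.
    if spec.speckle_sd > 0:
        shape = 1.0 / spec.speckle_sd ** 2
        img *= rng.gamma(shape, 1.0 / shape, size=(H, W))
    img = np.clip(img, 0.0, 1.0)

    trace = BoundaryTrace(cols=cols, upper=upper, lower=lower, fovea_col=W // 2)
    scan_wo_fraction = SyntheticScan(
        image=BScan(pixels=img, scale=spec.scale),
        trace=trace,
        lumen_mask=BinaryMask(dark=lumen),
        true_fraction=0.0,
    )
    roi = subfoveal_window(trace, window_mm, spec.scale)
    frac = true_cvi(scan_wo_fraction, roi) / 100.0
    return SyntheticScan(image=scan_wo_fraction.image, trace=trace,
                         lumen_mask=scan_wo_fraction.lumen_mask, true_fraction=frac)


def true_cvi(scan: SyntheticScan, roi: ROIPolygon) -> float:
    """Ground-truth CVI: lumen pixel centers over choroid pixel centers in the ROI."""
    inside = pixel_centers_in_polygon(roi, shape=scan.image.shape)
    H, W = scan.image.shape
    rr = np.arange(H)[:, None]
    band = (rr >= scan.trace.upper[None, :]) & (rr < scan.trace.lower[None, :])
    denom = int(np.count_nonzero(inside & band))
    if denom == 0:
        raise ValueError("ROI contains no choroid pixel centers")
    num = int(np.count_nonzero(inside & scan.lumen_mask.dark))
    return 100.0 * num / denom


# ---------------------------------------------------------------------------
# Synthetic cohorts

#: Covariate marginals of a healthy elderly Asian population: normal
#: (mean, sd) or Bernoulli probability for 0/1 covariates.
TABLE_MARGINALS: dict[str, tuple] = {
    "age_years": ("normal", 61.53, 8.77),
    "sex_female": ("bernoulli", 0.551),
    "axial_length_mm": ("normal", 23.58, 0.96),
    "iop_mmhg": ("normal", 14.41, 2.84),
    "sbp_mmhg": ("normal", 139.21, 20.63),
    "dbp_mmhg": ("normal", 77.27, 10.85),
    "bmi": ("normal", 26.75, 5.13),
    "glucose_mmol": ("normal", 6.98, 3.35),
    "hba1c_pct": ("normal", 6.26, 1.27),
    "cholesterol_mmol": ("normal", 5.43, 1.26),
    "triglycerides_mmol": ("normal", 1.95, 1.38),
    "creatinine_umol": ("normal", 78.92, 33.11),
    "smoking_current": ("bernoulli", 0.198),
    "alcohol": ("bernoulli", 0.015),
}

#: Default outcome models: a thinner, older choroid and a CVI coupled to
#: thickness, on the scale of a healthy cohort (SFCT ~241 µm, CVI ~65.6%).
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "sfct_um": {"intercept": 486.7, "age_years": -3.99},
    "cvi_percent": {"intercept": 62.7, "sfct_um": 0.012},
}
DEFAULT_NOISE_SD: dict[str, float] = {"sfct_um": 80.0, "cvi_percent": 1.8}


def generate_cohort(n: int, effects: dict[str, dict[str, float]] | None = None,
                    noise_sd: dict[str, float] | float | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic cohort with known regression structure.

    Covariates come from ``TABLE_MARGINALS`` (independent draws). Each
    outcome named in ``effects`` is built as
    ``intercept + sum(coef * covariate) + Normal(0, noise_sd)``; outcomes
    may reference previously generated outcomes (dict order). Screening
    fields (visual acuity, refraction, disease flags, scan quality) are
    generated to *pass* the cohort exclusion filters, so the default cohort
    is analysis-ready. Deterministic per seed.
    """
    if n < 10:
        raise ValueError("need n >= 10 subjects")
    effects = DEFAULT_EFFECTS if effects is None else effects
    if noise_sd is None:
        noise = dict(DEFAULT_NOISE_SD)
    elif isinstance(noise_sd, dict):
        noise = dict(noise_sd)
    else:
        noise = {out: float(noise_sd) for out in effects}
    for out, coefs in effects.items():
        for name, val in coefs.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite effect {name}={val} for outcome {out}")

    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"id": [f"S{i:04d}" for i in range(n)]})
    for col, spec_ in TABLE_MARGINALS.items():
        if spec_[0] == "normal":
            df[col] = rng.normal(spec_[1], spec_[2], size=n)
        else:
            df[col] = (rng.uniform(size=n) < spec_[1]).astype(int)
    # Marginals are literal normals (no truncation), so sample means stay
    # unbiased; rare implausible tail values are harmless for regression use.

    # Anthropometrics consistent with BMI.
    df["height_m"] = rng.normal(1.62, 0.08, size=n).clip(1.3, 2.1)
    df["weight_kg"] = df["bmi"] * df["height_m"] ** 2

    # Screening fields for a healthy, analysis-ready cohort.
    df["logmar_va"] = rng.normal(0.08, 0.08, size=n).clip(-0.1, 0.30)
    df["sphere_d"] = rng.normal(-0.25, 1.5, size=n).clip(-5.5, 5.0)
    df["cylinder_d"] = rng.normal(-0.5, 0.5, size=n).clip(-1.0, 0.0)
    df["glaucoma_flag"] = 0
    df["retinal_disease_flag"] = 0
    df["scan_quality_db"] = rng.normal(26.0, 3.0, size=n).clip(18.0, 40.0)

    for out, coefs in effects.items():
        y = np.full(n, float(coefs.get("intercept", 0.0)))
        for name, coef in coefs.items():
            if name == "intercept":
                continue
            if name not in df.columns:
                raise KeyError(f"effect references unknown covariate {name!r}")
            y = y + coef * df[name].to_numpy(dtype=float)
        y = y + rng.normal(0.0, float(noise.get(out, 0.0)), size=n)
        df[out] = y
    return df
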