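"""Membrane-order metrics: generalized polarization, DPH anisotropy, and
liquid-disordered domain area on vesicle images.

Generalized polarization (GP) of an environment-sensitive dye is
``(I_B - I_R)/(I_B + I_R)`` where I_B and I_R are the blue- and
red-shifted emission intensities (defaults 442 and 496 nm for C-laurdan,
or the 420-460 / 470-510 nm detection bands in two-band live imaging).
Steady-state fluorescence anisotropy is
``r = (I_VV - G*I_VH)/(I_VV + 2*G*I_VH)`` with the grating factor
``G = I_HV/I_HH`` correcting detector polarization bias. Both are
ratiometric and therefore invariant to detector gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LambdaStack",
    "AnisotropyReading",
    "GPMap",
    "gp",
    "channel_for_wavelength",
    "band_channels",
    "stack_gp_channels",
    "region_gp",
    "anisotropy",
    "ld_area_fraction",
    "GP_BLUE_NM",
    "GP_RED_NM",
]

GP_BLUE_NM = 442.0
GP_RED_NM = 496.0

#: Spectral-detector geometry of the reference acquisition: 32 channels
#: from 415 nm at 8.9 nm spacing (covering 415-691 nm).
SPECTRAL_START_NM = 415.0
SPECTRAL_STEP_NM = 8.9
SPECTRAL_N_CHANNELS = 32


@dataclass(frozen=True)
class LambdaStack:
    """Spectral image stack indexed (channel, y, x) with channel geometry."""

    data: np.ndarray
    start_wavelength: float = SPECTRAL_START_NM
    step: float = SPECTRAL_STEP_NM
    pixel_size_um: float | None = None

    def __post_init__(self):
        data = np.asarray(self.data, float)
        if data.ndim != 3 or data.shape[0] < 2:
            raise ValueError("stack must be (channel, y, x) with >= 2 channels")
        if self.step <= 0:
            raise ValueError("channel step must be positive")
        if np.any(data < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def channel_centers(self) -> np.ndarray:
        return self.start_wavelength + self.step * np.arange(self.n_channels)


@dataclass(frozen=True)
class AnisotropyReading:
    """Polarizer-resolved intensities (excitation/emission orientation)."""

    I_VV: float
    I_VH: float
    I_HV: float
    I_HH: float

    def __post_init__(self):
        if min(self.I_VV, self.I_VH, self.I_HV, self.I_HH) <= 0:
            raise ValueError("all polarized intensities must be positive")


@dataclass
class GPMap:
    """Per-pixel GP values with a validity mask (True = valid)."""

    values: np.ndarray
    valid: np.ndarray


def gp(I_B, I_R, floor: float | None = None):
    """Generalized polarization (I_B - I_R)/(I_B + I_R).

    Scalars give a float in [-1, 1]. Arrays give a :class:`GPMap`; pixels
    whose summed intensity is <= ``floor`` (default: 1% of the image's
    99th-percentile sum) are masked invalid.
    """
    b = np.asarray(I_B, float)
    r = np.asarray(I_R, float)
    if b.shape != r.shape:
        raise ValueError("I_B and I_R must have the same shape")
    if np.any(b < 0) or np.any(r < 0):
        raise ValueError("intensities must be non-negative")
    total = b + r
    if b.ndim == 0:
        if total <= 0:
            raise ValueError("I_B + I_R must be positive")
        return float((b - r) / total)
    if not np.any(total > 0):
        raise ValueError("all-zero input")
    if floor is None:
        floor = 0.01 * np.percentile(total, 99)
    valid = total > max(floor, 0.0)
    values = np.zeros_like(total)
    np.divide(b - r, total, out=values, where=valid)
    return GPMap(values=values, valid=valid)


def channel_for_wavelength(stack: LambdaStack, wavelength: float) -> int:
    """0-based index of the channel whose center is nearest ``wavelength``.

    Raises if the wavelength falls outside the detection range by more
    than half a channel spacing. No spectral interpolation is performed.
    """
    centers = stack.channel_centers
    if not (centers[0] - stack.step / 2
            <= wavelength <= centers[-1] + stack.step / 2):
        raise ValueError(
            f"wavelength {wavelength} nm outside detection range "
            f"[{centers[0]}, {centers[-1]}] nm"
        )
    return int(np.argmin(np.abs(centers - wavelength)))


def band_channels(stack: LambdaStack, lo: float, hi: float) -> np.ndarray:
    """Indices of channels whose centers fall within [lo, hi] nm."""
    centers = stack.channel_centers
    idx = np.nonzero((centers >= lo) & (centers <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"no channel centers within [{lo}, {hi}] nm")
    return idx


def stack_gp_channels(
    stack: LambdaStack,
    blue_nm: float = GP_BLUE_NM,
    red_nm: float = GP_RED_NM,
    blue_band: tuple[float, float] | None = None,
    red_band: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Blue and red intensity images from a spectral stack.

    Single-channel mode picks the nearest channel to each wavelength;
    band mode averages the channels whose centers lie within each band
    (a per-channel mean rather than a sum, so that bands holding
    different numbers of channels stay comparable and two-band GP
    reduces to single-channel GP on spectra that are flat within each
    band).
    """
    if blue_band is not None or red_band is not None:
        if blue_band is None or red_band is None:
            raise ValueError("give both bands or neither")
        b = stack.data[band_channels(stack, *blue_band)].mean(axis=0)
        r = stack.data[band_channels(stack, *red_band)].mean(axis=0)
    else:
        b = stack.data[channel_for_wavelength(stack, blue_nm)]
        r = stack.data[channel_for_wavelength(stack, red_nm)]
    return b, r


def region_gp(gp_map: GPMap, mask: np.ndarray) -> tuple[float, float, int]:
    """Mean and SD of GP over the valid pixels of a region mask.

    Returns ``(mean, sd, n_pixels)``; SD is the population SD (ddof=0).
    """
    mask = np.asarray(mask, bool)
    if mask.shape != gp_map.values.shape:
        raise ValueError("mask shape differs from GP map")
    sel = mask & gp_map.valid
    n = int(sel.sum())
    if n == 0:
        raise ValueError("mask overlaps no valid pixels")
    vals = gp_map.values[sel]
    return float(vals.mean()), float(vals.std()), n


def anisotropy(reading: AnisotropyReading, G: float | None = None) -> float:
    """Steady-state anisotropy r = (I_VV - G*I_VH)/(I_VV + 2*G*I_VH).

    The grating factor G defaults to I_HV/I_HH from the reading.
    """
    if G is None:
        G = reading.I_HV / reading.I_HH
    denom = reading.I_VV + 2.0 * G * reading.I_VH
    if denom <= 0:
        raise ValueError("nonpositive anisotropy denominator")
    return float((reading.I_VV - G * reading.I_VH) / denom)


def ld_area_fraction(
    image: np.ndarray,
    pixel_size_um: float,
    n_angle_bins: int = 360,
    ring_rel_width: float = 0.25,
    min_contrast: float = 0.3,
) -> tuple[float, float]:
    """Liquid-disordered area and perimeter fraction on an equatorial
    vesicle image.

    The dye partitions into the Ld phase, so bright arcs of the ring are
    Ld. The ring is located by an algebraic circle fit to
    above-background pixels; ring pixels are binned by polar angle, each
    bin summarized by its radial peak intensity, and bins are split
    bright/dark at the midpoint of the profile's robust extremes. If the
    angular intensity modulation is below ``min_contrast`` (relative
    dynamic range), the vesicle is called single-phase (fraction 1).

    Returns ``(ld_area_um2, ld_perimeter_fraction)``.
    """
    img = np.asarray(image, float)
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    background = np.percentile(img, 50)
    peak = img.max()
    if peak <= background:
        raise ValueError("no ring detected (flat image)")
    fg = img > background + 0.1 * (peak - background)
    if fg.sum() < n_angle_bins // 4:
        raise ValueError("no ring detected (too few foreground pixels)")
    ys, xs = np.nonzero(fg)
    # algebraic (Kasa) circle fit: unlike an intensity-weighted centroid
    # it is not dragged toward a bright Ld arc
    A = np.column_stack([ys, xs, np.ones_like(ys)])
    b_vec = ys.astype(float) ** 2 + xs.astype(float) ** 2
    try:
        coef, *_ = np.linalg.lstsq(A, b_vec, rcond=None)
    except np.linalg.LinAlgError:
        raise ValueError("no ring detected (circle fit failed)") from None
    cy, cx = coef[0] / 2.0, coef[1] / 2.0
    r2 = coef[2] + cy**2 + cx**2
    if not np.isfinite(r2) or r2 <= 0:
        raise ValueError("no ring detected (circle fit degenerate)")
    radius = float(np.sqrt(r2))
    if radius < 3:
        raise ValueError("no ring detected (degenerate radius)")

    yy, xx = np.indices(img.shape)
    dist = np.hypot(yy - cy, xx - cx)
    on_ring = np.abs(dist - radius) <= ring_rel_width * radius
    theta = np.arctan2(yy - cy, xx - cx)[on_ring]
    vals = img[on_ring]
    bins = np.clip(
        ((theta + np.pi) / (2 * np.pi) * n_angle_bins).astype(int),
        0, n_angle_bins - 1,
    )
    # per-angle ring brightness: the radial maximum is insensitive to how
    # pixel radii are distributed within the annulus, unlike the mean
    prof = np.full(n_angle_bins, np.nan)
    for b in range(n_angle_bins):
        sel = bins == b
        if sel.any():
            prof[b] = vals[sel].max()
    covered = ~np.isnan(prof)
    if covered.sum() < n_angle_bins // 2:
        raise ValueError("no ring detected (incomplete ring coverage)")
    prof_c = prof[covered]

    ring_fg = vals > background + 0.1 * (peak - background)
    lo_lvl, hi_lvl = np.percentile(prof_c, [2, 98])
    if hi_lvl - lo_lvl <= min_contrast * hi_lvl:
        # uniform ring: single phase, dye everywhere -> all Ld
        bright_frac = 1.0
        bright_pixels = int(ring_fg.sum())
    else:
        # the angular profile of a phase-separated ring is two-level;
        # split at the midpoint of its robust extremes
        thr = 0.5 * (lo_lvl + hi_lvl)
        bright_bins = np.zeros(n_angle_bins, bool)
        bright_bins[covered] = prof_c > thr
        bright_frac = float(bright_bins[covered].mean())
        bright_pixels = int((ring_fg & bright_bins[bins]).sum())
    area = bright_pixels * pixel_size_um**2
    return area, bright_frac
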