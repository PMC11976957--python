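"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a documented inverse of one analysis stage and returns
its ground truth alongside the artifact, so all stages are testable
without instrument data. Noise models: log-normal multiplicative for MS
intensities, Poisson for photon-counting images, additive Gaussian for
absorbance and electron-image profiles. All randomness flows through a
``numpy.random.Generator`` constructed from an integer seed; the same
seed and parameters give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bilayer_profile import DEFAULT_PIXEL_SIZE_A, BilayerProfile
from .kinetics import GrowthCurve, TurbidityTrace, logistic
from .lipid_model import (
    ChemistryConfig,
    default_chemistry,
    parse_shorthand,
    species_mz,
)
from .membrane_order import (
    GP_BLUE_NM,
    GP_RED_NM,
    SPECTRAL_N_CHANNELS,
    SPECTRAL_START_NM,
    SPECTRAL_STEP_NM,
    LambdaStack,
    channel_for_wavelength,
)
from .quantify import ACQUISITION_WINDOW, PeakList, StandardMix

__all__ = [
    "SimConfig",
    "CrossModel",
    "DEFAULT_SPECIES_PANEL",
    "gen_lipidome",
    "gen_peaklist",
    "gen_gp_stack",
    "gen_bilayer_profile",
    "gen_liposome_image",
    "gen_growth",
    "gen_turbidity",
    "expected_counts",
    "simulate_cross",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    """Seed plus per-generator parameter overrides for CLI scenarios."""

    seed: int
    scenario: str = ""
    params: dict = field(default_factory=dict)


# --- lipidome ----------------------------------------------------------------

#: Default species panel: an asymmetric-saturated-rich fission-yeast-like
#: lipidome. Values are fractions of the polar total; storage species carry
#: fractions relative to the same polar total. Compositions avoid mass
#: degeneracy with each other and with the internal-standard species.
DEFAULT_SPECIES_PANEL: dict[str, float] = {
    # PC 0.30
    "PC(28:0)": 0.10, "PC(34:1)": 0.08, "PC(26:0)": 0.07, "PC(36:2)": 0.05,
    # PE 0.22
    "PE(28:0)": 0.09, "PE(34:1)": 0.07, "PE(26:0)": 0.06,
    # PI 0.18
    "PI(28:0)": 0.08, "PI(34:1)": 0.06, "PI(26:0)": 0.04,
    # PS 0.08
    "PS(34:1)": 0.05, "PS(36:1)": 0.03,
    # minor GPL 0.10
    "PA(34:1)": 0.04, "PG(34:1)": 0.02, "CL(68:4)": 0.02,
    "LPC(18:1)": 0.01, "LPE(18:1)": 0.01,
    # sphingolipids 0.12
    "Cer(44:0:4)": 0.04, "IPC(44:0:4)": 0.05, "MIPC(44:0:4)": 0.03,
    # storage (relative to polar total; excluded from it)
    "DG(34:1)": 0.05, "TG(50:1)": 0.08, "EE(18:2)": 0.03,
}


@dataclass
class LipidomeTruth:
    """Ground truth for one generated sample set."""

    pmol: dict[str, float]           # per-species true amount
    mol_percent: dict[str, float]    # mol% of polar lipids
    fractions: dict[str, float]


def _panel_truth(panel: dict[str, float], total_polar_pmol: float
                 ) -> LipidomeTruth:
    polar = {lbl: f for lbl, f in panel.items()
             if parse_shorthand(lbl).is_polar}
    polar_sum = sum(polar.values())
    if not math.isclose(polar_sum, 1.0, abs_tol=1e-9):
        raise ValueError(
            f"polar fractions must sum to 1 (got {polar_sum})"
        )
    pmol = {lbl: f * total_polar_pmol for lbl, f in panel.items()}
    molpct = {lbl: f * 100.0 for lbl, f in panel.items()}
    return LipidomeTruth(pmol, molpct, dict(panel))


def gen_lipidome(
    seed,
    panel: dict[str, float] | None = None,
    n_samples: int = 6,
    cv: float = 0.05,
    total_polar_pmol: float = 400.0,
    standard_intensity: float = 1e6,
    standards: StandardMix | None = None,
) -> tuple[list[dict[str, float]], LipidomeTruth]:
    """Per-sample intensity tables with internal-standard rows.

    Standard rows sit at ``standard_intensity`` counts; analyte
    intensities are set so that single-point internal-standard
    quantification returns the true pmol, then multiplied by log-normal
    noise of coefficient of variation ``cv``. The default 6 samples
    mirror a 3-biological x 2-technical replicate design.

    Returns ``(samples, truth)`` where samples is a list of
    label -> intensity dicts (canonical species labels).
    """
    rng = _rng(seed)
    panel = panel or DEFAULT_SPECIES_PANEL
    standards = standards or StandardMix.default()
    truth = _panel_truth(panel, total_polar_pmol)
    std_canonical = {
        parse_shorthand(lbl).label: (pmol, cls)
        for lbl, (pmol, cls) in standards.entries.items()
    }
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0
    samples = []
    for _ in range(n_samples):
        table: dict[str, float] = {}
        for lbl, (pmol_std, _) in std_canonical.items():
            table[lbl] = standard_intensity
        for lbl, pmol in truth.pmol.items():
            sp = parse_shorthand(lbl)
            std_label = standards.standard_for_class(sp.lipid_class)
            pmol_std = standards.entries[std_label][0]
            clean = pmol / pmol_std * standard_intensity
            noise = math.exp(rng.normal(0.0, sigma)) if sigma else 1.0
            table[lbl] = clean * noise
        samples.append(table)
    return samples, truth


#: Adduct used per class when generating peak lists (one ion per species).
DEFAULT_CLASS_ADDUCT: dict[str, str] = {
    "PC": "[M+H]+", "LPC": "[M+H]+", "EE": "[M+H]+",
    "DG": "[M+NH4]+", "TG": "[M+NH4]+",
}
_NEGATIVE_DEFAULT = "[M-H]-"


def gen_peaklist(
    seed,
    intensities: dict[str, float],
    ppm_jitter: float = 2.0,
    n_decoys: int = 50,
    config: ChemistryConfig | None = None,
    decoy_clearance_ppm: float = 10.0,
) -> tuple[dict[str, PeakList], list]:
    """Peak lists (one per polarity) from a label -> intensity table.

    Each species contributes one peak at its class-default adduct m/z
    perturbed by a uniform(-jitter, +jitter) ppm error. Decoy peaks are
    drawn uniformly over the acquisition window, re-drawn if they land
    within ``decoy_clearance_ppm`` of a library m/z so they cannot steal
    true assignments. Returns the peak lists and the matching library.
    """
    from .quantify import LibraryEntry

    rng = _rng(seed)
    config = config or default_chemistry()
    library: list[LibraryEntry] = []
    peaks: dict[str, list[tuple[float, float]]] = {
        "positive": [], "negative": []
    }
    for lbl, inten in intensities.items():
        sp = parse_shorthand(lbl)
        pol = config.classes[sp.lipid_class].polarity
        ad_name = DEFAULT_CLASS_ADDUCT.get(sp.lipid_class, _NEGATIVE_DEFAULT)
        ad = config.adducts[ad_name]
        mz = species_mz(sp, ad, config)
        library.append(LibraryEntry(sp, ad, mz))
        eps = rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6
        peaks[pol].append((mz * (1.0 + eps), inten))

    lib_mz = np.array([e.mz for e in library])
    lo, hi = ACQUISITION_WINDOW
    for pol in peaks:
        added = 0
        while added < n_decoys:
            mz = rng.uniform(lo, hi)
            if np.min(np.abs(mz - lib_mz) / lib_mz) * 1e6 < decoy_clearance_ppm:
                continue
            peaks[pol].append((mz, rng.uniform(1e2, 1e4)))
            added += 1

    out = {}
    for pol, pk in peaks.items():
        pk.sort()
        mz = np.array([p[0] for p in pk])
        inten = np.array([p[1] for p in pk])
        out[pol] = PeakList(polarity=pol, mz=mz, intensity=inten)
    return out, sorted(library, key=lambda e: e.mz)


# --- GP spectral stacks ------------------------------------------------------

# Two Gaussian emission components bracketing the dye's ordered (blue) and
# disordered (red) environments. Mixing weight per region is solved so the
# single-channel GP at the default blue/red channels hits the target.
_ORDERED_CENTER, _ORDERED_SIGMA = 445.0, 28.0
_DISORDERED_CENTER, _DISORDERED_SIGMA = 495.0, 32.0


def _component_spectra(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    o = np.exp(-0.5 * ((centers - _ORDERED_CENTER) / _ORDERED_SIGMA) ** 2)
    d = np.exp(-0.5 * ((centers - _DISORDERED_CENTER) / _DISORDERED_SIGMA) ** 2)
    return o, d


def gen_gp_stack(
    seed,
    region_gps: dict[str, float],
    shape: tuple[int, int] = (64, 64),
    snr: float = 20.0,
) -> tuple[LambdaStack, dict[str, np.ndarray], dict[str, float]]:
    """Spectral stack with per-region GP ground truth.

    The image is split into equal horizontal stripes, one per region.
    Each pixel's spectrum mixes the two Gaussian emission components with
    the weight that yields the region's target GP at the default
    blue/red channels; Poisson noise is applied after scaling so the
    brightest channel holds ``snr**2`` expected counts (``snr=inf`` or
    ``<=0`` disables noise). Returns the stack, boolean region masks, and
    the region truths.
    """
    rng = _rng(seed)
    centers = SPECTRAL_START_NM + SPECTRAL_STEP_NM * np.arange(
        SPECTRAL_N_CHANNELS
    )
    o, d = _component_spectra(centers)
    ref = LambdaStack(np.zeros((SPECTRAL_N_CHANNELS, 2, 2)))
    ib = channel_for_wavelength(ref, GP_BLUE_NM)
    ir = channel_for_wavelength(ref, GP_RED_NM)

    ny, nx = shape
    names = list(region_gps)
    edges = np.linspace(0, ny, len(names) + 1).astype(int)
    data = np.zeros((SPECTRAL_N_CHANNELS, ny, nx))
    masks: dict[str, np.ndarray] = {}
    for name, y0, y1 in zip(names, edges[:-1], edges[1:]):
        g = region_gps[name]
        if not -1.0 < g < 1.0:
            raise ValueError(f"GP truth {g} outside (-1, 1)")
        # linear solve for the ordered-component weight w
        co = (o[ib] - o[ir]) - g * (o[ib] + o[ir])
        cd = (d[ib] - d[ir]) - g * (d[ib] + d[ir])
        if co == cd:
            raise ValueError("degenerate spectral components")
        w = cd / (cd - co)
        if not 0.0 <= w <= 1.0:
            raise ValueError(
                f"GP truth {g} unreachable with the emission components"
            )
        spectrum = w * o + (1 - w) * d
        mask = np.zeros(shape, bool)
        mask[y0:y1, :] = True
        masks[name] = mask
        data[:, y0:y1, :] = spectrum[:, None, None]

    if np.isfinite(snr) and snr > 0:
        scale = snr**2 / data.max()
        data = rng.poisson(data * scale).astype(float)
    return LambdaStack(data), masks, dict(region_gps)


# --- cryo-EM liposomes -------------------------------------------------------

#: Width (SD, Å) of the electron-dense head-group troughs the generators
#: paint; a physical property of the bilayer, independent of pixel size.
TROUGH_SIGMA_A = 6.0


def _radial_bilayer(r: np.ndarray, radius_px: float, half_sep_px: float,
                    trough_sigma_px: float, depth: float) -> np.ndarray:
    """Radial intensity: bright background with two head-group troughs."""
    inner = np.exp(-0.5 * ((r - (radius_px - half_sep_px))
                           / trough_sigma_px) ** 2)
    outer = np.exp(-0.5 * ((r - (radius_px + half_sep_px))
                           / trough_sigma_px) ** 2)
    return 1.0 - depth * (inner + outer)


def gen_bilayer_profile(
    seed,
    true_dtt_a: float,
    pixel_size: float = DEFAULT_PIXEL_SIZE_A,
    n_points: int = 81,
    trough_sigma_a: float = TROUGH_SIGMA_A,
    depth: float = 0.5,
    noise_sd_frac: float = 0.05,
    center_jitter_px: float = 2.0,
) -> BilayerProfile:
    """1-D membrane-crossing profile with troughs ``true_dtt_a`` Å apart.

    ``noise_sd_frac`` is additive Gaussian noise as a fraction of the
    trough depth. The bilayer center is jittered so trough positions are
    not pixel-aligned.
    """
    rng = _rng(seed)
    half_sep = true_dtt_a / 2.0 / pixel_size
    trough_sigma_px = trough_sigma_a / pixel_size
    x = np.arange(n_points, dtype=float)
    c = (n_points - 1) / 2.0 + rng.uniform(-center_jitter_px,
                                           center_jitter_px)
    y = 1.0 - depth * (
        np.exp(-0.5 * ((x - c + half_sep) / trough_sigma_px) ** 2)
        + np.exp(-0.5 * ((x - c - half_sep) / trough_sigma_px) ** 2)
    )
    if noise_sd_frac > 0:
        y = y + rng.normal(0.0, noise_sd_frac * depth, size=y.shape)
    return BilayerProfile(y, pixel_size)


def gen_liposome_image(
    seed,
    true_dtt_a: float | tuple[float, float],
    radius_px: float = 120.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE_A,
    trough_sigma_a: float = TROUGH_SIGMA_A,
    depth: float = 0.5,
    noise_sd_frac: float = 0.0,
    n_trace_points: int = 180,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """2-D liposome image with a circular bilayer of known D_TT.

    ``true_dtt_a`` may be a single value or a (thick, thin) pair; the
    pair builds two half-ring arcs of different thickness for domain-
    classification tests. Returns ``(image, trace, truth)`` where trace
    is an (n, 2) array of (row, col) points on the membrane midline.
    """
    rng = _rng(seed)
    if isinstance(true_dtt_a, (tuple, list)):
        dtt_by_angle = np.asarray(true_dtt_a, float)
    else:
        dtt_by_angle = np.array([float(true_dtt_a)])
    if np.any(dtt_by_angle >= 2 * radius_px * pixel_size):
        raise ValueError("D_TT must be smaller than the liposome diameter")

    margin = int(radius_px * 0.4) + 20
    n = int(2 * (radius_px + margin))
    cy = cx = n / 2.0
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)

    img = np.ones((n, n))
    n_arcs = dtt_by_angle.size
    arc_edges = np.linspace(-np.pi, np.pi, n_arcs + 1)
    for j, (dtt, a0, a1) in enumerate(zip(dtt_by_angle, arc_edges[:-1],
                                          arc_edges[1:])):
        # the final arc is edge-inclusive so theta == pi pixels belong to it
        if j == len(dtt_by_angle) - 1:
            sel = (theta >= a0) & (theta <= a1)
        else:
            sel = (theta >= a0) & (theta < a1)
        half_sep = dtt / 2.0 / pixel_size
        img[sel] = _radial_bilayer(r[sel], radius_px, half_sep,
                                   trough_sigma_a / pixel_size, depth)
    if noise_sd_frac > 0:
        img = img + rng.normal(0.0, noise_sd_frac * depth, size=img.shape)

    ang = np.linspace(-np.pi, np.pi, n_trace_points, endpoint=False)
    trace = np.column_stack([cy + radius_px * np.sin(ang),
                             cx + radius_px * np.cos(ang)])
    truth = {
        "dtt_angstrom": dtt_by_angle.tolist(),
        "radius_px": radius_px,
        "pixel_size": pixel_size,
        "center": (cy, cx),
    }
    return img, trace, truth


# --- growth and turbidity ----------------------------------------------------

def gen_growth(
    seed,
    K: float = 1.0,
    N0: float = 0.1,
    r: float = 0.5,
    t_end_h: float = 24.0,
    dt_h: float = 1.0,
    cv: float = 0.02,
) -> GrowthCurve:
    """Logistic growth curve sampled every ``dt_h`` hours (default 60 min)
    with multiplicative log-normal OD noise of coefficient of variation
    ``cv``."""
    rng = _rng(seed)
    t = np.arange(0.0, t_end_h + dt_h / 2, dt_h)
    od = logistic(t, K, N0, r)
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv**2))
        od = od * np.exp(rng.normal(0.0, sigma, size=od.shape))
    return GrowthCurve(t, od)


def gen_turbidity(
    seed,
    A0: float = 1.0,
    Ainf: float = 0.4,
    k: float = 0.02,
    duration_s: float = 360.0,
    dt_s: float = 2.0,
    noise_sd_frac: float = 0.01,
) -> TurbidityTrace:
    """Exponential turbidity decay over the 6-min assay window with
    additive Gaussian noise of SD ``noise_sd_frac * A0``."""
    rng = _rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    a = Ainf + (A0 - Ainf) * np.exp(-k * t)
    if noise_sd_frac > 0:
        a = a + rng.normal(0.0, noise_sd_frac * A0, size=a.shape)
    return TurbidityTrace(t, a)


# --- genetic cross -----------------------------------------------------------

@dataclass(frozen=True)
class CrossModel:
    """Two-locus tetrad segregation with genotype-dependent viability."""

    n_spores: int = 189
    double_mutant_fraction: float = 0.25
    baseline_viability: float = 0.68
    double_mutant_viability: float = 0.0

    def __post_init__(self):
        for p in (self.double_mutant_fraction, self.baseline_viability,
                  self.double_mutant_viability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


GENOTYPES = ("wild_type", "single_a", "single_b", "double_mutant")


def expected_counts(model: CrossModel) -> dict[str, float]:
    """Expected genotype counts among dissected spores.

    The headline expectation, ``expected_double_mutants``, is the integer
    floor of n_spores x double_mutant_fraction (e.g. 47 of 189 at 25%);
    per-genotype viable expectations apply the viability probabilities.
    """
    n = model.n_spores
    f = model.double_mutant_fraction
    single_frac = (1.0 - f) / 3.0
    out = {
        "expected_double_mutants": math.floor(n * f),
        "viable_double_mutants": n * f * model.double_mutant_viability,
    }
    for g in GENOTYPES[:3]:
        out[f"viable_{g}"] = n * single_frac * model.baseline_viability
    return out


def simulate_cross(model: CrossModel, seed) -> dict[str, dict[str, int]]:
    """Draw spore genotypes (1:1:1:1 two-locus segregation, independent
    assortment) and apply genotype-dependent viability.

    Returns per-genotype ``{"dissected": n, "viable": m}``.
    """
    rng = _rng(seed)
    f = model.double_mutant_fraction
    probs = [(1 - f) / 3.0] * 3 + [f]
    counts = rng.multinomial(model.n_spores, probs)
    out = {}
    for g, n in zip(GENOTYPES, counts):
        v = (model.double_mutant_viability if g == "double_mutant"
             else model.baseline_viability)
        viable = int(rng.binomial(n, v)) if n else 0
        out[g] = {"dissected": int(n), "viable": viable}
    return out
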