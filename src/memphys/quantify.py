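"""Shotgun-lipidomics quantification and GC-MS calibration.

Implements the identification/quantification chain used for direct-infusion
lipidomics: peak assignment against an in-silico m/z library at a ppm
tolerance, single-point internal-standard quantification (analyte intensity
over class-standard intensity times the spiked pmol), normalization to mol%
of polar lipids (storage classes DG/TG/EE excluded from the denominator),
linear calibration-curve quantification for GC-MS response ratios, and the
regression-based exclusion of samples with anomalous lipid content relative
to culture density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipid_model import (
    Adduct,
    ChemistryConfig,
    LipidSpecies,
    default_chemistry,
    parse_shorthand,
    species_mz,
)

__all__ = [
    "PeakList",
    "LibraryEntry",
    "PeakAssignment",
    "MatchResult",
    "StandardMix",
    "QuantifiedLipidome",
    "CalibrationCurve",
    "build_library",
    "match_peaks",
    "quantify_internal_standard",
    "mol_percent_polar",
    "fit_calibration",
    "quantify_calibrated",
    "od_outlier_filter",
    "DEFAULT_STANDARD_MIX",
    "DEFAULT_CLASS_STANDARD_MAP",
    "ACQUISITION_WINDOW",
]

#: Direct-infusion acquisition window (m/z); library entries outside it are
#: dropped at construction.
ACQUISITION_WINDOW = (350.0, 1200.0)


@dataclass(frozen=True)
class PeakList:
    polarity: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        mz = np.asarray(self.mz, float)
        inten = np.asarray(self.intensity, float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class LibraryEntry:
    species: LipidSpecies
    adduct: Adduct
    mz: float


@dataclass(frozen=True)
class PeakAssignment:
    peak_index: int
    mz: float
    intensity: float
    entry: LibraryEntry
    ppm_error: float


@dataclass
class MatchResult:
    assignments: list[PeakAssignment]
    unassigned: list[int]
    ambiguous: list[tuple[int, list[LibraryEntry]]]

    def intensity_by_species(self) -> dict[str, float]:
        """Most-intense assigned peak intensity per species label."""
        return {a.entry.species.label: a.intensity for a in self.assignments}


def build_library(
    species: list[LipidSpecies],
    adducts: list[Adduct] | None = None,
    config: ChemistryConfig | None = None,
    window: tuple[float, float] = ACQUISITION_WINDOW,
) -> list[LibraryEntry]:
    """In-silico m/z library: each species with its class-polarity adducts.

    Species whose class is acquired in positive mode get the positive-mode
    adducts and vice versa; entries outside the acquisition window are
    excluded.
    """
    config = config or default_chemistry()
    if adducts is None:
        adducts = list(config.adducts.values())
    entries = []
    for sp in species:
        pol = config.classes[sp.lipid_class].polarity
        for ad in adducts:
            if ad.polarity != pol:
                continue
            mz = species_mz(sp, ad, config)
            if window[0] <= mz <= window[1]:
                entries.append(LibraryEntry(sp, ad, mz))
    return sorted(entries, key=lambda e: e.mz)


def match_peaks(
    peaks: PeakList,
    library: list[LibraryEntry],
    ppm_tol: float = 3.0,
) -> MatchResult:
    """Assign peaks to library entries within a ppm tolerance.

    A peak is assignable to entry e iff ``|mz_p - mz_e|/mz_e * 1e6 <=
    ppm_tol``. Each peak goes to at most one entry (nearest in ppm); when
    several peaks match one entry, the most intense wins. Two entries whose
    expected m/z coincide within tolerance of one peak are reported as
    ambiguous and the peak is not assigned.
    """
    if not library:
        raise ValueError("empty library")
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")

    lib_mz = np.array([e.mz for e in library])
    order = np.argsort(lib_mz)
    lib_mz = lib_mz[order]
    lib = [library[i] for i in order]

    best_for_entry: dict[int, PeakAssignment] = {}
    unassigned: list[int] = []
    ambiguous: list[tuple[int, list[LibraryEntry]]] = []

    for pi, (mz, inten) in enumerate(zip(peaks.mz, peaks.intensity)):
        ppm = np.abs(mz - lib_mz) / lib_mz * 1e6
        within = np.nonzero(ppm <= ppm_tol)[0]
        if within.size == 0:
            unassigned.append(pi)
            continue
        j = within[np.argmin(ppm[within])]
        # distinct species both within tolerance at (near-)identical m/z
        clash = [
            k for k in within
            if k != j
            and abs(lib_mz[k] - lib_mz[j]) / lib_mz[j] * 1e6 <= ppm_tol
            and lib[k].species != lib[j].species
        ]
        if clash:
            ambiguous.append((pi, [lib[j]] + [lib[k] for k in clash]))
            continue
        cand = PeakAssignment(pi, float(mz), float(inten), lib[j],
                              float(ppm[j]))
        prev = best_for_entry.get(j)
        if prev is None or cand.intensity > prev.intensity:
            if prev is not None:
                unassigned.append(prev.peak_index)
            best_for_entry[j] = cand
        else:
            unassigned.append(pi)

    return MatchResult(
        assignments=sorted(best_for_entry.values(), key=lambda a: a.entry.mz),
        unassigned=sorted(unassigned),
        ambiguous=ambiguous,
    )


# --- internal-standard quantification ----------------------------------------

#: Spiked internal-standard mix: label -> (amount pmol, quantified class).
DEFAULT_STANDARD_MIX: dict[str, tuple[float, str]] = {
    "PC(15:0/18:1-d7)": (35.0, "PC"),
    "PE(15:0/18:1-d7)": (24.0, "PE"),
    "PI(15:0/18:1-d7)": (20.0, "PI"),
    "PS(15:0/18:1-d7)": (11.0, "PS"),
    "PG(15:0/18:1-d7)": (4.0, "PG"),
    "PA(15:0/18:1-d7)": (4.0, "PA"),
    "CL(tetra14:1)": (2.0, "CL"),
    "Cer(t18:0/16:0)": (5.0, "Cer"),
    "DG(15:0/18:1-d7)": (5.0, "DG"),
    "TG(15:0/18:1-d7/15:0)": (7.0, "TG"),
    "CE(18:1)": (9.0, "EE"),
}

#: Classes without their own spiked standard borrow a related class's
#: standard (lyso -> parent, methylated PE -> PE, complex sphingo -> Cer).
DEFAULT_CLASS_STANDARD_MAP: dict[str, str] = {
    "LPC": "PC",
    "LPE": "PE",
    "LPI": "PI",
    "LPS": "PS",
    "MMPE": "PE",
    "DMPE": "PE",
    "IPC": "Cer",
    "MIPC": "Cer",
}


@dataclass(frozen=True)
class StandardMix:
    """Internal-standard species with spiked amounts and target classes."""

    entries: dict[str, tuple[float, str]]  # label -> (pmol, target class)
    class_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_STANDARD_MAP)
    )

    def __post_init__(self):
        if any(amount <= 0 for amount, _ in self.entries.values()):
            raise ValueError("standard amounts must be positive")
        targets = [t for _, t in self.entries.values()]
        if len(set(targets)) != len(targets):
            raise ValueError("one standard entry per quantified class")

    @classmethod
    def default(cls) -> "StandardMix":
        return cls(dict(DEFAULT_STANDARD_MIX))

    def standard_for_class(self, lipid_class: str) -> str | None:
        """Label of the standard quantifying a class, or None."""
        target = self.class_map.get(lipid_class, lipid_class)
        for label, (_, tcls) in self.entries.items():
            if tcls == target:
                return label
        return None

    def species(self) -> list[LipidSpecies]:
        return [parse_shorthand(lbl) for lbl in self.entries]


@dataclass
class QuantifiedLipidome:
    """Per-species pmol and mol%-of-polar-lipids for one sample."""

    sample_id: str
    amounts: dict[str, float]  # species label -> pmol
    mol_percent: dict[str, float] = field(default_factory=dict)
    unquantified_classes: list[str] = field(default_factory=list)
    od: float | None = None

    def species(self) -> list[LipidSpecies]:
        return [parse_shorthand(lbl) for lbl in self.amounts]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: sample,species,class,carbons,db,oh,pmol,molpct_polar,is_polar."""
        rows = []
        for label, pmol in self.amounts.items():
            sp = parse_shorthand(label)
            rows.append({
                "sample": self.sample_id,
                "species": label,
                "class": sp.lipid_class,
                "carbons": sp.carbons,
                "db": sp.double_bonds,
                "oh": sp.hydroxyls,
                "pmol": pmol,
                "molpct_polar": self.mol_percent.get(label, math.nan),
                "is_polar": sp.is_polar,
            })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str | None = None
                   ) -> "QuantifiedLipidome":
        if sample_id is not None:
            df = df[df["sample"] == sample_id]
        else:
            ids = df["sample"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds multiple samples; pass sample_id")
            sample_id = ids[0]
        return cls(
            sample_id=str(sample_id),
            amounts=dict(zip(df["species"], df["pmol"].astype(float))),
            mol_percent=dict(
                zip(df["species"], df["molpct_polar"].astype(float))
            ),
        )


def quantify_internal_standard(
    intensities: dict[str, float],
    standards: StandardMix | None = None,
    sample_id: str = "sample",
) -> QuantifiedLipidome:
    """Single-point internal-standard quantification.

    amount(species) = intensity(species) / intensity(class standard)
    x pmol(class standard). Classes whose standard is missing or has zero
    intensity are reported as unquantifiable and skipped; the run continues.
    No isotope-overlap correction is applied.
    """
    standards = standards or StandardMix.default()
    # labels may arrive in per-chain or sum-composition form; compare on
    # the canonical shorthand
    canon = {parse_shorthand(lbl).label: v for lbl, v in intensities.items()}
    std_canon = {
        parse_shorthand(lbl).label: lbl for lbl in standards.entries
    }
    std_intensity = {
        lbl: canon.get(c, 0.0) for c, lbl in std_canon.items()
    }
    amounts: dict[str, float] = {}
    dead_classes: set[str] = set()
    for label, inten in canon.items():
        if label in std_canon:
            continue
        sp = parse_shorthand(label)
        std_label = standards.standard_for_class(sp.lipid_class)
        if std_label is None or std_intensity[std_label] <= 0:
            dead_classes.add(sp.lipid_class)
            continue
        pmol_std = standards.entries[std_label][0]
        amounts[label] = inten / std_intensity[std_label] * pmol_std
    return QuantifiedLipidome(
        sample_id=sample_id,
        amounts=amounts,
        unquantified_classes=sorted(dead_classes),
    )


def mol_percent_polar(lipidome: QuantifiedLipidome) -> QuantifiedLipidome:
    """Fill mol%-of-polar-lipids in place (and return the lipidome).

    Polar lipids are all measured lipids except the storage classes DG, TG
    and EE; storage species keep a mol% relative to the same polar
    denominator but are flagged non-polar in the tidy output.
    """
    polar_total = sum(
        pmol for lbl, pmol in lipidome.amounts.items()
        if parse_shorthand(lbl).is_polar
    )
    if polar_total <= 0:
        raise ValueError("no polar species with positive amount")
    lipidome.mol_percent = {
        lbl: pmol / polar_total * 100.0
        for lbl, pmol in lipidome.amounts.items()
    }
    return lipidome


# --- GC-MS calibration --------------------------------------------------------

@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response-ratio calibration (analyte/IS vs concentration ratio)."""

    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def fit_calibration(
    concentrations: np.ndarray,
    responses: np.ndarray,
    weighting: str = "none",
) -> CalibrationCurve:
    """Least-squares line through calibration points.

    ``weighting='1/x'`` applies inverse-concentration weights (all
    concentrations must then be positive); default is unweighted.
    """
    x = np.asarray(concentrations, float)
    y = np.asarray(responses, float)
    if x.size < 2:
        raise ValueError("calibration needs at least 2 points")
    if weighting == "none":
        w = np.ones_like(x)
    elif weighting == "1/x":
        if np.any(x <= 0):
            raise ValueError("1/x weighting requires positive concentrations")
        w = 1.0 / x
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    W = np.diag(w)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    slope, intercept = float(beta[0]), float(beta[1])
    fitted = slope * x + intercept
    ss_res = float(np.sum(w * (y - fitted) ** 2))
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(x, y, slope, intercept, r2)


def quantify_calibrated(
    curve: CalibrationCurve,
    response_ratio: float,
    od: float | None = None,
) -> tuple[float, bool]:
    """Invert the calibration: concentration = (response - intercept)/slope.

    Returns ``(concentration, below_range)``; dividing by ``od`` when given
    yields per-OD units. Negative concentrations are reported with the
    below-range flag rather than clipped.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    conc = (response_ratio - curve.intercept) / curve.slope
    if od is not None:
        if od <= 0:
            raise ValueError("OD must be positive")
        conc /= od
    return conc, conc < 0


# --- OD vs lipid-content outlier exclusion -----------------------------------

@dataclass
class OutlierFilterResult:
    kept: np.ndarray          # indices into the input
    excluded: np.ndarray
    slope: float
    intercept: float
    skipped: bool = False
    reason: str = ""


def od_outlier_filter(
    od: np.ndarray,
    content: np.ndarray,
    threshold: float = 2.5,
) -> OutlierFilterResult:
    """Exclude samples with anomalous lipid content relative to culture OD.

    Ordinary least squares of content on OD; samples whose absolute
    externally studentized (leave-one-out) residual exceeds ``threshold``
    are excluded, and the line is refit once on the keepers. With fewer
    than 4 samples, or a degenerate (zero-variance) predictor, the filter
    is skipped with a warning and nothing is excluded.
    """
    import statsmodels.api as sm

    od = np.asarray(od, float)
    content = np.asarray(content, float)
    n = od.size
    if n < 4:
        warnings.warn("fewer than 4 samples; outlier filter skipped")
        line = _ols_line(od, content) if n >= 2 and np.ptp(od) > 0 else (np.nan, np.nan)
        return OutlierFilterResult(np.arange(n), np.array([], int),
                                   line[0], line[1], skipped=True,
                                   reason="n < 4")
    if np.ptp(od) == 0:
        warnings.warn("zero-variance OD; outlier filter skipped")
        return OutlierFilterResult(np.arange(n), np.array([], int),
                                   np.nan, np.nan, skipped=True,
                                   reason="degenerate predictor")
    X = sm.add_constant(od)
    fit = sm.OLS(content, X).fit()
    resid = fit.get_influence().resid_studentized_external
    # exact-fit keepers make the studentized residual blow up only for the
    # true outlier; NaN (zero residual variance after deletion) means the
    # deleted point was the sole source of variance -> treat as outlier
    bad = np.abs(np.nan_to_num(resid, nan=np.inf)) > threshold
    keep = np.nonzero(~bad)[0]
    excl = np.nonzero(bad)[0]
    if keep.size >= 2 and np.ptp(od[keep]) > 0:
        slope, intercept = _ols_line(od[keep], content[keep])
    else:
        slope, intercept = fit.params[1], fit.params[0]
    return OutlierFilterResult(keep, excl, float(slope), float(intercept))


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
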