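"""Lipid nomenclature, elemental composition, and adduct m/z.

Lipid species are handled at the sum-composition level used by shotgun
lipidomics: a class plus the total number of fatty-acyl (and, for
sphingolipids, long-chain-base) carbons, double bonds and hydroxyl groups,
written in the standard shorthand, e.g. ``PC(34:1)`` or ``Cer(44:0:4)``.
Explicit per-chain labels with deuterium tags, as printed for internal
standards (``PC(15:0/18:1-d7)``), are collapsed to the same sum composition
with the deuterium count retained for mass computation.

Elemental formulas are built from a per-class base formula at the (0:0)
reference composition plus CH2/H2/O increments; monoisotopic masses come
from a shipped IUPAC atomic-mass table, so results are bit-reproducible
with no external services.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "LipidSpecies",
    "ElementalFormula",
    "Adduct",
    "ChemistryConfig",
    "load_chemistry",
    "default_chemistry",
    "species_mz",
    "parse_shorthand",
    "format_shorthand",
    "species_formula",
    "monoisotopic_mass",
    "expected_mz",
    "LIPID_CLASSES",
]

#: Classes recognised by the shorthand grammar.
LIPID_CLASSES = (
    "PC", "LPC", "PE", "LPE", "MMPE", "DMPE", "PI", "LPI", "PS", "LPS",
    "PA", "PG", "CL", "Cer", "IPC", "MIPC", "DG", "TG", "EE",
)

#: Sphingolipid classes; the only ones that may carry hydroxyl counts.
SPHINGOLIPID_CLASSES = frozenset({"Cer", "IPC", "MIPC"})

#: Storage classes excluded from the polar-lipid denominator.
NONPOLAR_CLASSES = frozenset({"DG", "TG", "EE"})

_H_MASS = 1.00782503207
_D_MASS = 2.01410177812


class LipidParseError(ValueError):
    """A shorthand label that the grammar cannot interpret."""


class UnknownLipidClassError(LipidParseError):
    """A label whose class prefix is not a recognised lipid class."""


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at sum-composition resolution.

    Parameters
    ----------
    lipid_class : str
        One of :data:`LIPID_CLASSES`.
    carbons : int
        Total fatty-acyl + long-chain-base carbons.
    double_bonds : int
        Total carbon-carbon double bonds across all chains.
    hydroxyls : int
        Total hydroxyl groups (sphingolipids only; 0 otherwise).
    deuterium : int
        Number of deuterium labels (internal standards); affects mass only.
    """

    lipid_class: str
    carbons: int
    double_bonds: int
    hydroxyls: int = 0
    deuterium: int = 0

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise UnknownLipidClassError(
                f"unknown lipid class {self.lipid_class!r}"
            )
        if self.carbons < 0 or self.double_bonds < 0 or self.hydroxyls < 0:
            raise ValueError("composition counts must be non-negative")
        if self.double_bonds > self.carbons:
            raise ValueError(
                f"double bonds ({self.double_bonds}) exceed carbons "
                f"({self.carbons})"
            )
        if self.hydroxyls > 0 and self.lipid_class not in SPHINGOLIPID_CLASSES:
            raise ValueError(
                f"hydroxyls only allowed for sphingolipid classes, "
                f"not {self.lipid_class}"
            )

    @property
    def label(self) -> str:
        """Canonical shorthand label."""
        return format_shorthand(self)

    @property
    def is_polar(self) -> bool:
        """Whether the species counts towards the polar-lipid denominator."""
        return self.lipid_class not in NONPOLAR_CLASSES

    def unlabeled(self) -> "LipidSpecies":
        """The same sum composition without isotope labels."""
        return replace(self, deuterium=0)


@dataclass(frozen=True)
class ElementalFormula:
    """Element-symbol -> count mapping with element-wise arithmetic."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "ElementalFormula":
        items = tuple(sorted((el, int(n)) for el, n in counts.items() if n))
        if any(n < 0 for _, n in items):
            raise ValueError("element counts must be non-negative")
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = self.as_dict()
        for el, n in other.counts:
            out[el] = out.get(el, 0) + n
        return ElementalFormula.from_dict(out)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = self.as_dict()
        for el, n in other.counts:
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {el}"
                )
        return ElementalFormula.from_dict(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalFormula.from_dict(
            {el: n * k for el, n in self.counts}
        )

    __rmul__ = __mul__

    def hill(self) -> str:
        """Hill-notation string (C, H, then alphabetical)."""
        d = self.as_dict()
        parts = []
        for el in ("C", "H"):
            if el in d:
                n = d.pop(el)
                parts.append(el + (str(n) if n != 1 else ""))
        for el in sorted(d):
            parts.append(el + (str(d[el]) if d[el] != 1 else ""))
        return "".join(parts)


_CH2 = ElementalFormula.from_dict({"C": 1, "H": 2})
_H2 = ElementalFormula.from_dict({"H": 2})
_O = ElementalFormula.from_dict({"O": 1})


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct: neutral-mass delta and charge.

    ``mass_delta`` includes the electron mass, so
    ``(M + mass_delta)/|charge|`` is directly the expected m/z.
    """

    name: str
    polarity: str
    mass_delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        if (self.charge > 0) != (self.polarity == "positive"):
            raise ValueError(
                f"adduct {self.name}: polarity {self.polarity} inconsistent "
                f"with charge {self.charge}"
            )


@dataclass(frozen=True)
class ClassInfo:
    base: ElementalFormula
    polarity: str
    polar: bool
    n_chains: int
    sphingo: bool = False


@dataclass(frozen=True)
class ChemistryConfig:
    """Atomic masses, per-class base formulas, and the adduct table."""

    atomic_masses: dict[str, float] = field(default_factory=dict)
    electron_mass: float = 0.0
    classes: dict[str, ClassInfo] = field(default_factory=dict)
    adducts: dict[str, Adduct] = field(default_factory=dict)


def load_chemistry(path: str | Path | None = None) -> ChemistryConfig:
    """Load the chemistry tables, by default the shipped configuration.

    Parameters
    ----------
    path : optional
        A YAML file with the same schema as the shipped
        ``data/chemistry.yaml``, for user overrides.
    """
    if path is None:
        text = (
            resources.files("memphys") / "data" / "chemistry.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    classes = {
        name: ClassInfo(
            base=ElementalFormula.from_dict(info["base"]),
            polarity=info["polarity"],
            polar=bool(info["polar"]),
            n_chains=int(info["n_chains"]),
            sphingo=bool(info.get("sphingo", False)),
        )
        for name, info in raw["classes"].items()
    }
    adducts = {
        name: Adduct(
            name=name,
            polarity=info["polarity"],
            mass_delta=float(info["mass_delta"]),
            charge=int(info["charge"]),
        )
        for name, info in raw["adducts"].items()
    }
    return ChemistryConfig(
        atomic_masses={k: float(v) for k, v in raw["atomic_masses"].items()},
        electron_mass=float(raw["electron_mass"]),
        classes=classes,
        adducts=adducts,
    )


_DEFAULT_CHEMISTRY: ChemistryConfig | None = None


def default_chemistry() -> ChemistryConfig:
    global _DEFAULT_CHEMISTRY
    if _DEFAULT_CHEMISTRY is None:
        _DEFAULT_CHEMISTRY = load_chemistry()
    return _DEFAULT_CHEMISTRY


# --- shorthand grammar ------------------------------------------------------

_LABEL_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z]+)\s*\(\s*(?P<body>[^()]*?)\s*\)"
    r"(?:-d(?P<dn>\d+))?\s*$"
)
_SUM_RE = re.compile(
    r"^(?P<c>\d+)\s*:\s*(?P<d>\d+)(?:\s*:\s*(?P<h>\d+))?$"
)
_CHAIN_RE = re.compile(
    r"^(?P<pfx>tetra|[dt](?=\d))?(?P<c>\d+):(?P<d>\d+)(?:-d(?P<dn>\d+))?$"
)


def parse_shorthand(label: str) -> LipidSpecies:
    """Parse a shorthand lipid label into a :class:`LipidSpecies`.

    Accepts sum-composition labels ``CLASS(c:d)`` and ``CLASS(c:d:h)``
    with optional whitespace, and per-chain labels such as
    ``PC(15:0/18:1-d7)``, ``TG(15:0/18:1-d7/15:0)``, ``CL(tetra14:1)``
    and ``Cer(t18:0/16:0)`` (``d``/``t`` long-chain-base prefixes mark 2
    and 3 hydroxyls; ``-dN`` marks N deuterium labels; ``tetra`` repeats
    a chain four times).
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise LipidParseError(f"malformed lipid label {label!r}")
    cls = m.group("cls")
    if cls == "CE":  # cholesteryl-ester standards quantify the ester class
        cls = "EE"
    if cls not in LIPID_CLASSES:
        raise UnknownLipidClassError(
            f"unknown lipid class {cls!r} in label {label!r}"
        )
    body = m.group("body")
    outer_d = int(m.group("dn")) if m.group("dn") else 0

    sm = _SUM_RE.match(body)
    if sm is not None:
        c, d = int(sm.group("c")), int(sm.group("d"))
        h = int(sm.group("h")) if sm.group("h") is not None else 0
        return LipidSpecies(cls, c, d, h, outer_d)

    # per-chain notation
    carbons = double_bonds = hydroxyls = deuterium = 0
    for chain in body.split("/"):
        chain = chain.strip()
        cm = _CHAIN_RE.match(chain)
        if cm is None:
            raise LipidParseError(
                f"malformed chain token {chain!r} in label {label!r}"
            )
        mult = 1
        pfx = cm.group("pfx")
        if pfx == "tetra":
            mult = 4
        elif pfx == "d":
            hydroxyls += 2
        elif pfx == "t":
            hydroxyls += 3
        carbons += mult * int(cm.group("c"))
        double_bonds += mult * int(cm.group("d"))
        if cm.group("dn"):
            deuterium += int(cm.group("dn"))
    if cls not in SPHINGOLIPID_CLASSES:
        hydroxyls = 0
    return LipidSpecies(cls, carbons, double_bonds, hydroxyls,
                        deuterium + outer_d)


def format_shorthand(species: LipidSpecies) -> str:
    """Canonical shorthand label, ``CLASS(c:d)`` or ``CLASS(c:d:h)``."""
    body = f"{species.carbons}:{species.double_bonds}"
    if species.lipid_class in SPHINGOLIPID_CLASSES:
        body += f":{species.hydroxyls}"
    suffix = f"-d{species.deuterium}" if species.deuterium else ""
    return f"{species.lipid_class}({body}){suffix}"


# --- elemental formulas and masses ------------------------------------------

def species_formula(
    species: LipidSpecies, config: ChemistryConfig | None = None
) -> ElementalFormula:
    """Elemental formula of a species from its class base formula.

    formula = base + carbons*CH2 - double_bonds*H2 + hydroxyls*O, with
    ``deuterium`` protium atoms swapped for deuterium.
    """
    config = config or default_chemistry()
    try:
        info = config.classes[species.lipid_class]
    except KeyError:
        raise KeyError(
            f"class {species.lipid_class!r} missing from chemistry config"
        ) from None
    formula = (
        info.base
        + species.carbons * _CH2
        + species.hydroxyls * _O
    ) - species.double_bonds * _H2
    if species.deuterium:
        counts = formula.as_dict()
        if counts.get("H", 0) < species.deuterium:
            raise ValueError("more deuterium labels than hydrogens")
        counts["H"] -= species.deuterium
        counts["D"] = counts.get("D", 0) + species.deuterium
        formula = ElementalFormula.from_dict(counts)
    return formula


def monoisotopic_mass(
    formula: ElementalFormula, config: ChemistryConfig | None = None
) -> float:
    """Monoisotopic mass in Da: sum of count x atomic monoisotopic mass."""
    config = config or default_chemistry()
    mass = 0.0
    for el, n in formula.counts:
        try:
            mass += n * config.atomic_masses[el]
        except KeyError:
            raise KeyError(f"unknown element {el!r}") from None
    return mass


def expected_mz(
    formula: ElementalFormula,
    adduct: Adduct,
    config: ChemistryConfig | None = None,
) -> float:
    """Expected m/z of an adduct ion, (M + mass_delta)/|charge|."""
    if adduct.charge == 0:
        raise ValueError("adduct charge must be nonzero")
    mass = monoisotopic_mass(formula, config)
    return (mass + adduct.mass_delta) / abs(adduct.charge)


def species_mz(
    species: LipidSpecies,
    adduct: Adduct,
    config: ChemistryConfig | None = None,
) -> float:
    """Convenience: expected m/z straight from a species."""
    return expected_mz(species_formula(species, config), adduct, config)
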