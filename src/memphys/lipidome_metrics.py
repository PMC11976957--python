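"""Summary statistics on quantified lipidomes.

All metrics operate on mol%-of-polar-lipids profiles. The double-bond
index (DBI) and average chain length are mol%-weighted means of total
fatty-acyl double bonds and carbons over a declared glycerophospholipid
class set (default PC, PI, PE, PS). The PE/(PC+PI) ratio compares
non-bilayer-prone to bilayer-forming phospholipid classes. SoamD is the
sum of absolute mol% differences between a sample and a reference
lipidome over the union of their species - a total-variation-style score
of lipidome remodeling (range 0 to 200).
"""

from __future__ import annotations

from dataclasses import dataclass

from .lipid_model import LipidSpecies, parse_shorthand
from .quantify import QuantifiedLipidome

__all__ = [
    "LipidProfile",
    "MetricResult",
    "DEFAULT_GPL_CLASSES",
    "dbi",
    "avg_chain_length",
    "pe_ratio",
    "soamd",
    "class_abundance",
    "mean_profile",
]

#: Major glycerophospholipid classes entering DBI / chain-length averages.
DEFAULT_GPL_CLASSES = ("PC", "PI", "PE", "PS")


@dataclass(frozen=True)
class MetricResult:
    name: str
    value: float
    sample_id: str = ""
    class_set: tuple[str, ...] = ()


class LipidProfile:
    """species label -> mol% mapping restricted to a class set."""

    def __init__(self, mol_percent: dict[str, float],
                 class_set: tuple[str, ...] = DEFAULT_GPL_CLASSES):
        self.class_set = tuple(class_set)
        self.mol_percent: dict[str, float] = {}
        for label, pct in mol_percent.items():
            if pct < 0:
                raise ValueError(f"negative mol% for {label}")
            sp = parse_shorthand(label)
            if sp.lipid_class in self.class_set:
                self.mol_percent[label] = float(pct)

    @classmethod
    def from_lipidome(cls, lipidome: QuantifiedLipidome,
                      class_set: tuple[str, ...] = DEFAULT_GPL_CLASSES
                      ) -> "LipidProfile":
        return cls(lipidome.mol_percent, class_set)

    def items(self) -> list[tuple[LipidSpecies, float]]:
        return [(parse_shorthand(lbl), pct)
                for lbl, pct in self.mol_percent.items()]

    def total(self) -> float:
        return sum(self.mol_percent.values())


def _weighted_mean(profile: LipidProfile, attr: str, name: str,
                   sample_id: str) -> MetricResult:
    total = profile.total()
    if not profile.mol_percent:
        raise ValueError(f"empty profile for {name}")
    if total <= 0:
        raise ValueError(f"profile mol% sums to zero; {name} undefined")
    num = sum(getattr(sp, attr) * pct for sp, pct in profile.items())
    return MetricResult(name, num / total, sample_id, profile.class_set)


def dbi(profile: LipidProfile, sample_id: str = "") -> MetricResult:
    """Double-bond index: sum(db x [GPLi]) / sum([GPLi])."""
    return _weighted_mean(profile, "double_bonds", "dbi", sample_id)


def avg_chain_length(profile: LipidProfile, sample_id: str = ""
                     ) -> MetricResult:
    """Average chain length: sum(C x [GPLi]) / sum([GPLi])."""
    return _weighted_mean(profile, "carbons", "avg_chain_length", sample_id)


def class_abundance(lipidome: QuantifiedLipidome) -> dict[str, float]:
    """Per-class sums of species mol%; polar classes total 100."""
    out: dict[str, float] = {}
    for label, pct in lipidome.mol_percent.items():
        cls = parse_shorthand(label).lipid_class
        out[cls] = out.get(cls, 0.0) + pct
    return out


def pe_ratio(lipidome: QuantifiedLipidome) -> MetricResult:
    """PE/(PC+PI) class-abundance ratio."""
    by_class = class_abundance(lipidome)
    denom = by_class.get("PC", 0.0) + by_class.get("PI", 0.0)
    if denom <= 0:
        raise ValueError("PC + PI mol% is zero; PE ratio undefined")
    return MetricResult("pe_ratio", by_class.get("PE", 0.0) / denom,
                        lipidome.sample_id, ("PE", "PC", "PI"))


def _polar_molpct(lipidome: QuantifiedLipidome) -> dict[str, float]:
    return {lbl: pct for lbl, pct in lipidome.mol_percent.items()
            if parse_shorthand(lbl).is_polar}


def soamd(sample: QuantifiedLipidome,
          reference: QuantifiedLipidome) -> MetricResult:
    """Sum of absolute mol% differences vs a reference lipidome.

    Computed over the union of polar species, missing species at 0 mol%.
    Zero iff the profiles agree; at most 200 (fully disjoint lipidomes).
    """
    a = _polar_molpct(sample)
    b = _polar_molpct(reference)
    labels = set(a) | set(b)
    value = sum(abs(a.get(lbl, 0.0) - b.get(lbl, 0.0)) for lbl in labels)
    return MetricResult("soamd", value, sample.sample_id)


def mean_profile(lipidomes: list[QuantifiedLipidome],
                 sample_id: str = "mean") -> QuantifiedLipidome:
    """Mean mol% profile of a replicate group (e.g. the wild-type reference).

    Species missing from a replicate contribute 0 to its mean.
    """
    if not lipidomes:
        raise ValueError("no lipidomes to average")
    labels = sorted({lbl for lp in lipidomes for lbl in lp.mol_percent})
    n = len(lipidomes)
    mol = {lbl: sum(lp.mol_percent.get(lbl, 0.0) for lp in lipidomes) / n
           for lbl in labels}
    amounts = {lbl: sum(lp.amounts.get(lbl, 0.0) for lp in lipidomes) / n
               for lbl in labels}
    return QuantifiedLipidome(sample_id=sample_id, amounts=amounts,
                              mol_percent=mol)
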