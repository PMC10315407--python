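"""Lipid shorthand nomenclature: classes, fatty acids, molecular species.

Plasma lipidomics panels report molecular species in the shorthand dialect
``CLASS(C:D/...)``, where each ``C:D`` token is one acyl chain with ``C``
carbons and ``D`` double bonds.  Sixteen lipid classes are supported, each
carrying a fixed number of acyl chains per molecule (1 for cholesteryl
esters, lysophospholipids, monoacylglycerols and sphingolipids; 2 for
diacylglycerols and most phospholipids; 3 for triacylglycerols).  The class
taxonomy ships as a human-readable TSV (``data/lipid_classes.tsv``) so it
can be audited and extended.

Chain identity is (carbons, double bonds) only: the assay carries no
information on double-bond position or cis/trans geometry, so none is
modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "FattyAcid",
    "LipidClass",
    "LipidSpecies",
    "NomenclatureError",
    "UnsupportedClassError",
    "ArityMismatchError",
    "ChainParseError",
    "LIPID_CLASSES",
    "CLASS_ALIASES",
    "parse_species",
    "fa_multiplicity",
    "wcfa_label",
    "total_label",
    "parse_wcfa_label",
]


class NomenclatureError(ValueError):
    """Base error for species-name parsing failures."""


class UnsupportedClassError(NomenclatureError):
    """Unsupported lipid class code."""


class ArityMismatchError(NomenclatureError):
    """Chain count does not match the class's chains per molecule."""


class ChainParseError(NomenclatureError):
    """Malformed C:D acyl-chain token."""


@dataclass(frozen=True, order=True)
class FattyAcid:
    """An acyl chain identified by carbon count and number of double bonds."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ChainParseError(f"fatty acid needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ChainParseError(f"negative double-bond count: {self.double_bonds}")

    @classmethod
    def from_string(cls, token: str) -> "FattyAcid":
        m = re.fullmatch(r"\s*(\d+)\s*:\s*(\d+)\s*", token)
        if m is None:
            raise ChainParseError(f"malformed C:D token: {token!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    @property
    def shorthand(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:
        return self.shorthand


@dataclass(frozen=True)
class LipidClass:
    """One of the 16 supported lipid classes."""

    code: str
    name: str
    category: str  # neutral | sphingolipid | phospholipid
    chains_per_molecule: int


def _load_classes() -> dict[str, LipidClass]:
    classes: dict[str, LipidClass] = {}
    text = resources.files("lipidfa").joinpath("data/lipid_classes.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        cls = LipidClass(
            code=row["code"],
            name=row["name"],
            category=row["category"],
            chains_per_molecule=int(row["chains_per_molecule"]),
        )
        classes[cls.code] = cls
    return classes


LIPID_CLASSES: dict[str, LipidClass] = _load_classes()

# Vendor / prose variants mapped onto canonical codes.  "SPE" appears in
# some panels as a synonym for the 1-chain ethanolamine lysophospholipid.
CLASS_ALIASES: dict[str, str] = {
    "SPE": "LPE",
    "TAG": "TG",
    "DG": "DAG",
    "MG": "MAG",
    "CHOLESTEROL ESTER": "CE",
}


@dataclass(frozen=True)
class LipidSpecies:
    """A molecular species: class plus its ordered acyl chains."""

    lipid_class: LipidClass
    chains: tuple[FattyAcid, ...]
    raw_name: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if len(self.chains) != self.lipid_class.chains_per_molecule:
            raise ArityMismatchError(
                f"arity mismatch: {self.lipid_class.code} requires "
                f"{self.lipid_class.chains_per_molecule} chain(s), got {len(self.chains)}"
            )

    def format(self) -> str:
        """Canonical shorthand, e.g. ``DAG(16:0/18:1)``."""
        return f"{self.lipid_class.code}({'/'.join(str(c) for c in self.chains)})"

    def __str__(self) -> str:
        return self.format()


_SPECIES_RE = re.compile(r"\s*([A-Za-z ]+?)\s*[\(\[]\s*([^\)\]]*)\s*[\)\]]\s*$")


def parse_species(name: str) -> LipidSpecies:
    """Parse a shorthand species name like ``DAG(16:0/18:1)``.

    The class code is matched case-insensitively and through the alias
    table; chain order is preserved as written.  Both ``CLASS(...)`` and the
    prose form ``CLASS (...)`` are accepted.

    Raises
    ------
    UnsupportedClassError
        If the class code is not one of the 16 supported classes.
    ArityMismatchError
        If the number of chains does not match the class.
    ChainParseError
        If a chain token is not of the form ``C:D``.
    """
    m = _SPECIES_RE.match(name)
    if m is None:
        raise NomenclatureError(f"cannot parse species name: {name!r}")
    code_raw, body = m.group(1).strip().upper(), m.group(2)
    code = CLASS_ALIASES.get(code_raw, code_raw)
    if code not in LIPID_CLASSES:
        raise UnsupportedClassError(f"unsupported lipid class: {code_raw!r} in {name!r}")
    chains = tuple(FattyAcid.from_string(tok) for tok in body.split("/"))
    lipid_class = LIPID_CLASSES[code]
    if len(chains) != lipid_class.chains_per_molecule:
        raise ArityMismatchError(
            f"arity mismatch in {name!r}: {code} requires "
            f"{lipid_class.chains_per_molecule} chain(s), got {len(chains)}"
        )
    return LipidSpecies(lipid_class=lipid_class, chains=chains, raw_name=name)


def fa_multiplicity(species: LipidSpecies, fa: FattyAcid) -> int:
    """Number of chains of ``species`` equal to ``fa``.

    This is the weight with which the species contributes to the
    within-class fatty-acid concentration of ``fa``: a DAG with two 16:0
    chains contributes twice to DAG[16:0].
    """
    return sum(1 for c in species.chains if c == fa)


def wcfa_label(class_code: str, fa: FattyAcid) -> str:
    """Interchange column label for a within-class FA, e.g. ``DAG[16:0]``."""
    return f"{class_code}[{fa}]"


def total_label(class_code: str) -> str:
    """Interchange column label for a class total, e.g. ``DAG[total]``."""
    return f"{class_code}[total]"


_WCFA_RE = re.compile(r"\s*([A-Za-z]+)\s*\[\s*(\d+\s*:\s*\d+)\s*\]\s*$")


def parse_wcfa_label(label: str) -> tuple[LipidClass, FattyAcid]:
    """Parse a ``CLASS[C:D]`` within-class FA label back into its parts."""
    m = _WCFA_RE.match(label)
    if m is None:
        raise NomenclatureError(f"cannot parse within-class FA label: {label!r}")
    code = CLASS_ALIASES.get(m.group(1).upper(), m.group(1).upper())
    if code not in LIPID_CLASSES:
        raise UnsupportedClassError(f"unsupported lipid class: {m.group(1)!r}")
    return LIPID_CLASSES[code], FattyAcid.from_string(m.group(2))
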