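"""Targeted metabolite panel definitions.

The default panel emulates a Biocrates AbsoluteIDQ p180-style kit: 188
metabolites of which 146 hydrophobic species (acylcarnitines, lyso-, diacyl-
and acyl-alkyl-phosphatidylcholines, sphingomyelins) are acquired by
flow-injection analysis (FIA) and 42 polar species (amino acids, biogenic
amines, hexose) by liquid chromatography (LC).  Enzyme-activity proxy ratios
(e.g. Cit/Arg for urea-cycle flux) are defined on top of the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "CHEM_CLASSES",
    "FIA_CLASSES",
    "LC_CLASSES",
    "MetaboliteDef",
    "RatioDef",
    "MetabolitePanel",
    "default_panel",
    "load_panel",
]

CHEM_CLASSES = frozenset({
    "acylcarnitine", "amino_acid", "biogenic_amine", "hexose",
    "lysoPC", "PC_aa", "PC_ae", "SM", "SM_OH",
})
FIA_CLASSES = frozenset({"acylcarnitine", "lysoPC", "PC_aa", "PC_ae", "SM", "SM_OH"})
LC_CLASSES = frozenset({"amino_acid", "biogenic_amine", "hexose"})

#: ratios shipped with the default panel (numerator, denominator)
DEFAULT_RATIOS = [
    ("Cit/Arg", "Cit", "Arg"),
    ("Kynurenine/Trp", "Kynurenine", "Trp"),
    ("Putrescine/Orn", "Putrescine", "Orn"),
]


@dataclass(frozen=True)
class MetaboliteDef:
    """A single quantified metabolite: name, chemical class, acquisition method."""

    name: str
    chem_class: str
    method: str

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValueError(f"unknown chemical class {self.chem_class!r}")
        expected = "FIA" if self.chem_class in FIA_CLASSES else "LC"
        if self.method != expected:
            raise ValueError(
                f"{self.name}: class {self.chem_class} must use {expected}, "
                f"got {self.method}"
            )


@dataclass(frozen=True)
class RatioDef:
    """Concentration ratio of two panel metabolites (enzyme-activity proxy)."""

    name: str
    numerator: str
    denominator: str


@dataclass
class MetabolitePanel:
    """Ordered metabolite registry plus derived ratio definitions."""

    metabolites: list[MetaboliteDef]
    ratios: list[RatioDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.metabolites]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate metabolite names: {dupes}")
        name_set = set(names)
        for r in self.ratios:
            if r.numerator not in name_set:
                raise ValueError(f"ratio {r.name}: numerator {r.numerator!r} not in panel")
            if r.denominator not in name_set:
                raise ValueError(f"ratio {r.name}: denominator {r.denominator!r} not in panel")
            if r.name in name_set:
                raise ValueError(f"ratio name {r.name!r} collides with a metabolite")
        ratio_names = [r.name for r in self.ratios]
        if len(set(ratio_names)) != len(ratio_names):
            raise ValueError("duplicate ratio names")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.metabolites]

    @property
    def ratio_names(self) -> list[str]:
        return [r.name for r in self.ratios]

    @property
    def feature_names(self) -> list[str]:
        """Metabolite names followed by ratio names (model feature order)."""
        return self.names + self.ratio_names

    def __len__(self) -> int:
        return len(self.metabolites)

    def count_by_method(self, method: str) -> int:
        return sum(1 for m in self.metabolites if m.method == method)

    def count_by_class(self, chem_class: str) -> int:
        return sum(1 for m in self.metabolites if m.chem_class == chem_class)

    def classes_of(self) -> dict[str, str]:
        """Map metabolite name -> chemical class."""
        return {m.name: m.chem_class for m in self.metabolites}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.name, m.chem_class, m.method) for m in self.metabolites],
            columns=["name", "chem_class", "method"],
        )


def load_panel(path, ratios: list[tuple[str, str, str]] | None = None) -> MetabolitePanel:
    """Read a panel CSV (columns name, chem_class, method)."""
    df = pd.read_csv(path)
    mets = [
        MetaboliteDef(str(r.name), str(r.chem_class), str(r.method))
        for r in df.itertuples(index=False)
    ]
    ratio_defs = [RatioDef(n, num, den) for n, num, den in (ratios or [])]
    return MetabolitePanel(mets, ratio_defs)


def default_panel() -> MetabolitePanel:
    """The built-in 188-metabolite panel (146 FIA, 42 LC) with default ratios."""
    ref = resources.files("metabosig.data").joinpath("panel_p180.csv")
    with resources.as_file(ref) as path:
        return load_panel(path, ratios=DEFAULT_RATIOS)
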