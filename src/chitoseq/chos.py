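"""Domain types and exact mass arithmetic for chitooligosaccharides (CHOS).

A CHOS is a beta-1,4-linked oligomer of N-acetylglucosamine (GlcNAc, written
``A``) and glucosamine (GlcN, written ``D``) units.  Patterns are written from
the non-reducing end to the reducing end, left to right; the reducing end may
carry a 2-aminoacridone (AMAC) fluorophore attached by reductive amination.

Mass conventions
----------------
Residue masses are glycosidic *residue* masses (monomer minus water).  An
unlabeled oligomer's neutral mass is the sum of residue masses plus one water.
Reductive amination with AMAC condenses away the reducing-end water and adds
two hydrogens on reduction, so an AMAC-labeled oligomer weighs

    sum(residues) + AMAC + H2

and the label adds a constant AMAC + H2 - H2O = 194.084 Da (monoisotopic)
relative to the free sugar, independent of the pattern.
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import dataclass, field


class Label(str, enum.Enum):
    """Reducing-end label state."""

    NONE = "none"
    AMAC = "AMAC"


MAX_DP = 12

ALPHABET = frozenset("AD")


class AlphabetError(ValueError):
    """Pattern contains a symbol outside {A, D}."""


@dataclass(frozen=True)
class ChosPattern:
    """An ordered A/D pattern, non-reducing end -> reducing end.

    Parameters
    ----------
    residues:
        String over {A, D}; position 1 is the non-reducing terminus and the
        last position is the (optionally labeled) reducing terminus.
    label:
        Reducing-end label state (:class:`Label`).
    """

    residues: str
    label: Label = Label.NONE

    def __post_init__(self) -> None:
        if not 1 <= len(self.residues) <= MAX_DP:
            raise ValueError(
                f"DP must be in [1, {MAX_DP}], got {len(self.residues)}"
            )
        bad = set(self.residues) - ALPHABET
        if bad:
            raise AlphabetError(f"unknown residue symbol(s): {sorted(bad)}")
        if not isinstance(self.label, Label):
            object.__setattr__(self, "label", Label(self.label))

    @property
    def dp(self) -> int:
        """Degree of polymerization."""
        return len(self.residues)

    @property
    def n_acetylated(self) -> int:
        return self.residues.count("A")

    @property
    def n_deacetylated(self) -> int:
        return self.residues.count("D")

    def __str__(self) -> str:
        suffix = "+AMAC" if self.label is Label.AMAC else ""
        return self.residues + suffix

    @classmethod
    def parse(cls, text: str) -> "ChosPattern":
        """Parse the serialized form, e.g. ``"AADAA+AMAC"``."""
        if text.endswith("+AMAC"):
            return cls(text[: -len("+AMAC")], Label.AMAC)
        return cls(text, Label.NONE)


@dataclass(frozen=True)
class Composition:
    """Counts of GlcNAc (nA) and GlcN (nD) units; DP = nA + nD."""

    nA: int
    nD: int

    def __post_init__(self) -> None:
        if self.nA < 0 or self.nD < 0 or self.nA + self.nD < 1:
            raise ValueError(f"invalid composition ({self.nA}, {self.nD})")

    @property
    def dp(self) -> int:
        return self.nA + self.nD

    @property
    def fa(self) -> float:
        """Fraction of acetylation F_A = nA / DP."""
        return self.nA / self.dp

    def label_str(self) -> str:
        """Product shorthand, e.g. A4D1."""
        return f"A{self.nA}D{self.nD}"


@dataclass(frozen=True)
class MassTable:
    """Residue and constant masses in Da under one convention.

    The monoisotopic defaults are computed from the elemental compositions
    C8H13NO5 (GlcNAc residue), C6H11NO4 (GlcN residue), H2O, H2, H+, C2H2O
    (acetyl) and C13H10N2O (AMAC).
    """

    convention: str = "monoisotopic"
    residue_a: float = 203.0794
    residue_d: float = 161.0688
    water: float = 18.0106
    h2: float = 2.0157
    proton: float = 1.00728
    acetyl: float = 42.0106
    amac: float = 210.0793

    def __post_init__(self) -> None:
        for name in ("residue_a", "residue_d", "water", "h2", "proton",
                     "acetyl", "amac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs((self.residue_a - self.residue_d) - self.acetyl) > 1e-3:
            raise ValueError("mass(A) - mass(D) must equal the acetyl delta")

    def residue(self, symbol: str) -> float:
        if symbol == "A":
            return self.residue_a
        if symbol == "D":
            return self.residue_d
        raise AlphabetError(f"unknown residue symbol: {symbol!r}")

    @property
    def amac_label_delta(self) -> float:
        """Labeled minus unlabeled neutral mass: AMAC + H2 - H2O."""
        return self.amac + self.h2 - self.water

    def to_json(self) -> str:
        return json.dumps(
            {
                "convention": self.convention,
                "residue_masses": {"A": self.residue_a, "D": self.residue_d},
                "water": self.water,
                "H2": self.h2,
                "proton": self.proton,
                "acetyl": self.acetyl,
                "AMAC": self.amac,
            },
            indent=2,
        )


MONOISOTOPIC = MassTable()

#: Average-mass variant (standard atomic weights), kept for completeness;
#: unit-resolution ion-trap data does not distinguish the two for DP <= 12.
AVERAGE = MassTable(
    convention="average",
    residue_a=203.1925,
    residue_d=161.1558,
    water=18.0153,
    h2=2.0159,
    proton=1.00739,
    acetyl=42.0367,
    amac=210.2319,
)


def neutral_mass(pattern: ChosPattern, table: MassTable = MONOISOTOPIC) -> float:
    """Neutral (uncharged) mass of a possibly AMAC-labeled CHOS in Da."""
    total = sum(table.residue(r) for r in pattern.residues)
    if pattern.label is Label.AMAC:
        return total + table.amac + table.h2
    return total + table.water


def ion_mz(
    pattern: ChosPattern,
    table: MassTable = MONOISOTOPIC,
    charge: int = 1,
) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass(pattern, table) + charge * table.proton) / charge


def composition_mass(
    comp: Composition, label: Label, table: MassTable = MONOISOTOPIC
) -> float:
    """Neutral mass from composition alone (mass is pattern-independent)."""
    total = comp.nA * table.residue_a + comp.nD * table.residue_d
    if label is Label.AMAC:
        return total + table.amac + table.h2
    return total + table.water


def composition_mz(
    comp: Composition,
    label: Label,
    table: MassTable = MONOISOTOPIC,
    charge: int = 1,
) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (composition_mass(comp, label, table) + charge * table.proton) / charge


def composition_from_mz(
    mz_obs: float,
    dp_range: tuple[int, int],
    label: Label = Label.AMAC,
    table: MassTable = MONOISOTOPIC,
    tol: float = 0.5,
) -> list[tuple[int, Composition]]:
    """All (DP, composition) whose singly protonated ion lies within ``tol``.

    Results are sorted by absolute m/z error, ascending.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lo, hi = dp_range
    if lo > hi or lo < 1 or hi > MAX_DP:
        raise ValueError(f"dp_range must be within [1, {MAX_DP}], got {dp_range}")
    hits: list[tuple[float, int, Composition]] = []
    for dp in range(lo, hi + 1):
        for n_d in range(dp + 1):
            comp = Composition(nA=dp - n_d, nD=n_d)
            err = abs(composition_mz(comp, label, table) - mz_obs)
            if err <= tol:
                hits.append((err, dp, comp))
    hits.sort(key=lambda t: t[0])
    return [(dp, comp) for _, dp, comp in hits]


def pattern_stats(pattern: ChosPattern) -> tuple[Composition, float]:
    """Composition counts and fraction of acetylation F_A = nA / DP."""
    comp = Composition(nA=pattern.n_acetylated, nD=pattern.n_deacetylated)
    return comp, comp.fa


def enumerate_patterns(comp: Composition, label: Label = Label.NONE):
    """All C(DP, nD) positional arrangements of one composition,
    lexicographic order."""
    for d_positions in itertools.combinations(range(comp.dp), comp.nD):
        residues = ["A"] * comp.dp
        for i in d_positions:
            residues[i] = "D"
        yield ChosPattern("".join(residues), label)
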