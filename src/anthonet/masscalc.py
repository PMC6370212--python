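"""Exact monoisotopic mass arithmetic for decorated anthocyanins.

Anthocyanins are flavylium cations (permanently charged aglycones such as
pelargonidin) decorated with glycosyl and acyl residues.  Every m/z seen in
positive-mode LC-MS of these pigments is a sum of residue masses, so the whole
annotation problem reduces to exact integer-weighted sums of monoisotopic
atomic masses.  This module provides the elemental-formula container, the
building-block library (aglycones + sugar/acyl residues) and the four mass
operations everything downstream relies on.

Residue formulas follow condensation chemistry: a glycosyl or acyl block
contributes its free molecule minus one water, while an aglycone contributes
its full flavylium-cation formula.  Theoretical cation m/z is the neutral-atom
formula mass minus one electron mass ([M]+ convention; the intact cation, not
a protonated adduct).
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "BuildingBlock",
    "BuildingBlockLibrary",
    "Composition",
    "formula_mass",
    "cation_mass",
    "compose",
    "loss_mass",
    "default_library",
]

# IUPAC/CODATA monoisotopic atomic masses in Da (most abundant isotope).
# 12C is exact by definition of the unified atomic mass unit.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.99491461956,
    "N": 14.00307400443,
    "S": 31.97207117354,
}

#: CODATA electron mass in Da; subtracted once for a singly charged cation.
ELECTRON_MASS: float = 0.00054857990907

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(KeyError):
    """Raised when a formula contains an element without a tabulated mass."""


class ElementalFormula(Mapping[str, int]):
    """Immutable element -> count map with element-wise arithmetic.

    Parameters
    ----------
    counts
        Mapping from element symbol (e.g. ``"C"``) to a non-negative integer
        count.  At least one count must be positive.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int]) -> None:
        cleaned: dict[str, int] = {}
        for element, count in counts.items():
            if not isinstance(count, (int,)) or isinstance(count, bool):
                raise TypeError(f"count for {element!r} must be an integer, got {count!r}")
            if count < 0:
                raise ValueError(f"negative count for element {element!r}: {count}")
            if count > 0:
                cleaned[element] = int(count)
        if not cleaned:
            raise ValueError("empty elemental formula (no atoms)")
        self._counts: dict[str, int] = cleaned

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._counts))

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element: object) -> bool:
        return element in self._counts

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = Counter(self._counts)
        merged.update(other._counts)
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        result = Counter(self._counts)
        result.subtract(other._counts)
        negatives = [el for el, n in result.items() if n < 0]
        if negatives:
            raise ValueError(
                f"subtraction would produce negative counts for {sorted(negatives)}"
            )
        return ElementalFormula(result)

    def __mul__(self, factor: int) -> "ElementalFormula":
        if not isinstance(factor, int) or factor < 1:
            raise ValueError("formula can only be multiplied by a positive integer")
        return ElementalFormula({el: n * factor for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(tuple(sorted(self._counts.items())))

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"

    # -- conversions -------------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-notation string such as ``"C27H31O15"``."""
        counts: Counter[str] = Counter()
        pos = 0
        for match in _FORMULA_RE.finditer(text):
            if match.start() != pos:
                raise ValueError(f"malformed formula {text!r} at position {pos}")
            pos = match.end()
            if not match.group(0):
                break
            element, digits = match.groups()
            counts[element] += int(digits) if digits else 1
        if pos != len(text):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        return cls(counts)

    def hill(self) -> str:
        """Hill-notation string: C first, H second, then alphabetical."""
        order = sorted(
            self._counts, key=lambda el: (el != "C", el != "H", el)
        )
        return "".join(
            f"{el}{self._counts[el]}" if self._counts[el] != 1 else el for el in order
        )

    def atom_count(self) -> int:
        return sum(self._counts.values())


def formula_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass of a neutral-atom formula in Da."""
    total = 0.0
    for element, count in formula.items():
        try:
            total += count * ATOMIC_MASS[element]
        except KeyError:
            raise UnknownElementError(
                f"no monoisotopic mass tabulated for element {element!r}"
            ) from None
    return total


def cation_mass(formula: ElementalFormula) -> float:
    """Theoretical [M]+ m/z of a singly charged cation with this atom content.

    The flavylium core is permanently charged, so the observed ion is the
    intact cation: formula mass minus one electron mass.
    """
    return formula_mass(formula) - ELECTRON_MASS


@dataclass(frozen=True)
class BuildingBlock:
    """One unit of the decoration chemistry.

    ``residue_formula`` is what the block contributes after condensation:
    the free molecule minus one water for glycosyl/acyl blocks, the full
    flavylium-cation formula for aglycones.
    """

    id: str
    block_class: str  # "aglycone" | "glycosyl" | "acyl"
    residue_formula: ElementalFormula

    _CLASSES = ("aglycone", "glycosyl", "acyl")

    def __post_init__(self) -> None:
        if self.block_class not in self._CLASSES:
            raise ValueError(
                f"block_class must be one of {self._CLASSES}, got {self.block_class!r}"
            )

    @property
    def residue_mass(self) -> float:
        return formula_mass(self.residue_formula)


class BuildingBlockLibrary:
    """Collection of uniquely named building blocks.

    Invariants: ids are unique, at least one aglycone is present, and no two
    blocks of the same class share a residue mass within 1 mDa (such a pair
    would be indistinguishable to mass decomposition).
    """

    def __init__(self, blocks: Iterable[BuildingBlock]) -> None:
        self._blocks: dict[str, BuildingBlock] = {}
        for block in blocks:
            if block.id in self._blocks:
                raise ValueError(f"duplicate building-block id {block.id!r}")
            self._blocks[block.id] = block
        if not self.aglycones():
            raise ValueError("library must contain at least one aglycone")
        items = sorted(self._blocks.values(), key=lambda b: b.residue_mass)
        for a, b in zip(items, items[1:]):
            if (
                a.block_class == b.block_class
                and abs(a.residue_mass - b.residue_mass) < 1e-3
            ):
                raise ValueError(
                    f"blocks {a.id!r} and {b.id!r} have indistinguishable residue "
                    f"masses ({a.residue_mass:.6f} vs {b.residue_mass:.6f} Da)"
                )

    def __getitem__(self, block_id: str) -> BuildingBlock:
        try:
            return self._blocks[block_id]
        except KeyError:
            raise KeyError(f"no building block named {block_id!r} in library") from None

    def __contains__(self, block_id: str) -> bool:
        return block_id in self._blocks

    def __iter__(self) -> Iterator[BuildingBlock]:
        return iter(self._blocks.values())

    def __len__(self) -> int:
        return len(self._blocks)

    def aglycones(self) -> list[BuildingBlock]:
        return [b for b in self._blocks.values() if b.block_class == "aglycone"]

    def glycosyls(self) -> list[BuildingBlock]:
        return [b for b in self._blocks.values() if b.block_class == "glycosyl"]

    def acyls(self) -> list[BuildingBlock]:
        return [b for b in self._blocks.values() if b.block_class == "acyl"]

    def decoration_blocks(self) -> list[BuildingBlock]:
        return self.glycosyls() + self.acyls()

    def fingerprint(self) -> tuple:
        """Hashable identity of the library content (used for caching)."""
        return tuple(
            (b.id, b.block_class, b.residue_formula.hill())
            for b in sorted(self._blocks.values(), key=lambda b: b.id)
        )

    # -- JSON serialization (masses are always recomputed, never trusted) --
    def to_json(self) -> str:
        payload = {
            "format": "anthonet-building-blocks",
            "version": 1,
            "blocks": [
                {
                    "id": b.id,
                    "class": b.block_class,
                    "residue_formula": b.residue_formula.hill(),
                }
                for b in self._blocks.values()
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BuildingBlockLibrary":
        payload = json.loads(text)
        if payload.get("format") != "anthonet-building-blocks":
            raise ValueError("not a building-block library file")
        blocks = [
            BuildingBlock(
                id=entry["id"],
                block_class=entry["class"],
                residue_formula=ElementalFormula.parse(entry["residue_formula"]),
            )
            for entry in payload["blocks"]
        ]
        return cls(blocks)


def default_library() -> BuildingBlockLibrary:
    """The standard anthocyanin building blocks.

    Aglycones are the three base anthocyanidins (differing in B-ring
    hydroxylation); glycosyl residues cover hexoses (glucose/galactose,
    indistinguishable by mass) and deoxyhexoses (rhamnose); acyl residues are
    the common aliphatic (malonyl) and aromatic (coumaroyl, caffeoyl,
    feruloyl) decorations.
    """
    F = ElementalFormula.parse
    return BuildingBlockLibrary(
        [
            BuildingBlock("pelargonidin", "aglycone", F("C15H11O5")),
            BuildingBlock("cyanidin", "aglycone", F("C15H11O6")),
            BuildingBlock("delphinidin", "aglycone", F("C15H11O7")),
            BuildingBlock("hexose", "glycosyl", F("C6H10O5")),
            BuildingBlock("deoxyhexose", "glycosyl", F("C6H10O4")),
            BuildingBlock("malonyl", "acyl", F("C3H2O3")),
            BuildingBlock("coumaroyl", "acyl", F("C9H6O2")),
            BuildingBlock("caffeoyl", "acyl", F("C9H6O3")),
            BuildingBlock("feruloyl", "acyl", F("C10H8O3")),
        ]
    )


@dataclass(frozen=True)
class Composition:
    """A candidate structure: an aglycone plus a multiset of decorations.

    Decorations are stored as a sorted tuple of block ids (multiset
    semantics); positional and stereochemical isomers are deliberately
    collapsed — mass decomposition cannot resolve them.
    """

    aglycone_id: str
    decorations: tuple[str, ...]
    total_formula: ElementalFormula
    cation_mz: float

    @property
    def n_blocks(self) -> int:
        return 1 + len(self.decorations)

    def decoration_counts(self) -> Counter:
        return Counter(self.decorations)

    def sort_key(self) -> tuple:
        return (self.aglycone_id, self.decorations)


def compose(
    aglycone_id: str,
    decorations: Iterable[str],
    library: BuildingBlockLibrary,
) -> Composition:
    """Build a :class:`Composition` from block ids.

    Decoration order is irrelevant; the multiset is canonicalized by sorting.
    """
    aglycone = library[aglycone_id]
    if aglycone.block_class != "aglycone":
        raise ValueError(f"{aglycone_id!r} is not an aglycone block")
    deco = tuple(sorted(decorations))
    total = aglycone.residue_formula
    for block_id in deco:
        block = library[block_id]
        if block.block_class == "aglycone":
            raise ValueError(f"decoration {block_id!r} is an aglycone, not a residue")
        total = total + block.residue_formula
    return Composition(
        aglycone_id=aglycone_id,
        decorations=deco,
        total_formula=total,
        cation_mz=cation_mass(total),
    )


def loss_mass(block_ids: Iterable[str], library: BuildingBlockLibrary) -> float:
    """Theoretical neutral-loss mass of removing the given residues.

    The empty multiset is a valid identity loss of 0 Da.
    """
    total = 0.0
    for block_id in block_ids:
        block = library[block_id]
        if block.block_class == "aglycone":
            raise ValueError(f"{block_id!r} is an aglycone; losses are residues only")
        total += block.residue_mass
    return total
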