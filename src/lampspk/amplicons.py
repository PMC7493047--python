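"""The structural grammar of LAMP amplicons.

Every product of a four-primer LAMP reaction falls into one of four
structural categories:

* ``SS`` — predominantly single-stranded, >= 2 loops, only the short F1/B1
  stem duplexes; the two-loop special case is the dumbbell that seeds the
  exponential phase.
* ``SL`` — one single-stranded loop, otherwise fully double-stranded.
* ``PDS`` — a continuous double-stranded stretch plus one or more
  single-stranded loops.
* ``T`` — fully double-stranded; inert.

A species is identified by its structure and length alone.  Structures are
encoded as a left-to-right run of dumbbell-sized units, each either
single-stranded (``s``) or duplex (``d``), together with a loop count and a
strand sign — the :class:`StructureCode`.  Two amplicons are the same
species iff their codes are equal.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from typing import Optional

from .geometry import AssayGeometry


class Category(str, enum.Enum):
    SS = "SS"
    SL = "SL"
    PDS = "PDS"
    T = "T"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Strand(str, enum.Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"

    @property
    def sign(self) -> str:
        return "+" if self is Strand.SENSE else "-"

    @property
    def opposite(self) -> "Strand":
        return Strand.ANTISENSE if self is Strand.SENSE else Strand.SENSE


class StructureCodeError(ValueError):
    """Raised for malformed structure codes."""


@dataclass(frozen=True, order=True)
class StructureCode:
    """Compact symbolic identity of an amplicon species.

    ``units`` lists the dumbbell-sized units 5'->3' of the displayed strand:
    ``s`` for a single-stranded unit, ``d`` for a duplex unit.  ``loops``
    counts single-stranded loops.  String form: ``"dss:2:+"``.
    """

    units: str
    loops: int
    strand: Strand

    def __post_init__(self) -> None:
        if not self.units or set(self.units) - {"s", "d"}:
            raise StructureCodeError(f"bad unit string {self.units!r}")
        if self.loops < 0:
            raise StructureCodeError("loop count must be >= 0")
        if self.loops == 0 and "s" in self.units:
            raise StructureCodeError("a loop-free amplicon cannot contain ss units")
        if "s" not in self.units and self.loops > 1:
            raise StructureCodeError("an all-duplex amplicon carries at most one loop")
        if "d" not in self.units and self.loops != self.size + 1:
            raise StructureCodeError(
                "an all-single-stranded amplicon folds into size+1 loops"
            )

    @property
    def size(self) -> int:
        """Number of dumbbell units spanned."""
        return len(self.units)

    def __str__(self) -> str:
        return f"{self.units}:{self.loops}:{self.strand.sign}"

    @classmethod
    def parse(cls, text: str) -> "StructureCode":
        try:
            units, loops, sign = text.strip().split(":")
            strand = {"+": Strand.SENSE, "-": Strand.ANTISENSE}[sign]
            return cls(units, int(loops), strand)
        except (ValueError, KeyError) as exc:
            raise StructureCodeError(f"cannot parse structure code {text!r}") from exc

    def complement(self) -> "StructureCode":
        """The complementary-strand species: same structure, opposite strand."""
        return replace(self, strand=self.strand.opposite)


def classify(code: StructureCode) -> Category:
    """Map a structure code onto its category (total and single-valued)."""
    if code.loops == 0:
        return Category.T
    if "s" not in code.units:
        return Category.SL
    if "d" not in code.units:
        return Category.SS
    return Category.PDS


# -- concrete species constructors ------------------------------------------------


def ss_code(size: int, strand: Strand) -> StructureCode:
    """SS concatemer of ``size`` units (size 1 = dumbbell, loops = size + 1)."""
    if size < 1:
        raise StructureCodeError("SS size must be >= 1")
    return StructureCode("s" * size, size + 1, strand)


def sl_code(size: int, strand: Strand) -> StructureCode:
    """Fully zipped hairpin of ``size`` units with its one terminal loop."""
    if size < 1:
        raise StructureCodeError("SL size must be >= 1")
    return StructureCode("d" * size, 1, strand)


def t_code(size: int, strand: Strand) -> StructureCode:
    if size < 1:
        raise StructureCodeError("T size must be >= 1")
    return StructureCode("d" * size, 0, strand)


def pds_highway_code(size: int, strand: Strand) -> StructureCode:
    """PDS born from an SL: primer-made duplex unit at the 5' side, the
    opened hairpin arm single-stranded behind it (loops = size - 1)."""
    if size < 2:
        raise StructureCodeError("a PDS spans at least 2 units")
    return StructureCode("d" + "s" * (size - 1), size - 1, strand)


def pds_linker_code(size: int, loops: int, strand: Strand) -> StructureCode:
    """PDS born from internal-loop priming (on an SS or a PDS): the extension
    runs toward the 5' end, leaving ``loops`` single-stranded units at the
    3' side."""
    if size < 2 or not (1 <= loops <= size - 1):
        raise StructureCodeError(f"bad linker PDS ({size=}, {loops=})")
    return StructureCode("s" * loops + "d" * (size - loops), loops, strand)


def is_linker_pds(code: StructureCode) -> bool:
    """True for PDS species created by internal-loop priming (pathway III).

    Structurally: the single-stranded units sit at the 3'-terminal side
    (code starts with ``s``).  These species only ever self-extend and are
    routed through the PDS linker.
    """
    return classify(code) is Category.PDS and code.units.startswith("s")


# -- amplicon instances -----------------------------------------------------------

_ids = itertools.count(1)


@dataclass
class Amplicon:
    """One structural species instance produced during a simulation."""

    code: StructureCode
    length_nt: int
    birth_time: float = 0.0
    copies: float = 1.0
    lineage: str = "root"
    parent_id: Optional[int] = None
    id: int = field(default_factory=lambda: next(_ids))

    def __post_init__(self) -> None:
        if self.birth_time < 0:
            raise ValueError("birth_time must be >= 0")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        if self.length_nt <= 0:
            raise ValueError("length must be positive")

    @property
    def category(self) -> Category:
        return classify(self.code)

    @property
    def loops(self) -> int:
        return self.code.loops

    @property
    def strand(self) -> Strand:
        return self.code.strand

    @property
    def species_id(self) -> str:
        return str(self.code)

    def complement(self) -> "Amplicon":
        """Same category, loop count and length on the opposite strand."""
        return replace(self, code=self.code.complement(), id=next(_ids))


def length_of(code: StructureCode, geometry: AssayGeometry) -> int:
    """Length in nucleotides: ``size`` dumbbell units on the geometry's ruler."""
    return code.size * geometry.unit_length


def make_dumbbell(geometry: AssayGeometry, strand: Strand = Strand.SENSE) -> Amplicon:
    """The two-loop SS seed species (loops = 2, birth at t = 0)."""
    code = ss_code(1, strand)
    return Amplicon(
        code=code,
        length_nt=length_of(code, geometry),
        birth_time=0.0,
        copies=1.0,
        lineage="root",
        parent_id=None,
    )
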