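"""Brute-force generation-matrix simulator.

Starting from dumbbell seeds, every amplicon's fates are expanded generation
by generation: row 1 holds the roots, row *n+1* holds every product of a row
*n* entry whose formation completes within the reaction time.  Each entry is
one species produced by one parent; within a parent's product group the
displaced SS (if any) is listed first, then the primary products in fate
order.  Entries carry the Fig-style lineage suffix (a/b/c by parent
category; displaced SS amplicons are suffix-free).

Internally each entry keeps *fate-resolved arrivals* — a map from arrival
time (in polymerized nucleotides along the lineage path) to copies — so the
copy bookkeeping is exactly the arithmetic the compressed engine performs,
and the end-of-run census of the two engines can be compared species by
species.

This engine is exponential in depth; it exists as the ground-truth oracle
for short horizons and refuses to grow past a configurable species cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from io import StringIO
from typing import Iterable, Optional, Union

import pandas as pd

from .amplicons import Category, Strand, StructureCode, classify, length_of, ss_code
from .geometry import AssayGeometry
from .rules import (
    KineticParams,
    displaced_code,
    enumerate_fates,
    lineage_suffix,
    nt_added_for,
    product_code,
)

Number = Union[float, Fraction]


class ResourceLimitError(RuntimeError):
    """The generation matrix outgrew the configured species cap."""


@dataclass
class MatrixEntry:
    """One cell of the generation matrix: a species produced by one parent."""

    id: int
    row: int  # 1-based generation index
    parent_id: Optional[int]
    code: StructureCode
    name: str
    arrivals: dict[int, Number] = field(default_factory=dict)

    @property
    def category(self) -> Category:
        return classify(self.code)

    @property
    def birth_nt(self) -> int:
        """Earliest arrival, in polymerized nucleotides since reaction start."""
        return min(self.arrivals)

    @property
    def copies(self) -> Number:
        return sum(self.arrivals.values())


@dataclass
class GenerationMatrix:
    rows: list[list[MatrixEntry]]
    horizon_nt: float
    t_R: float
    params: KineticParams
    geometry: AssayGeometry
    census: dict[StructureCode, Number]
    """Copies of each species *present* at t_R: terminated amplicons plus
    every reactant fraction whose next event would complete after t_R."""

    @property
    def total_entries(self) -> int:
        return sum(len(row) for row in self.rows)

    def all_entries(self) -> Iterable[MatrixEntry]:
        for row in self.rows:
            yield from row


def build_generation_matrix(
    n0: float,
    t_R: float,
    params: KineticParams,
    geometry: AssayGeometry,
    *,
    seeds: Optional[list[tuple[StructureCode, Number]]] = None,
    max_entries: int = 10**6,
    exact: bool = False,
) -> GenerationMatrix:
    """Expand all products born within ``t_R`` seconds from ``n0`` dumbbells.

    ``seeds`` overrides the default single sense-strand dumbbell root (each
    seed becomes one row-1 entry).  With ``exact=True`` copies are tracked
    as exact rationals, which is what the engine-equivalence tests use.
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if t_R <= 0:
        raise ValueError("t_R must be > 0")
    if seeds is None:
        seeds = [(ss_code(1, Strand.SENSE), Fraction(n0) if exact else float(n0))]

    horizon_nt = params.v * t_R
    census: dict[StructureCode, Number] = {}
    next_id = 1
    roots = []
    for code, copies in seeds:
        roots.append(MatrixEntry(next_id, 1, None, code, _entry_name(code, None), {0: copies}))
        next_id += 1
    rows = [roots]
    total = len(roots)

    current = roots
    while current:
        # children keyed by (parent entry, species); insertion order fixes layout
        children: dict[tuple[int, StructureCode], MatrixEntry] = {}
        for entry in current:
            cat = entry.category
            if cat is Category.T:
                for t, c in entry.arrivals.items():
                    census[entry.code] = census.get(entry.code, 0) + c
                continue
            probs = params.branching.fate_probabilities(entry.code)
            displaced = displaced_code(entry.code) if cat is Category.PDS else None
            # displaced SS is listed first within the parent's group
            if displaced is not None:
                _child(children, entry, displaced, "")
            for pathway, p in probs.items():
                pcode = product_code(entry.code, pathway)
                nt = nt_added_for(entry.code, pathway, geometry, params)
                suffix = lineage_suffix(classify(pcode), cat)
                for t, c in entry.arrivals.items():
                    tc = t + nt
                    amount = c * p
                    if tc <= horizon_nt:
                        child = _child(children, entry, pcode, suffix)
                        child.arrivals[tc] = child.arrivals.get(tc, 0) + amount
                        if displaced is not None:
                            dchild = _child(children, entry, displaced, "")
                            dchild.arrivals[tc] = dchild.arrivals.get(tc, 0) + amount
                    else:
                        # the reactant fraction is still mid-event at t_R
                        census[entry.code] = census.get(entry.code, 0) + amount
        next_row = [e for e in children.values() if e.arrivals]
        for i, entry in enumerate(next_row):
            entry.id = next_id
            next_id += 1
        total += len(next_row)
        if total > max_entries:
            raise ResourceLimitError(
                f"generation matrix exceeded {max_entries} entries at row "
                f"{len(rows) + 1}; shorten t_R or raise max_entries"
            )
        if next_row:
            rows.append(next_row)
        current = next_row

    return GenerationMatrix(rows, horizon_nt, t_R, params, geometry, census)


def _child(
    children: dict,
    parent: MatrixEntry,
    code: StructureCode,
    suffix: str,
) -> MatrixEntry:
    key = (parent.id, code)
    if key not in children:
        children[key] = MatrixEntry(
            id=-1,
            row=parent.row + 1,
            parent_id=parent.id,
            code=code,
            name=_entry_name(code, suffix),
        )
    return children[key]


def _entry_name(code: StructureCode, suffix: Optional[str]) -> str:
    return classify(code).value + (suffix or "")


# -- census over the matrix -------------------------------------------------------


def census_matrix(m: GenerationMatrix) -> dict:
    """Counts over the matrix: total entries, unique species, per-category uniques.

    ``total_entries`` counts every cell (the root row included);
    ``unique_species`` deduplicates by structure code.
    """
    uniques: set[StructureCode] = set()
    per_category: dict[str, set[StructureCode]] = {c.value: set() for c in Category}
    for entry in m.all_entries():
        uniques.add(entry.code)
        per_category[entry.category.value].add(entry.code)
    return {
        "total_entries": m.total_entries,
        "generated_entries": m.total_entries - len(m.rows[0]),
        "unique_species": len(uniques),
        "per_category_unique": {k: len(v) for k, v in per_category.items()},
    }


# -- rendering --------------------------------------------------------------------

_COLUMNS = ["row", "parent_id", "entry_id", "name", "category", "loops",
            "length_nt", "strand", "birth_time_s", "copies", "species_id"]


def render_generation_matrix(m: GenerationMatrix) -> str:
    """Deterministic CSV layout of the matrix (one line per entry, grouped by
    generation and parent, as in the worked generation-matrix figure)."""
    records = []
    for row in m.rows:
        for e in row:
            records.append({
                "row": e.row,
                "parent_id": e.parent_id if e.parent_id is not None else "",
                "entry_id": e.id,
                "name": e.name,
                "category": e.category.value,
                "loops": e.code.loops,
                "length_nt": length_of(e.code, m.geometry),
                "strand": e.code.strand.value,
                "birth_time_s": round(e.birth_nt / m.params.v, 9),
                "copies": float(e.copies),
                "species_id": str(e.code),
            })
    df = pd.DataFrame.from_records(records, columns=_COLUMNS)
    buffer = StringIO()
    df.to_csv(buffer, index=False)
    return buffer.getvalue()


def parse_generation_matrix_csv(text: str) -> pd.DataFrame:
    """Read a rendered matrix back into a table (render ∘ parse round-trips)."""
    return pd.read_csv(StringIO(text), keep_default_na=False,
                       float_precision="round_trip")
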