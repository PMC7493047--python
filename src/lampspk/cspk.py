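"""Compressed stoichiometric & pseudo-kinetic (c-SPK) engine.

The brute-force generation matrix tracks every amplicon entry individually
and is exponential in depth.  The c-SPK engine aggregates by species: the
reaction state is a map ``(species, arrival time) -> copies`` and every
state is expanded exactly once, so the cost scales with the number of
distinct species/time pairs rather than with the number of molecules.
Copies are real-valued, probability-weighted multiplicities.

The network decomposes into four sub-networks, all driven by the same
condensed reaction rules:

* the **dumbbell (SSD) cycle** — regenerates dumbbells: the seed dumbbell
  self-extends to an equal-length SL, which primes into a two-unit PDS;
  that PDS's self-extension displaces the complementary dumbbell, and one
  turn later the original dumbbell itself;
* **SS cycles** — the same machinery seeded with larger displaced SS
  species; their equal-length regeneration runs through the internal-
  priming (cPDS) route and closes on the complement every second period;
* the **SL-PDS highway** — the ladder of ever-longer SL/PDS species; every
  highway PDS reaction displaces a dumbbell-sized SS and terminal priming
  tips product into the terminated pool;
* the **PDS linker** — routes internally-primed PDS species: one
  self-extension hands an SL to the highway and a displaced SS to a new SS
  cycle; deeper cPDS recursion is not expanded.

The end-of-run census counts the amplicons *present* at ``t_R``: all
terminated products plus every reactant fraction whose next event would
complete after ``t_R``.
"""

from __future__ import annotations

import hashlib
import heapq
import json
from dataclasses import dataclass, field
from fractions import Fraction
from io import StringIO
from typing import Callable, Iterable, Optional, Union

import pandas as pd

from .amplicons import (
    Amplicon,
    Category,
    Strand,
    StructureCode,
    classify,
    is_linker_pds,
    length_of,
    ss_code,
)
from .brute import ResourceLimitError
from .geometry import AssayGeometry
from .rules import (
    ContractViolation,
    KineticParams,
    displaced_code,
    enumerate_fates,
    nt_added_for,
    product_code,
)

Number = Union[float, Fraction]


# ---------------------------------------------------------------------------------
# census container


@dataclass
class AmpliconCensus:
    """Copies of every species present at the end of the reaction time.

    The map is keyed by species (structure code); views aggregate it by
    category, by length, or by ``(category, length, strand)``.
    """

    species: dict[StructureCode, Number]
    t_R: float
    n0: float
    params_hash: str = ""

    @property
    def total_copies(self) -> float:
        return float(sum(self.species.values()))

    def by_category(self) -> dict[str, float]:
        out = {c.value: 0.0 for c in Category}
        for code, copies in self.species.items():
            out[classify(code).value] += float(copies)
        return out

    def by_length(self, geometry: AssayGeometry) -> dict[int, float]:
        out: dict[int, float] = {}
        for code, copies in self.species.items():
            length = length_of(code, geometry)
            out[length] = out.get(length, 0.0) + float(copies)
        return out

    def by_key(self, geometry: AssayGeometry) -> dict[tuple[str, int, str], Number]:
        """Aggregate to the ``(category, length_nt, strand)`` map."""
        out: dict[tuple[str, int, str], Number] = {}
        for code, copies in self.species.items():
            key = (classify(code).value, length_of(code, geometry), code.strand.value)
            out[key] = out.get(key, 0) + copies
        return out

    def to_dataframe(self, geometry: AssayGeometry) -> pd.DataFrame:
        rows = [
            {
                "species_id": str(code),
                "category": classify(code).value,
                "loops": code.loops,
                "length_nt": length_of(code, geometry),
                "strand": code.strand.value,
                "birth_time_s": "",
                "copies": float(copies),
                "lineage": "",
                "parent_id": "",
            }
            for code, copies in sorted(self.species.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["species_id", "category", "loops", "length_nt", "strand",
                     "birth_time_s", "copies", "lineage", "parent_id"],
        )

    def to_csv(self, geometry: AssayGeometry) -> str:
        buf = StringIO()
        self.to_dataframe(geometry).to_csv(buf, index=False)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, t_R: float = 0.0, n0: float = 0.0) -> "AmpliconCensus":
        df = pd.read_csv(StringIO(text), keep_default_na=False)
        species = {
            StructureCode.parse(row["species_id"]): float(row["copies"])
            for _, row in df.iterrows()
        }
        return cls(species=species, t_R=t_R, n0=n0)


def params_hash(params: KineticParams, geometry: AssayGeometry) -> str:
    payload = {
        "v": params.v,
        "branching": params.branching.to_dict(),
        "init_self_nt": params.init_self_nt,
        "init_internal_nt": params.init_internal_nt,
        "geometry": geometry.to_dict(),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------------
# packets and network labels


@dataclass(frozen=True)
class CyclePacket:
    """The data package handed between network stages."""

    code: StructureCode
    copies: Number
    time_nt: int  # availability time in polymerized nucleotides (time_s = nt / v)
    origin: str = "root"  # sister1 | sister2 | linker | root

    def __post_init__(self) -> None:
        if self.copies <= 0:
            raise ContractViolation("packet copies must be > 0")
        if self.time_nt < 0:
            raise ContractViolation("packet availability time must be >= 0")

    def time_s(self, params: KineticParams) -> float:
        return self.time_nt / params.v


def network_of(code: StructureCode) -> str:
    """Which sub-network owns a species."""
    category = classify(code)
    if category is Category.SS:
        return "ssd_cycle" if code.size == 1 else "ss_cycle"
    if category is Category.SL:
        return "highway"
    if category is Category.PDS:
        return "linker" if is_linker_pds(code) else "highway"
    return "terminated"


# ---------------------------------------------------------------------------------
# the aggregated engine


class _Expander:
    """Per-species expansion table: (product, displaced, dt, probability)."""

    def __init__(self, params: KineticParams, geometry: AssayGeometry, exact: bool):
        self.params = params
        self.geometry = geometry
        self.exact = exact
        self._table: dict[StructureCode, list] = {}

    def __call__(self, code: StructureCode) -> list:
        table = self._table.get(code)
        if table is None:
            probs = self.params.branching.fate_probabilities(code)
            displaced = (
                displaced_code(code) if classify(code) is Category.PDS else None
            )
            table = [
                (
                    product_code(code, fate),
                    displaced,
                    nt_added_for(code, fate, self.geometry, self.params),
                    p if self.exact else float(p),
                )
                for fate, p in probs.items()
            ]
            self._table[code] = table
        return table


def run_cspk(
    n0: float,
    t_R: float,
    params: KineticParams,
    geometry: AssayGeometry,
    *,
    seeds: Optional[list[tuple[StructureCode, Number]]] = None,
    exact: bool = False,
    max_states: int = 10**7,
    audit: Optional[dict] = None,
) -> AmpliconCensus:
    """Propagate the condensed network to ``t_R`` seconds and take the census.

    ``n0`` counts starting dumbbells; one double-stranded template yields one
    sense and one antisense dumbbell, so by default ``n0/2`` copies of each
    strand are seeded.  ``seeds`` overrides this.  With ``exact=True`` the
    copy arithmetic uses exact rationals (matching the brute-force oracle
    bit for bit).  ``audit``, if given a dict, receives counters used by the
    conservation checks (one displaced SS per PDS event).
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if t_R < 0:
        raise ValueError("t_R must be >= 0")
    if seeds is None:
        half = Fraction(n0, 2) if exact else n0 / 2.0
        seeds = [
            (ss_code(1, Strand.SENSE), half),
            (ss_code(1, Strand.ANTISENSE), half),
        ]

    horizon_nt = params.v * t_R
    expand = _Expander(params, geometry, exact)
    zero = Fraction(0) if exact else 0.0

    # worklist keyed by (time, species); heap gives deterministic time order
    pending: dict[tuple[int, StructureCode], Number] = {}
    heap: list[tuple[int, StructureCode]] = []
    census: dict[StructureCode, Number] = {}

    def push(t: int, code: StructureCode, copies: Number) -> None:
        key = (t, code)
        if key in pending:
            pending[key] += copies
        else:
            pending[key] = copies
            heapq.heappush(heap, key)

    for code, copies in seeds:
        if classify(code) is not Category.SS or code.size != 1:
            raise ContractViolation("seeds must be dumbbells (two-loop SS)")
        push(0, code, copies)

    states = 0
    pds_events = zero
    displaced_total = zero
    while heap:
        t, code = heapq.heappop(heap)
        copies = pending.pop((t, code))
        states += 1
        if states > max_states:
            raise ResourceLimitError(
                f"c-SPK state count exceeded {max_states}; shorten t_R"
            )
        if classify(code) is Category.T:
            census[code] = census.get(code, zero) + copies
            continue
        for pcode, dcode, dt, p in expand(code):
            amount = copies * p
            tc = t + dt
            if tc <= horizon_nt:
                push(tc, pcode, amount)
                if dcode is not None:
                    push(tc, dcode, amount)
                    displaced_total += amount
                    pds_events += amount
            else:
                # mid-event at t_R: the reactant fraction is still present
                census[code] = census.get(code, zero) + amount

    if audit is not None:
        audit["states"] = states
        audit["pds_event_copies"] = pds_events
        audit["displaced_ss_copies"] = displaced_total

    return AmpliconCensus(
        species=census,
        t_R=t_R,
        n0=n0,
        params_hash=params_hash(params, geometry),
    )


def copies_curve(
    n0: float,
    t_grid: Iterable[float],
    params: KineticParams,
    geometry: AssayGeometry,
    *,
    seeds: Optional[list[tuple[StructureCode, Number]]] = None,
    max_states: int = 10**7,
) -> pd.DataFrame:
    """Total and per-category copies for each reaction time in ``t_grid``.

    Each grid point is an independent run of :func:`run_cspk` (the census at
    time t does not depend on the final horizon, so the curve equals the
    trace of a single long run sampled at the grid).
    """
    grid = list(t_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("t_grid must be strictly increasing")
    rows = []
    for t_R in grid:
        census = run_cspk(
            n0, t_R, params, geometry, seeds=seeds, max_states=max_states
        )
        by_cat = census.by_category()
        rows.append(
            {
                "t_R_s": t_R,
                "total_copies": census.total_copies,
                **{f"copies_{k}": v for k, v in by_cat.items()},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------------
# the four networks as restricted runs (inspection / unit-test surfaces)
#
# run_cspk drives the whole network through one aggregated worklist; the
# functions below run the same arithmetic restricted to the species a single
# sub-network owns, returning what that network hands to its neighbours.


@dataclass
class NetworkRun:
    """Result of running one sub-network in isolation."""

    internal: list[CyclePacket] = field(default_factory=list)
    to_highway: list[CyclePacket] = field(default_factory=list)
    to_linker: list[CyclePacket] = field(default_factory=list)
    to_ss_cycles: list[CyclePacket] = field(default_factory=list)
    terminated: list[CyclePacket] = field(default_factory=list)
    frontier: dict[StructureCode, Number] = field(default_factory=dict)


def _restricted_run(
    seeds: list[CyclePacket],
    allowed: Callable[[StructureCode], bool],
    route: Callable[[NetworkRun, CyclePacket], None],
    t_R: float,
    params: KineticParams,
    geometry: AssayGeometry,
) -> NetworkRun:
    horizon_nt = params.v * t_R
    expand = _Expander(params, geometry, exact=False)
    result = NetworkRun()
    pending: dict[tuple[int, StructureCode], float] = {}
    heap: list[tuple[int, StructureCode]] = []

    def push(packet: CyclePacket) -> None:
        if not allowed(packet.code) or classify(packet.code) is Category.T:
            route(result, packet)
            return
        key = (packet.time_nt, packet.code)
        if key in pending:
            pending[key] += packet.copies
        else:
            pending[key] = packet.copies
            heapq.heappush(heap, key)

    for packet in seeds:
        if packet.time_nt > horizon_nt:
            raise ContractViolation("packet availability time exceeds t_R")
        push(packet)

    while heap:
        t, code = heapq.heappop(heap)
        copies = pending.pop((t, code))
        result.internal.append(CyclePacket(code, copies, t, network_of(code)))
        for pcode, dcode, dt, p in expand(code):
            amount = copies * p
            tc = t + dt
            if tc <= horizon_nt:
                push(CyclePacket(pcode, amount, tc, network_of(code)))
                if dcode is not None:
                    push(CyclePacket(dcode, amount, tc, network_of(code)))
            else:
                result.frontier[code] = result.frontier.get(code, 0.0) + amount
    return result


def _route_by_network(result: NetworkRun, packet: CyclePacket) -> None:
    target = network_of(packet.code)
    if target == "terminated":
        result.terminated.append(packet)
    elif target == "linker":
        result.to_linker.append(packet)
    elif target == "highway":
        result.to_highway.append(packet)
    else:
        result.to_ss_cycles.append(packet)


def run_ssd_cycle(
    seed: Amplicon,
    t_R: float,
    params: KineticParams,
    geometry: AssayGeometry,
) -> NetworkRun:
    """Run the dumbbell cycle in isolation.

    The cycle owns the two dumbbell species, their equal-length SLs and the
    two-unit PDS species they prime into; the PDS self-extension edge (which
    displaces first the complementary and then the original dumbbell) is
    computed here because the regeneration depends on it.  Emitted SLs of
    size two head the sister-network highways: the one on the seed's strand
    is sister 1, its complement sister 2.
    """
    if seed.category is not Category.SS or seed.loops != 2:
        raise ContractViolation("the dumbbell cycle must be seeded with a dumbbell")

    def allowed(code: StructureCode) -> bool:
        cat = classify(code)
        if cat is Category.SS:
            return code.size == 1
        if cat is Category.SL:
            return code.size == 1
        if cat is Category.PDS:
            return code.size == 2 and not is_linker_pds(code)
        return False

    def route(result: NetworkRun, packet: CyclePacket) -> None:
        if classify(packet.code) is Category.SL:
            sister = "sister1" if packet.code.strand is seed.strand else "sister2"
            packet = CyclePacket(
                packet.code, packet.copies, packet.time_nt, sister
            )
            result.to_highway.append(packet)
        else:
            _route_by_network(result, packet)

    seeds = [CyclePacket(seed.code, seed.copies, int(round(seed.birth_time * params.v)))]
    return _restricted_run(seeds, allowed, route, t_R, params, geometry)


def run_ss_cycle(
    seed: Amplicon,
    t_R: float,
    params: KineticParams,
    geometry: AssayGeometry,
) -> NetworkRun:
    """Run one equal-length SS cycle in isolation.

    For a dumbbell seed this delegates to :func:`run_ssd_cycle`.  For an SS
    of n >= 2 units the regeneration route runs through self-extension, the
    highway PDS one unit longer, its internal priming (cPDS) and one linker
    self-extension, which displaces the complementary SS of the seed's
    length; two periods close on the seed itself.  Terminal priming events
    (T), internally-primed PDS hand-offs and larger SLs leave the cycle.
    """
    if seed.category is not Category.SS:
        raise ContractViolation("SS cycles must be seeded with an SS amplicon")
    if seed.loops == 2:
        return run_ssd_cycle(seed, t_R, params, geometry)
    n = seed.code.size

    def allowed(code: StructureCode) -> bool:
        cat = classify(code)
        if cat is Category.SS:
            return code.size == n
        if cat is Category.SL:
            return code.size == n
        if cat is Category.PDS:
            if is_linker_pds(code):
                # the cycle's own cPDS: internally primed, one unit longer,
                # whose self-extension regenerates the seed-length SS
                return code.size == n + 1 and code.units.count("d") == n
            return code.size == n + 1
        return False

    seeds = [CyclePacket(seed.code, seed.copies, int(round(seed.birth_time * params.v)))]
    return _restricted_run(seeds, allowed, _route_by_network, t_R, params, geometry)


def run_sl_pds_highway(
    packet: CyclePacket,
    t_R: float,
    params: KineticParams,
    geometry: AssayGeometry,
) -> NetworkRun:
    """Run the increasing-length SL-PDS ladder from one packet.

    Alternates SL -> (primer) -> PDS -> (self-extension) -> larger SL,
    displacing one dumbbell-sized SS per PDS reaction (routed to an SS
    cycle), terminating a fraction at every PDS via terminal priming, and
    handing internally-primed cPDS species to the linker.
    """
    category = classify(packet.code)
    if category not in (Category.SL, Category.PDS) or (
        category is Category.PDS and is_linker_pds(packet.code)
    ):
        raise ContractViolation("highway packets carry an SL or a highway PDS")

    def allowed(code: StructureCode) -> bool:
        cat = classify(code)
        if cat is Category.SL:
            return code.size >= packet.code.size
        if cat is Category.PDS:
            return not is_linker_pds(code) and code.size >= packet.code.size
        return False

    return _restricted_run(
        [packet], allowed, _route_by_network, t_R, params, geometry
    )


def run_pds_linker(
    packet: CyclePacket,
    t_R: float,
    params: KineticParams,
    geometry: AssayGeometry,
) -> NetworkRun:
    """Self-extend an internally-primed PDS once.

    Emits the resulting SL to the highway and the displaced SS to a new SS
    cycle; deeper cPDS recursion never occurs (internally-primed PDS species
    self-extend only).
    """
    if not is_linker_pds(packet.code):
        raise ContractViolation("linker packets carry an internally-primed PDS")

    def allowed(code: StructureCode) -> bool:
        return code == packet.code

    return _restricted_run(
        [packet], allowed, _route_by_network, t_R, params, geometry
    )
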