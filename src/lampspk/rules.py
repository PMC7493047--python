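"""The condensed LAMP reaction network.

Each non-terminated amplicon category has at most three fates:

* kind ``I``   — self-extension of the free 3' end,
* kind ``II``  — inner-primer annealing at the 3'-terminal loop,
* kind ``III`` — inner-primer annealing at an internal loop.

The product map is closed over the four categories::

    SS  + I   -> SL   (same length)
    SS  + II  -> T
    SS  + III -> PDS            (linker-routed; needs >= 3 loops)
    SL  + PBE -> PDS            (one unit longer)
    PDS + I   -> SL  + displaced SS
    PDS + II  -> T   + displaced SS
    PDS + III -> cPDS + displaced SS   (needs >= 2 loops)

Whenever a PDS reacts, its bound complementary strand is released as an SS
spanning the PDS's duplex units, on the opposite strand — dumbbell-sized for
every highway PDS, larger for linker PDS species.  PDS species created by pathway
III (internal priming) self-extend only — the deeper PDS -> cPDS recursion
contributes negligibly and is not expanded.

Kinetics are pseudo-kinetic: the single time scale is the polymerase
nucleotide-incorporation rate ``v``; an event lasts ``nt_added / v`` seconds
and rates never depend on free enzyme, primer or dNTP concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Optional

from .amplicons import (
    Amplicon,
    Category,
    StructureCode,
    classify,
    is_linker_pds,
    length_of,
    pds_highway_code,
    pds_linker_code,
    sl_code,
    ss_code,
    t_code,
)
from .geometry import AssayGeometry, ConfigurationError


class NoFatesError(ValueError):
    """Raised when asking for the fates of an inert (T) amplicon."""


class ContractViolation(ValueError):
    """Raised when a pathway is applied to a reactant it is not legal for."""


@dataclass(frozen=True, order=True)
class Pathway:
    reactant_category: Category
    kind: str  # "I" | "II" | "III"
    label: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


SS_I = Pathway(Category.SS, "I", "SS_I")
SS_II = Pathway(Category.SS, "II", "SS_II")
SS_III = Pathway(Category.SS, "III", "SS_III")
SL_I = Pathway(Category.SL, "I", "SL_I")
PDS_I = Pathway(Category.PDS, "I", "PDS_I")
PDS_II = Pathway(Category.PDS, "II", "PDS_II")
PDS_III = Pathway(Category.PDS, "III", "PDS_III")


@dataclass(frozen=True)
class BranchingPolicy:
    """Probability of each fate for reactants with more than one fate.

    When a reactant's structure forbids some fates (the dumbbell has no
    internal loop; a one-loop PDS cannot make a cPDS; a linker PDS only
    self-extends) the remaining probabilities are renormalised, so copies
    are conserved at every branch point.
    """

    pSS_I: Fraction = Fraction(1, 3)
    pSS_II: Fraction = Fraction(1, 3)
    pSS_III: Fraction = Fraction(1, 3)
    pPDS_I: Fraction = Fraction(1, 3)
    pPDS_II: Fraction = Fraction(1, 3)
    pPDS_III: Fraction = Fraction(1, 3)

    def __post_init__(self) -> None:
        ss = (self.pSS_I, self.pSS_II, self.pSS_III)
        pds = (self.pPDS_I, self.pPDS_II, self.pPDS_III)
        for trio, name in ((ss, "SS"), (pds, "PDS")):
            if any(p < 0 or p > 1 for p in trio):
                raise ConfigurationError(f"{name} fate probabilities must lie in [0,1]")
            if sum(trio) != 1:
                raise ConfigurationError(f"{name} fate probabilities must sum to 1")

    @classmethod
    def from_self_extension_ratio(cls, ratio: Fraction | int | str) -> "BranchingPolicy":
        """Build a policy from a single self-extension : primer-capture ratio.

        Self-extension (kind I) gets weight ``ratio``; primer capture gets
        weight 1 split equally between terminal (II) and internal (III)
        annealing.  Inner primers are in large excess in LAMP, so ratios
        below 1 describe primer-dominated kinetics.
        """
        r = Fraction(ratio)
        if r <= 0:
            raise ConfigurationError("self-extension ratio must be positive")
        p_i = r / (r + 1)
        p_cap = Fraction(1, 2) / (r + 1)
        return cls(p_i, p_cap, p_cap, p_i, p_cap, p_cap)

    def fate_probabilities(self, code: StructureCode) -> dict[Pathway, Fraction]:
        """Renormalised fate probabilities for a concrete reactant species."""
        fates = enumerate_fates(code)
        raw = {
            SS_I: self.pSS_I, SS_II: self.pSS_II, SS_III: self.pSS_III,
            SL_I: Fraction(1),
            PDS_I: self.pPDS_I, PDS_II: self.pPDS_II, PDS_III: self.pPDS_III,
        }
        total = sum(raw[f] for f in fates)
        return {f: raw[f] / total for f in fates}

    def to_dict(self) -> dict:
        return {
            "pSS_I": str(self.pSS_I), "pSS_II": str(self.pSS_II),
            "pSS_III": str(self.pSS_III), "pPDS_I": str(self.pPDS_I),
            "pPDS_II": str(self.pPDS_II), "pPDS_III": str(self.pPDS_III),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BranchingPolicy":
        return cls(**{k: Fraction(v) for k, v in data.items()})


#: Default fate probabilities (see docs/methods.md).  On a predominantly
#: single-stranded template, intramolecular self-extension outcompetes
#: intermolecular priming (pSS_I = 19/20); on a partially double-stranded
#: template the many internal loops dominate the single 3'-terminal site
#: (pPDS_III ≈ pPDS_I, terminal capture rare).  The profile is calibrated
#: once so the default model reproduces the canonical dominance (~85%) of
#: double-stranded product categories over SS + T.
DEFAULT_BRANCHING = dict(
    pSS_I=Fraction(19, 20), pSS_II=Fraction(1, 40), pSS_III=Fraction(1, 40),
    pPDS_I=Fraction(1, 2), pPDS_II=Fraction(1, 40), pPDS_III=Fraction(19, 40),
)


@dataclass(frozen=True)
class KineticParams:
    """Polymerase rate, branching policy and the two initiation penalties.

    ``v`` is the nucleotide incorporation rate (nt/s) — the model's only
    time scale.  ``init_self_nt`` is the fixed nt-equivalent cost of
    initiating self-extension (the closed 3'-terminal stem must open before
    the polymerase engages); ``init_internal_nt`` is the cost of a primer
    invading an internal loop of a folded amplicon.  Terminal-loop priming
    carries no penalty: terminal loops are freely accessible.
    """

    v: float = 100.0  # nt/s, representative of Bst 2.0 WarmStart
    branching: BranchingPolicy = BranchingPolicy(**DEFAULT_BRANCHING)
    init_self_nt: int = 0
    init_internal_nt: int = 0

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ConfigurationError(f"incorporation rate v={self.v} must be > 0")
        if self.init_self_nt < 0 or self.init_internal_nt < 0:
            raise ConfigurationError("initiation penalties must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "KineticParams":
        branching = data.get("branching")
        if branching is None and "self_extension_ratio" in data:
            branching = BranchingPolicy.from_self_extension_ratio(
                Fraction(data["self_extension_ratio"])
            )
        elif isinstance(branching, dict):
            branching = BranchingPolicy.from_dict(branching)
        elif branching is None:
            branching = BranchingPolicy(**DEFAULT_BRANCHING)
        return cls(
            v=float(data.get("v", 100.0)),
            branching=branching,
            init_self_nt=int(data.get("init_self_nt", 0)),
            init_internal_nt=int(data.get("init_internal_nt", 0)),
        )


@dataclass
class ReactionEvent:
    reactant: Amplicon
    pathway: Pathway
    products: list[Amplicon]
    nt_added: int
    duration_s: float


# -- fate enumeration -------------------------------------------------------------


def enumerate_fates(code: StructureCode) -> list[Pathway]:
    """Legal pathways for a reactant species; T amplicons are inert."""
    category = classify(code)
    if category is Category.T:
        raise NoFatesError("terminated amplicons do not react")
    if category is Category.SL:
        return [SL_I]
    if category is Category.SS:
        if code.loops == 2:  # the dumbbell: no internal loop to prime
            return [SS_I, SS_II]
        return [SS_I, SS_II, SS_III]
    # PDS
    if is_linker_pds(code):
        return [PDS_I]
    if code.loops == 1:
        return [PDS_I, PDS_II]
    return [PDS_I, PDS_II, PDS_III]


# -- product construction ---------------------------------------------------------


def product_code(code: StructureCode, pathway: Pathway) -> StructureCode:
    """Primary product species of ``pathway`` applied to ``code``."""
    n = code.size
    s = code.strand
    category = classify(code)
    if category is Category.SS:
        if pathway == SS_I:
            return sl_code(n, s)
        if pathway == SS_II:
            return t_code(n, s)
        if pathway == SS_III:
            return pds_linker_code(n, 1, s)
    elif category is Category.SL:
        if pathway == SL_I:
            return pds_highway_code(n + 1, s)
    elif category is Category.PDS:
        if pathway == PDS_I:
            return sl_code(n, s)
        if pathway == PDS_II:
            return t_code(n, s)
        if pathway == PDS_III:
            # internal priming at the loop next to the 3'-terminal one; the
            # extension runs to the 5' end, leaving only the terminal loop
            return pds_linker_code(n, 1, s)
    raise ContractViolation(f"pathway {pathway.label} is illegal for {code}")


def displaced_code(code: StructureCode) -> StructureCode:
    """The SS released by strand displacement when a PDS reacts.

    The bound complement spans exactly the duplex units of the PDS and sits
    on the opposite strand.  A highway PDS carries a single duplex unit, so
    every highway turn displaces a dumbbell-sized SS — in the dumbbell cycle
    the first displaced SS is the complement of the seed dumbbell and the
    second turn re-displaces the seed itself.  Linker PDS species carry
    longer complements and seed the larger SS cycles.
    """
    if classify(code) is not Category.PDS:
        raise ContractViolation("only PDS amplicons displace an SS")
    return ss_code(code.units.count("d"), code.strand.opposite)


def nt_added_for(
    code: StructureCode,
    pathway: Pathway,
    geometry: AssayGeometry,
    params: KineticParams,
) -> int:
    """Effective nucleotides polymerized by one event, on the unit ruler.

    The per-pathway counts are closed forms in the geometry constants
    (unit span U, primer footprint fp, loop slack λ) plus the two
    initiation penalties, and encode both true polymerization and the
    rate-modifying effect of template secondary structure:

    ====================  =======================  ==========================
    event                 effective nt             rationale
    ====================  =======================  ==========================
    SS self-extension     n·λ + c_self             zips the stem-folded
                                                   concatemer, polymerizing
                                                   the loop slack of each
                                                   unit, after opening the
                                                   closed 3'-terminal stem
    SS terminal priming   n·U − fp                 full second strand
    SS internal priming   (n−1)·U − fp + c_int     runs to the 5' end after
                                                   invading the fold
    SL priming            U − fp                   one unit; the template's
                                                   first stem junction stalls
                                                   the extension
    PDS self-extension    λ                        fills the 3'-terminal loop
                                                   slack; the free 3' end sits
                                                   at an open junction, so no
                                                   initiation penalty
    PDS terminal priming  (n−1)·U − fp             copies the single-stranded
                                                   portion, displacing through
                                                   the duplex
    PDS internal priming  (n−2)·U − fp + c_int     to the 5' end after
                                                   invasion
    ====================  =======================  ==========================
    """
    u = geometry.unit_length
    slack = geometry.loop_slack
    fp = geometry.primer_footprint
    n = code.size
    category = classify(code)
    if category is Category.SS:
        if pathway == SS_I:
            return n * slack + params.init_self_nt
        if pathway == SS_II:
            return n * u - fp
        if pathway == SS_III:
            return (n - 1) * u - fp + params.init_internal_nt
    elif category is Category.SL:
        if pathway == SL_I:
            return u - fp
    elif category is Category.PDS:
        if pathway == PDS_I:
            return slack
        if pathway == PDS_II:
            return (n - 1) * u - fp
        if pathway == PDS_III:
            return (n - 2) * u - fp + params.init_internal_nt
    raise ContractViolation(f"pathway {pathway.label} is illegal for {code}")


def event_duration(nt_added: int, v: float) -> float:
    """Seconds taken to polymerize ``nt_added`` nucleotides."""
    if v <= 0:
        raise ConfigurationError(f"incorporation rate v={v} must be > 0")
    if nt_added < 0:
        raise ContractViolation("nt_added must be >= 0")
    return nt_added / v


_SUFFIX = {
    (Category.SL, Category.SS): "a",
    (Category.SL, Category.PDS): "b",
    (Category.T, Category.SS): "a",
    (Category.T, Category.PDS): "b",
    (Category.PDS, Category.SS): "a",
    (Category.PDS, Category.SL): "b",
    (Category.PDS, Category.PDS): "c",
}


def lineage_suffix(product: Category, parent: Category) -> str:
    """Generation-matrix suffix: a/b/c indexes the possible parent categories
    of each product type (displaced SS amplicons carry no suffix)."""
    if product is Category.SS:
        return ""
    return _SUFFIX[(product, parent)]


def apply_pathway(
    a: Amplicon,
    pathway: Pathway,
    params: KineticParams,
    geometry: AssayGeometry,
) -> ReactionEvent:
    """Run one pathway on one amplicon, producing the primary product (and the
    displaced SS for a PDS reactant), copy-weighted by the branching policy."""
    fates = enumerate_fates(a.code)
    if pathway not in fates:
        raise ContractViolation(f"{pathway.label} not a fate of {a.code}")
    prob = params.branching.fate_probabilities(a.code)[pathway]
    nt = nt_added_for(a.code, pathway, geometry, params)
    duration = event_duration(nt, params.v)
    birth = a.birth_time + duration
    parent_cat = a.category

    pcode = product_code(a.code, pathway)
    products = [
        Amplicon(
            code=pcode,
            length_nt=length_of(pcode, geometry),
            birth_time=birth,
            copies=a.copies * prob,
            lineage=lineage_suffix(classify(pcode), parent_cat),
            parent_id=a.id,
        )
    ]
    if parent_cat is Category.PDS:
        dcode = displaced_code(a.code)
        products.append(
            Amplicon(
                code=dcode,
                length_nt=length_of(dcode, geometry),
                birth_time=birth,
                copies=a.copies * prob,
                lineage="",
                parent_id=a.id,
            )
        )
    return ReactionEvent(a, pathway, products, nt, duration)


def displaced_ss(reactant: Amplicon, pathway: Pathway, geometry: AssayGeometry) -> Amplicon:
    """The SS species released when ``reactant`` (a PDS) follows ``pathway``.

    The release happens at the fate's completion; :func:`apply_pathway`
    stamps the actual birth time, this helper only identifies the species.
    """
    if reactant.category is not Category.PDS:
        raise ContractViolation("only PDS amplicons displace an SS")
    if pathway not in enumerate_fates(reactant.code):
        raise ContractViolation(f"{pathway.label} not a fate of {reactant.code}")
    dcode = displaced_code(reactant.code)
    return Amplicon(
        code=dcode,
        length_nt=length_of(dcode, geometry),
        birth_time=reactant.birth_time,
        copies=reactant.copies,
        lineage="",
        parent_id=reactant.id,
    )
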