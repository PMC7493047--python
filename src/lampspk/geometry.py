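"""Assay geometry: the nucleotide ruler for all length arithmetic.

A four-primer LAMP assay is defined by six primer-binding regions
(F3, F2, F1 on the forward side; B1, B2, B3 on the backward side) plus the
stretches between them.  Every amplicon the simulator produces is a
concatemer of one repeating *dumbbell unit*, so a single derived quantity —
the unit span in nucleotides — grounds every length and every
nucleotide-addition count in the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from importlib import resources
from pathlib import Path


class ConfigurationError(ValueError):
    """Raised for geometric or kinetic parameters that make no sense."""


_SEGMENT_FIELDS = ("seg_F3", "seg_F2", "seg_F1", "seg_B1", "seg_B2", "seg_B3")
_SPACER_FIELDS = ("spacer_F1F2", "spacer_B1B2", "spacer_F2F3", "spacer_B2B3", "core")


@dataclass(frozen=True)
class AssayGeometry:
    """Nucleotide lengths of the six primer regions and the inter-region spacers.

    ``seg_*`` are the primer-binding regions (typically ~20 nt each);
    ``spacer_F1F2`` / ``spacer_B1B2`` are the single-stranded loop stretches
    of the dumbbell; ``spacer_F2F3`` / ``spacer_B2B3`` separate the inner
    from the outer primer regions (they matter for primer design, not for
    amplicon lengths); ``core`` is the stretch between F1 and B1.
    ``conc_inner`` / ``conc_outer`` are primer concentrations in µM — inner
    primers are always in excess in LAMP.
    """

    seg_F3: int = 20
    seg_F2: int = 20
    seg_F1: int = 20
    seg_B1: int = 20
    seg_B2: int = 20
    seg_B3: int = 20
    spacer_F1F2: int = 40
    spacer_B1B2: int = 40
    spacer_F2F3: int = 40
    spacer_B2B3: int = 40
    core: int = 40
    conc_inner: float = 1.6
    conc_outer: float = 0.2

    def __post_init__(self) -> None:
        for name in _SEGMENT_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ConfigurationError(
                    f"segment length {name}={value!r} must be a positive integer"
                )
        for name in _SPACER_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ConfigurationError(
                    f"spacer length {name}={value!r} must be a non-negative integer"
                )
        if self.conc_inner <= 0 or self.conc_outer <= 0:
            raise ConfigurationError("primer concentrations must be positive")
        if self.conc_inner < self.conc_outer:
            raise ConfigurationError(
                "inner primers must be at least as concentrated as outer primers "
                f"(got inner={self.conc_inner}, outer={self.conc_outer})"
            )
        if self.primer_footprint >= self.unit_length:
            raise ConfigurationError(
                "inner primer footprint must be smaller than the dumbbell unit"
            )

    # -- derived ruler quantities -------------------------------------------------

    @property
    def unit_length(self) -> int:
        """Span of one dumbbell unit in nucleotides.

        The dumbbell covers the target from F2 to B2: the two stem regions
        (F1, B1), the two loop stretches carrying the F2/B2 sites, and the
        core between the stems::

            U = F2 + spacer_F1F2 + F1 + core + B1 + spacer_B1B2 + B2
        """
        return (
            self.seg_F2
            + self.spacer_F1F2
            + self.seg_F1
            + self.core
            + self.seg_B1
            + self.spacer_B1B2
            + self.seg_B2
        )

    @property
    def dumbbell_length(self) -> int:
        """Length (nt) of the dumbbell — the minimum-length species (= one unit)."""
        return self.unit_length

    @property
    def primer_footprint(self) -> int:
        """Annealed (not polymerized) part of an inner primer, in nucleotides.

        The inner primer anneals via its F2-type half; both inner primers are
        assumed to share this annealing length, which keeps the sense and
        antisense halves of the network exactly symmetric.
        """
        return self.seg_F2

    @property
    def loop_slack(self) -> int:
        """Unpaired nucleotides per single-stranded unit of a folded amplicon.

        A predominantly single-stranded stretch folds into dumbbell-like
        stem-loop repeats; only the forward loop stretch (spacer + F2 site)
        stays unpaired per unit.  Self-extension events polymerize exactly
        this slack per unit they zip, which is why they are much faster than
        primer-based synthesis of a whole new strand.
        """
        return self.spacer_F1F2 + self.seg_F2

    @property
    def primer_excess(self) -> float:
        """Inner:outer primer concentration ratio (>= 1)."""
        return self.conc_inner / self.conc_outer

    # -- serialisation ------------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AssayGeometry":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown geometry fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "AssayGeometry":
        with open(path) as fh:
            payload = json.load(fh)
        return cls.from_dict(payload.get("geometry", payload))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def load_bundled_config(name: str = "default") -> dict:
    """Load a bundled JSON config (``default`` or ``reference``) as a dict.

    ``default`` holds a generic four-primer assay; ``reference`` is the
    calibrated geometry/rate pair used for the 25-second generation-matrix
    worked example.
    """
    ref = resources.files("lampspk.data").joinpath(f"{name}.json")
    try:
        payload = json.loads(ref.read_text())
    except FileNotFoundError:
        raise ConfigurationError(f"no bundled config named {name!r}") from None
    return payload


def load_bundled_geometry(name: str = "default") -> AssayGeometry:
    return AssayGeometry.from_dict(load_bundled_config(name)["geometry"])
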