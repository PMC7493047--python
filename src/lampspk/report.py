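"""Post-processing of amplicon censuses: category fractions, length
pyramids, and the simulated electrophoresis gel."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .amplicons import Category
from .cspk import AmpliconCensus
from .geometry import AssayGeometry


class EmptyCensusError(ValueError):
    """Raised for operations that need a non-empty census."""


def category_fractions(census: AmpliconCensus) -> dict[str, float]:
    """Fraction of total copies per category, plus the double-stranded-rich
    (PDS+SL) vs single-stranded/terminated (SS+T) split."""
    total = census.total_copies
    if total <= 0:
        raise EmptyCensusError("census has no copies")
    by_cat = census.by_category()
    out = {k: v / total for k, v in by_cat.items()}
    out["PDS+SL"] = out["PDS"] + out["SL"]
    out["SS+T"] = out["SS"] + out["T"]
    return out


@dataclass
class LengthPyramid:
    """Copies binned by amplicon length; half-open bins [lo, hi)."""

    bin_edges: np.ndarray  # length len(counts)+1
    counts: np.ndarray
    bin_width: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges)
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def monotone_decreasing_prefix(self) -> int:
        """Number of leading bins over which counts strictly decrease."""
        run = 1
        for a, b in zip(self.counts, self.counts[1:]):
            if b < a:
                run += 1
            else:
                break
        return run

    def to_rows(self) -> list[dict]:
        return [
            {"length_lo_nt": int(lo), "length_hi_nt": int(hi), "copies": float(c)}
            for lo, hi, c in zip(self.bin_edges[:-1], self.bin_edges[1:], self.counts)
        ]


def length_pyramid(
    census: AmpliconCensus,
    geometry: AssayGeometry,
    bin_width: int = 5000,
) -> LengthPyramid:
    """Bin census copies by length into half-open bins of ``bin_width`` nt."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    by_length = census.by_length(geometry)
    if not by_length:
        return LengthPyramid(np.array([0, bin_width]), np.array([0.0]), bin_width)
    max_length = max(by_length)
    n_bins = max_length // bin_width + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    for length, copies in by_length.items():
        counts[length // bin_width] += copies
    return LengthPyramid(edges, counts, bin_width)


# ---------------------------------------------------------------------------------
# simulated gel


DEFAULT_LADDER = (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000)


@dataclass
class GelImage:
    """A rendered two-lane gel: ladder lane and sample lane.

    Band vertical position is linear in log(length), interpolated against
    the ladder, so shorter fragments migrate farther.  Band intensity in the
    sample lane is mass-weighted (copies x length).  The model treats
    amplicons as rigid linear duplexes; real LAMP cauliflower structures
    migrate anomalously, so experimental band positions need not match.
    """

    ladder: tuple[int, ...]
    sample_bands: list[tuple[int, float]]  # (length_nt, intensity in [0,1])
    width: int = 240
    height: int = 400
    _margin: int = 30

    def band_y(self, length_nt: float) -> float:
        """Vertical pixel position of a band (larger y = migrated farther)."""
        lo, hi = np.log(self.ladder[0]), np.log(self.ladder[-1])
        frac = (np.log(length_nt) - lo) / (hi - lo)  # 0 at 100 nt .. 1 at 1000 nt
        usable = self.height - 2 * self._margin
        return self._margin + (1.0 - frac) * usable

    def to_image(self) -> Image.Image:
        img = Image.new("L", (self.width, self.height), color=0)
        draw = ImageDraw.Draw(img)
        lane_w = self.width // 2 - 20
        ladder_x = (10, 10 + lane_w)
        sample_x = (self.width // 2 + 10, self.width // 2 + 10 + lane_w)
        for length in self.ladder:
            y = self.band_y(length)
            draw.rectangle([ladder_x[0], y - 2, ladder_x[1], y + 2], fill=180)
        for length, intensity in self.sample_bands:
            y = self.band_y(length)
            fill = int(round(80 + 175 * min(max(intensity, 0.0), 1.0)))
            draw.rectangle([sample_x[0], y - 2, sample_x[1], y + 2], fill=fill)
        return img

    def save(self, path) -> None:
        self.to_image().save(path)


def simulated_gel(
    census: AmpliconCensus,
    geometry: AssayGeometry,
    ladder: Sequence[int] = DEFAULT_LADDER,
    *,
    max_length: int = 1000,
) -> GelImage:
    """Build the simulated gel from a census.

    Only amplicons with lengths between the smallest ladder rung and
    ``max_length`` nt are banded (the experimental ladder spans 100-1000 bp);
    a census with no such amplicon yields an empty sample lane.
    """
    ladder = tuple(ladder)
    if list(ladder) != sorted(ladder) or len(ladder) < 2:
        raise ValueError("ladder must be an ascending list of at least two lengths")
    by_length = census.by_length(geometry)
    in_range = {
        length: copies
        for length, copies in by_length.items()
        if ladder[0] <= length <= max_length
    }
    bands: list[tuple[int, float]] = []
    if in_range:
        masses = {length: copies * length for length, copies in in_range.items()}
        peak = max(masses.values())
        bands = [
            (length, mass / peak) for length, mass in sorted(masses.items())
        ]
    return GelImage(ladder=ladder, sample_bands=bands)
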