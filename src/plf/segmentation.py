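"""Fixed-size segmentation of protein primary structures and count aggregation.

A protein of length L is tiled into ceil(L / nominal_size) consecutive
segments of ``nominal_size`` residues (default 50); the final segment keeps
whatever remainder is left (1..nominal_size residues) and is never merged
into its neighbour — C-terminal resolution is where propeptide signals live.

A peptide contributes its *full* spectral count to every segment its
coordinates overlap: a peptide spanning two adjoining segments is counted
in both, so the grid total may exceed the raw count total. That double
counting is intentional and is what makes segment profiles continuous
across tile boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import DesignError, SegmentationError
from .io import LocatedPeptide, ProteinEntry


class Segment(NamedTuple):
    """One tile of a protein: 1-based ordinal and inclusive residue range."""

    index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class SampleKey(NamedTuple):
    """Identity of one biological replicate within a region's design."""

    sample_id: str
    group: str


def segment_boundaries(protein_length: int, nominal_size: int = 50) -> list[Segment]:
    """Tile a protein of ``protein_length`` residues into fixed-size segments."""
    if protein_length < 1:
        raise SegmentationError(f"protein_length must be >= 1, got {protein_length}")
    if nominal_size < 1:
        raise SegmentationError(f"nominal_size must be >= 1, got {nominal_size}")
    segments = []
    for i, start in enumerate(range(1, protein_length + 1, nominal_size), start=1):
        end = min(start + nominal_size - 1, protein_length)
        segments.append(Segment(index=i, start=start, end=end))
    return segments


def map_peptide_to_segments(
    start: int, end: int, protein_length: int, nominal_size: int = 50
) -> set[int]:
    """Indices of every segment whose residue range intersects [start, end].

    A peptide spanning adjoining segments belongs to all of them; a peptide
    long enough to overlap more than two segments is counted in each.
    """
    if not (1 <= start <= end <= protein_length):
        raise SegmentationError(
            f"peptide interval ({start}, {end}) outside protein of "
            f"length {protein_length}"
        )
    first = (start - 1) // nominal_size + 1
    last = (end - 1) // nominal_size + 1
    return set(range(first, last + 1))


@dataclass
class SegmentCountMatrix:
    """Per (protein, region): samples x segments grid of summed spectral counts."""

    accession: str
    region: str
    segments: list[Segment]
    samples: list[SampleKey]
    counts: np.ndarray  # shape (n_samples, n_segments), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.segments)):
            raise SegmentationError(
                f"{self.accession}: counts shape {self.counts.shape} does not "
                f"match {len(self.samples)} samples x {len(self.segments)} segments"
            )
        if (self.counts < 0).any():
            raise SegmentationError(f"{self.accession}: negative counts")


def infer_design(
    located: Iterable[LocatedPeptide],
) -> dict[str, list[SampleKey]]:
    """Recover the per-region sample design from the peptide records.

    Raises :class:`DesignError` when one sample id appears under two groups
    within a region.
    """
    design: dict[str, dict[str, str]] = {}
    for pep in located:
        reg = design.setdefault(pep.region, {})
        prev = reg.get(pep.sample_id)
        if prev is None:
            reg[pep.sample_id] = pep.group
        elif prev != pep.group:
            raise DesignError(
                f"sample {pep.sample_id!r} appears as both {prev!r} and "
                f"{pep.group!r} in region {pep.region!r}"
            )
    return {
        region: sorted(SampleKey(s, g) for s, g in samples.items())
        for region, samples in design.items()
    }


def build_segment_counts(
    located: Iterable[LocatedPeptide],
    proteins: Mapping[str, ProteinEntry],
    nominal_size: int = 50,
    design: Mapping[str, Sequence[SampleKey]] | None = None,
) -> dict[tuple[str, str], SegmentCountMatrix]:
    """Aggregate located peptides into per-(protein, region) count matrices.

    Each tissue region is an independent analysis unit. Every sample the
    design declares for a region appears as a row even when it contributed
    no peptides to a protein (an all-zero row); by default the design is
    inferred from the records themselves.
    """
    located = list(located)
    if design is None:
        design = infer_design(located)
    else:
        infer_design(located)  # still validate metadata consistency
    row_of = {
        region: {key: i for i, key in enumerate(samples)}
        for region, samples in design.items()
    }

    matrices: dict[tuple[str, str], np.ndarray] = {}
    for pep in located:
        prot = proteins[pep.accession]
        key = (pep.accession, pep.region)
        grid = matrices.get(key)
        if grid is None:
            n_seg = (prot.length + nominal_size - 1) // nominal_size
            grid = np.zeros((len(design[pep.region]), n_seg), dtype=np.int64)
            matrices[key] = grid
        row = row_of[pep.region].get(SampleKey(pep.sample_id, pep.group))
        if row is None:
            raise DesignError(
                f"sample {pep.sample_id!r} ({pep.group}) not declared in the "
                f"design for region {pep.region!r}"
            )
        first = (pep.start - 1) // nominal_size
        last = (pep.end - 1) // nominal_size
        grid[row, first : last + 1] += pep.spectral_count

    return {
        (acc, region): SegmentCountMatrix(
            accession=acc,
            region=region,
            segments=segment_boundaries(proteins[acc].length, nominal_size),
            samples=list(design[region]),
            counts=grid,
        )
        for (acc, region), grid in matrices.items()
    }
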