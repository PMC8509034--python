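"""Cross-region set comparison of flagged proteins.

After the per-region analyses, the flagged-protein sets are intersected to
separate structure-change signals shared across tissue regions (candidate
tissue-wide ageing mechanisms) from region-exclusive ones (candidate local
mechanisms), and compared against an abundance-based significant list to
isolate proteins whose structure changed without an abundance change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import AbstractSet, Iterable, Mapping

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionSets:
    """Per-region flagged-accession sets with the derived Venn structure."""

    flagged: dict[str, frozenset[str]]

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.flagged)

    @property
    def union(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.flagged.values():
            out |= s
        return out

    @property
    def intersection(self) -> frozenset[str]:
        sets = list(self.flagged.values())
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return out

    def exclusive(self, region: str) -> frozenset[str]:
        """Accessions flagged in ``region`` and nowhere else."""
        others: frozenset[str] = frozenset()
        for r, s in self.flagged.items():
            if r != region:
                others |= s
        return self.flagged[region] - others

    def venn_cells(self) -> dict[frozenset[str], frozenset[str]]:
        """Every non-empty combination of regions -> accessions exactly there.

        The 2^k − 1 cells partition the union: each accession appears in
        exactly the cell named by the full set of regions that flagged it.
        """
        cells: dict[frozenset[str], frozenset[str]] = {}
        regions = list(self.flagged)
        for k in range(1, len(regions) + 1):
            for combo in combinations(regions, k):
                inside: frozenset[str] = self.flagged[combo[0]]
                for r in combo[1:]:
                    inside &= self.flagged[r]
                for r in regions:
                    if r not in combo:
                        inside -= self.flagged[r]
                cells[frozenset(combo)] = inside
        return cells


def intersect_regions(flagged: Mapping[str, Iterable[str]]) -> RegionSets:
    """Build the full Venn structure over per-region flagged sets."""
    if len(flagged) < 2:
        raise ValueError("region comparison requires >= 2 regions")
    return RegionSets(flagged={r: frozenset(s) for r, s in flagged.items()})


def plf_unique(
    plf_union: AbstractSet[str], abundance_significant: AbstractSet[str]
) -> frozenset[str]:
    """Proteins flagged by location fingerprinting but not by abundance.

    These are the candidates whose structure changed while whole-protein
    abundance did not — the signal unique to this methodology. Warns when
    the two lists share no accession at all, which usually means mismatched
    identifier schemes.
    """
    plf_union = frozenset(plf_union)
    abundance_significant = frozenset(abundance_significant)
    if plf_union and abundance_significant and not (plf_union & abundance_significant):
        logger.warning(
            "no overlap between fingerprinting and abundance accessions; "
            "check that both lists use the same identifier scheme"
        )
    return plf_union - abundance_significant
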