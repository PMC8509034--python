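"""Input readers and peptide-to-protein location.

The pipeline consumes two kinds of input: protein sequences (FASTA) and
per-sample peptide lists of the kind exported from PSM-scoring software
(delimited text with one row per identified peptide per sample, carrying a
spectral count and optionally an identification probability).

Conventions fixed here and used everywhere downstream:

* residue coordinates are 1-based and inclusive at both ends;
* sequences are compared case-insensitively (stored upper-case);
* isoleucine and leucine are distinct — peptide lists come from database
  search and are sequence-exact.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import (
    AmbiguousPeptideError,
    DuplicateAccessionError,
    FastaError,
    InvalidSequenceError,
    PeptideNotFoundError,
    PeptideTableError,
    UnknownGroupError,
    UnknownProteinError,
)

logger = logging.getLogger(__name__)

#: the two study groups; group labels in peptide tables must normalise to one of these
GROUPS = ("young", "aged")

#: 20 standard residues plus ambiguity codes B, Z, X and the rare U, O
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXUO")

REQUIRED_COLUMNS = ("sample_id", "group", "region", "accession", "peptide_seq", "spectral_count")

# bracketed modification annotations, e.g. "M[+15.99]" or "C(+58)"
_MOD_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)")
# Scaffold-style flanking-residue notation "K.PEPTIDER.A"
_FLANK_RE = re.compile(r"^[A-Z-]\.([A-Za-z.\[\]()+\-0-9]+)\.[A-Z-]$")


@dataclass(frozen=True)
class ProteinEntry:
    """A protein accession plus its amino-acid sequence.

    The sequence is the coordinate frame for every downstream step.
    """

    accession: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise InvalidSequenceError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise InvalidSequenceError(
                f"{self.accession}: invalid residue(s) {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide in one sample, with its spectral count."""

    sample_id: str
    group: str
    region: str
    accession: str
    peptide_seq: str
    spectral_count: int
    probability: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise UnknownGroupError(f"group {self.group!r} not in {GROUPS}")
        if self.spectral_count < 0:
            raise PeptideTableError(
                f"negative spectral count {self.spectral_count} for {self.peptide_seq}"
            )
        if len(self.peptide_seq) < 1:
            raise PeptideTableError("empty peptide sequence")


@dataclass(frozen=True)
class LocatedPeptide:
    """A peptide record placed at residue coordinates within its parent protein.

    ``start``/``end`` are 1-based inclusive; the protein subsequence at
    [start, end] equals ``peptide_seq`` exactly.
    """

    sample_id: str
    group: str
    region: str
    accession: str
    peptide_seq: str
    spectral_count: int
    start: int
    end: int
    probability: float | None = None


def _parse_accession(header: str) -> str:
    """First whitespace token; UniProt ``db|ACC|name`` headers reduce to ACC."""
    token = header.split()[0]
    if "|" in token:
        parts = token.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return token


def read_fasta(path: str | Path) -> dict[str, ProteinEntry]:
    """Read a multi-record FASTA into an ordered accession -> ProteinEntry map.

    Raises
    ------
    FastaError
        Empty file / no records.
    DuplicateAccessionError
        Two records reduce to the same accession.
    InvalidSequenceError
        A sequence holds characters outside the amino-acid alphabet.
    """
    path = Path(path)
    proteins: dict[str, ProteinEntry] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _parse_accession(rec.description or rec.id)
        if acc in proteins:
            raise DuplicateAccessionError(f"duplicate accession {acc!r} in {path}")
        proteins[acc] = ProteinEntry(accession=acc, sequence=str(rec.seq).upper())
    if not proteins:
        raise FastaError(f"no FASTA records found in {path}")
    return proteins


def clean_peptide_sequence(raw: str) -> str:
    """Strip modification tags and flanking-residue notation, upper-case.

    ``"K.AM[+16]YR.S"`` -> ``"AMYR"``. The search-engine modification set is
    fixed upstream, so tags carry no information for location fingerprinting.
    """
    s = raw.strip()
    m = _FLANK_RE.match(s)
    if m:
        s = m.group(1)
    s = _MOD_RE.sub("", s)
    return s.upper()


def _sniff_delimiter(header_line: str) -> str:
    try:
        return csv.Sniffer().sniff(header_line, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in header_line else ","


def read_peptide_table(
    path: str | Path, min_probability: float = 0.95
) -> list[PeptideRecord]:
    """Read a delimited peptide list and apply the probability filter.

    Rows whose identification probability falls below ``min_probability``
    (default 0.95) are dropped; rows without a probability value are kept —
    that filter is then assumed already applied upstream. Group and region
    labels are normalised to lower case; spectral counts must parse as
    non-negative integers.
    """
    path = Path(path)
    if not 0.0 <= min_probability <= 1.0:
        raise PeptideTableError(f"min_probability {min_probability} outside [0, 1]")
    with open(path, "r", newline="") as fh:
        header_line = fh.readline()
    delim = _sniff_delimiter(header_line)
    df = pd.read_csv(path, sep=delim, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PeptideTableError(f"{path}: missing required column(s) {missing}")

    has_prob = "probability" in df.columns
    records: list[PeptideRecord] = []
    for row in df.itertuples(index=False):
        raw_count = str(getattr(row, "spectral_count")).strip()
        try:
            count = int(raw_count)
        except ValueError:
            raise PeptideTableError(
                f"{path}: non-integer spectral count {raw_count!r}"
            ) from None
        prob: float | None = None
        if has_prob:
            raw_prob = getattr(row, "probability")
            if raw_prob is not None and str(raw_prob).strip() not in ("", "nan"):
                prob = float(raw_prob)
                # percent-style probabilities ("95") normalise to fractions
                if prob > 1.0:
                    prob = prob / 100.0
                if prob < min_probability:
                    continue
        records.append(
            PeptideRecord(
                sample_id=str(getattr(row, "sample_id")).strip(),
                group=str(getattr(row, "group")).strip().lower(),
                region=str(getattr(row, "region")).strip().lower(),
                accession=str(getattr(row, "accession")).strip(),
                peptide_seq=clean_peptide_sequence(str(getattr(row, "peptide_seq"))),
                spectral_count=count,
                probability=prob,
            )
        )
    return records


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All 0-based start offsets of needle in haystack (overlaps allowed)."""
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def locate_peptides(
    records: Iterable[PeptideRecord],
    proteins: Mapping[str, ProteinEntry],
    occurrence_policy: str = "first",
) -> list[LocatedPeptide]:
    """Place each peptide at residue coordinates within its parent protein.

    ``occurrence_policy`` handles peptides that occur more than once in the
    parent sequence:

    * ``"first"`` (default) — lowest start index, with a logged warning;
      upstream exclusivity filtering makes multiplicity rare, and counting
      every occurrence would double-count spectra;
    * ``"all"`` — one located peptide per occurrence, each carrying the full
      spectral count;
    * ``"error"`` — reject the record.
    """
    if occurrence_policy not in ("first", "all", "error"):
        raise ValueError(f"unknown occurrence_policy {occurrence_policy!r}")
    located: list[LocatedPeptide] = []
    for rec in records:
        prot = proteins.get(rec.accession)
        if prot is None:
            raise UnknownProteinError(
                f"accession {rec.accession!r} not present in the protein FASTA"
            )
        hits = _occurrences(prot.sequence, rec.peptide_seq)
        if not hits:
            raise PeptideNotFoundError(
                f"peptide {rec.peptide_seq!r} not found in protein {rec.accession!r}"
            )
        if len(hits) > 1:
            if occurrence_policy == "error":
                raise AmbiguousPeptideError(
                    f"peptide {rec.peptide_seq!r} occurs {len(hits)} times "
                    f"in {rec.accession!r}"
                )
            if occurrence_policy == "first":
                logger.warning(
                    "peptide %s occurs %d times in %s; using first occurrence",
                    rec.peptide_seq,
                    len(hits),
                    rec.accession,
                )
                hits = hits[:1]
        else:
            hits = hits[:1] if occurrence_policy != "all" else hits
        for off in hits:
            located.append(
                LocatedPeptide(
                    sample_id=rec.sample_id,
                    group=rec.group,
                    region=rec.region,
                    accession=rec.accession,
                    peptide_seq=rec.peptide_seq,
                    spectral_count=rec.spectral_count,
                    start=off + 1,
                    end=off + len(rec.peptide_seq),
                    probability=rec.probability,
                )
            )
    return located
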