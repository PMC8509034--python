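"""Synthetic study generator with the statistical structure the pipeline assumes.

The generator emulates what a PSM-scoring export from a two-group,
multi-region spectral-counting experiment looks like:

* a proteome of random sequences with realistic tryptic-site density
  (or a user-supplied FASTA);
* in-silico tryptic digestion (cleave after K/R unless followed by P, up
  to ``missed_cleavage_max`` missed cleavages, default 2) filtered to a
  detectability length window (default 7–35 residues);
* a fixed per-peptide detectability weight (seeded uniform draw) creating
  uneven coverage along each protein, with whole-protein abundance
  log-normal across proteins;
* non-negative integer spectral counts drawn negative-binomially, so
  replicate noise is overdispersed relative to Poisson;
* implanted effects: multiplicative fold changes on the expected counts of
  every peptide overlapping a designated residue interval, applied to one
  group (optionally restricted to specific tissue regions) — the synthetic
  analogue of a localized structural difference that blocks or enhances
  peptide release.

The same seed and spec always reproduce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import SimulationError
from .io import GROUPS, ProteinEntry
from .segmentation import SampleKey

#: residue alphabet used by the random proteome (standard 20, no ambiguity codes)
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class DigestPeptide(NamedTuple):
    """An in-silico tryptic product with 1-based inclusive coordinates."""

    seq: str
    start: int
    end: int
    missed: int


def cleavage_sites(sequence: str) -> list[int]:
    """0-based offsets *after* which trypsin cuts (K/R not followed by P)."""
    sites = []
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == n or sequence[i + 1] != "P"):
            sites.append(i)
    return sites


def digest(
    protein: ProteinEntry | str,
    missed_cleavage_max: int = 2,
    length_window: tuple[int, int] = (7, 35),
) -> list[DigestPeptide]:
    """Enumerate tryptic peptides with up to ``missed_cleavage_max`` missed cuts.

    Fully-cleaved fragments are the stretches between consecutive cleavage
    sites; a product with k missed cleavages joins k+1 consecutive
    fragments. Products outside ``length_window`` are discarded.
    """
    seq = protein.sequence if isinstance(protein, ProteinEntry) else str(protein).upper()
    lo, hi = length_window
    # fragment boundaries: starts of fully-cleaved fragments, 0-based
    cut_after = cleavage_sites(seq)
    starts = [0] + [i + 1 for i in cut_after if i + 1 < len(seq)]
    ends = [s - 1 for s in starts[1:]] + [len(seq) - 1]

    peptides: list[DigestPeptide] = []
    n_frag = len(starts)
    for i in range(n_frag):
        for mc in range(missed_cleavage_max + 1):
            j = i + mc
            if j >= n_frag:
                break
            s, e = starts[i], ends[j]
            if lo <= e - s + 1 <= hi:
                peptides.append(DigestPeptide(seq[s : e + 1], s + 1, e + 1, mc))
    return peptides


@dataclass(frozen=True)
class Effect:
    """A localized, group-specific perturbation of expected peptide yield.

    Every peptide overlapping [start, end] in ``accession`` has its expected
    count multiplied by ``fold_change`` in samples of ``group`` — wholesale,
    with no partial-overlap proration, mirroring how a structural
    modification blocks (fold < 1) or enhances (fold > 1) release of the
    whole peptide. ``regions=None`` applies the effect in every tissue
    region; a tuple of region labels restricts it.
    """

    accession: str
    start: int
    end: int
    group: str
    fold_change: float
    regions: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.fold_change < 0:
            raise SimulationError(f"fold_change must be >= 0, got {self.fold_change}")
        if self.group not in GROUPS:
            raise SimulationError(f"effect group {self.group!r} not in {GROUPS}")
        if not (1 <= self.start <= self.end):
            raise SimulationError(f"bad effect interval ({self.start}, {self.end})")


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Full parameterization of a synthetic study; seed determines everything.

    Defaults emulate the study design the pipeline targets: two groups
    (young vs aged), three intervertebral-disc regions, three biological
    replicates per group per region (``replicate_overrides`` can reduce one
    region to 3 vs 2), whole-protein totals log-normal across proteins with
    a median of ~800 spectra, and negative-binomial replicate noise whose
    dispersion gives individual peptide counts a CV of roughly 20% at
    typical per-peptide means.
    """

    proteome: tuple[ProteinEntry, ...] | None = None
    n_proteins: int = 50
    length_range: tuple[int, int] = (300, 900)
    regions: tuple[str, ...] = ("posterior", "left_lateral", "anterior")
    n_replicates: Mapping[str, int] = field(
        default_factory=lambda: {"young": 3, "aged": 3}
    )
    replicate_overrides: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    baseline_log_mean: float = float(np.log(800.0))
    baseline_log_sd: float = 0.6
    detect_prob: float = 0.7
    length_window: tuple[int, int] = (7, 35)
    missed_cleavage_max: int = 2
    dispersion: float = 150.0
    effects: tuple[Effect, ...] = ()
    seed: int = 0

    def replicates(self, region: str, group: str) -> int:
        override = self.replicate_overrides.get(region, {})
        return int(override.get(group, self.n_replicates[group]))


@dataclass
class SimulatedStudy:
    """Everything one seeded run produced, in the formats the pipeline reads."""

    proteins: dict[str, ProteinEntry]
    table: pd.DataFrame  # io_model peptide-table schema, all regions
    design: dict[str, list[SampleKey]]
    effects: pd.DataFrame  # ground truth, one row per implanted effect

    def region_table(self, region: str) -> pd.DataFrame:
        return self.table[self.table["region"] == region].reset_index(drop=True)

    def records(self) -> list:
        """The peptide table as validated :class:`~plf.io.PeptideRecord` objects."""
        from .io import PeptideRecord

        return [
            PeptideRecord(
                sample_id=r.sample_id,
                group=r.group,
                region=r.region,
                accession=r.accession,
                peptide_seq=r.peptide_seq,
                spectral_count=int(r.spectral_count),
                probability=float(r.probability),
            )
            for r in self.table.itertuples(index=False)
        ]


def random_proteome(
    n_proteins: int,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (300, 900),
    kr_fraction: float = 0.11,
) -> list[ProteinEntry]:
    """Random sequences with K/R frequency ~11% so tryptic products are realistic."""
    probs = np.empty(len(_RESIDUES))
    kr = {i for i, aa in enumerate(_RESIDUES) if aa in "KR"}
    p_idx = _RESIDUES.index("P")
    probs[:] = (1.0 - kr_fraction - 0.05) / (len(_RESIDUES) - 3)
    for i in kr:
        probs[i] = kr_fraction / 2.0
    probs[p_idx] = 0.05  # proline suppresses adjacent cleavage; keep it realistic
    probs /= probs.sum()
    letters = np.array(list(_RESIDUES))
    proteome = []
    lo, hi = length_range
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(letters[rng.choice(len(letters), size=length, p=probs)])
        proteome.append(ProteinEntry(accession=f"SYN{i + 1:04d}", sequence=seq))
    return proteome


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with mean mu and var mu + mu^2/dispersion."""
    mu = np.asarray(mu, dtype=float)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def simulate_counts(spec: SyntheticStudySpec) -> SimulatedStudy:
    """Generate the peptide tables, FASTA-ready proteome and ground truth.

    For each (region, group, replicate, protein, detected peptide) the
    expected count is ``baseline_total(protein) × detectability_weight ×
    Π fold_change`` over matching effects, and the observed count is a
    negative-binomial draw. Rows with a zero count are omitted (an
    undetected peptide never appears in a PSM export).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.proteome is not None:
        proteome = list(spec.proteome)
    else:
        proteome = random_proteome(spec.n_proteins, rng, spec.length_range)
    proteins = {p.accession: p for p in proteome}

    for eff in spec.effects:
        if eff.accession not in proteins:
            raise SimulationError(f"effect references unknown accession {eff.accession!r}")
        if eff.end > proteins[eff.accession].length:
            raise SimulationError(
                f"effect interval ({eff.start}, {eff.end}) outside "
                f"{eff.accession} (length {proteins[eff.accession].length})"
            )

    design: dict[str, list[SampleKey]] = {
        region: [
            SampleKey(f"{group}_d{i + 1}", group)
            for group in GROUPS
            for i in range(spec.replicates(region, group))
        ]
        for region in spec.regions
    }

    effects_by_acc: dict[str, list[Effect]] = {}
    for eff in spec.effects:
        effects_by_acc.setdefault(eff.accession, []).append(eff)

    columns: dict[str, list] = {
        "sample_id": [],
        "group": [],
        "region": [],
        "accession": [],
        "peptide_seq": [],
        "spectral_count": [],
        "probability": [],
    }

    for prot in proteome:
        peptides = digest(prot, spec.missed_cleavage_max, spec.length_window)
        if not peptides:
            continue
        detected = rng.random(len(peptides)) < spec.detect_prob
        weights_raw = rng.random(len(peptides))
        if not detected.any():
            continue
        peptides = [p for p, d in zip(peptides, detected) if d]
        w = weights_raw[detected]
        w = w / w.sum()
        baseline_total = float(
            rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd)
        )
        mu0 = baseline_total * w  # expected count per peptide, no effects

        prot_effects = effects_by_acc.get(prot.accession, [])
        for region in spec.regions:
            for group in GROUPS:
                fold = np.ones(len(peptides))
                for eff in prot_effects:
                    if eff.group != group:
                        continue
                    if eff.regions is not None and region not in eff.regions:
                        continue
                    overlap = np.array(
                        [p.start <= eff.end and p.end >= eff.start for p in peptides]
                    )
                    fold = np.where(overlap, fold * eff.fold_change, fold)
                mu = mu0 * fold
                n_rep = spec.replicates(region, group)
                counts = _nb_counts(
                    rng, np.broadcast_to(mu, (n_rep, len(peptides))), spec.dispersion
                )
                probs = np.round(0.95 + 0.05 * rng.random(counts.shape), 4)
                for i in range(n_rep):
                    nz = np.nonzero(counts[i])[0]
                    columns["sample_id"].extend([f"{group}_d{i + 1}"] * len(nz))
                    columns["group"].extend([group] * len(nz))
                    columns["region"].extend([region] * len(nz))
                    columns["accession"].extend([prot.accession] * len(nz))
                    columns["peptide_seq"].extend(peptides[j].seq for j in nz)
                    columns["spectral_count"].extend(int(c) for c in counts[i, nz])
                    columns["probability"].extend(float(p) for p in probs[i, nz])

    table = pd.DataFrame(columns)
    effects_df = pd.DataFrame(
        [
            {
                "accession": e.accession,
                "start": e.start,
                "end": e.end,
                "group": e.group,
                "fold_change": e.fold_change,
                "regions": "all" if e.regions is None else ";".join(e.regions),
            }
            for e in spec.effects
        ],
        columns=["accession", "start", "end", "group", "fold_change", "regions"],
    )
    return SimulatedStudy(
        proteins=proteins, table=table, design=design, effects=effects_df
    )


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + one peptide table per region + ground truth + design."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = out_dir / "proteome.fasta"
    with open(fasta, "w") as fh:
        for prot in study.proteins.values():
            fh.write(f">{prot.accession}\n")
            for i in range(0, prot.length, 60):
                fh.write(prot.sequence[i : i + 60] + "\n")
    paths["fasta"] = fasta

    for region in study.table["region"].unique():
        p = out_dir / f"peptides_{region}.csv"
        study.region_table(region).to_csv(p, index=False)
        paths[f"peptides_{region}"] = p

    eff = out_dir / "true_effects.csv"
    study.effects.to_csv(eff, index=False)
    paths["effects"] = eff

    design = out_dir / "design.csv"
    pd.DataFrame(
        [
            {"region": region, "sample_id": s.sample_id, "group": s.group}
            for region, samples in study.design.items()
            for s in samples
        ]
    ).to_csv(design, index=False)
    paths["design"] = design
    return paths


def showcase_spec(seed: int = 0, n_proteins: int = 60) -> SyntheticStudySpec:
    """A three-region scenario with shared, region-specific and abundance-only effects.

    Implants (deterministic given ``seed``):

    * 6 proteins with a 4-fold suppression of aged peptide yield over a
      100-residue interval in *all* regions (tissue-wide structural change);
    * 6 proteins with the same perturbation confined to a single region
      (two per region — local structural change);
    * 5 proteins with a uniform 3-fold whole-protein abundance increase in
      aged (no localized change; fingerprinting should stay silent).

    The remaining proteins carry no effect.
    """
    if n_proteins < 20:
        raise SimulationError(
            "the showcase scenario implants 17 effects and needs >= 20 proteins"
        )
    rng = np.random.default_rng(seed)
    proteome = random_proteome(n_proteins, rng, (300, 900))
    regions = ("posterior", "left_lateral", "anterior")

    def interval(prot: ProteinEntry, span: int = 100) -> tuple[int, int]:
        # align to a 50-residue boundary so the effect covers whole segments
        n_slots = max(1, (prot.length - span) // 50)
        start = 1 + 50 * int(rng.integers(0, n_slots))
        return start, start + span - 1

    effects: list[Effect] = []
    idx = 0
    for _ in range(6):  # shared across all regions
        prot = proteome[idx]
        s, e = interval(prot)
        effects.append(Effect(prot.accession, s, e, "aged", 0.25))
        idx += 1
    for region in regions:  # two region-specific each
        for _ in range(2):
            prot = proteome[idx]
            s, e = interval(prot)
            effects.append(Effect(prot.accession, s, e, "aged", 0.25, regions=(region,)))
            idx += 1
    for _ in range(5):  # whole-protein abundance shift only
        prot = proteome[idx]
        effects.append(Effect(prot.accession, 1, prot.length, "aged", 3.0))
        idx += 1

    return SyntheticStudySpec(
        proteome=tuple(proteome),
        regions=regions,
        replicate_overrides={"posterior": {"aged": 2}},
        effects=tuple(effects),
        seed=seed + 1,  # generation noise independent of proteome draw
    )
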