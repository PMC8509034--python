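"""End-to-end orchestration of the multi-region young-vs-aged analysis.

The in-memory entry points are :func:`analyze_region` and
:func:`analyze_study`; :func:`run_plf` is the disk-facing wrapper that
reads a config, runs the analysis and writes the delimited result bundle
plus a manifest. Everything is deterministic given the inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .io import (
    LocatedPeptide,
    PeptideRecord,
    ProteinEntry,
    locate_peptides,
    read_fasta,
    read_peptide_table,
)
from .regions import RegionSets, intersect_regions, plf_unique
from .segmentation import SampleKey, build_segment_counts
from .stats import (
    DifferenceProfile,
    FLAG_ALPHA,
    GroupSummary,
    SegmentTestResult,
    composite_scale,
    difference_profile,
    flag_significant_proteins,
    group_average,
    normalize_matrix,
    test_segments,
)

logger = logging.getLogger(__name__)

#: machine-readable reasons a protein is excluded from testing in a region
EXCLUDE_UNDETECTED = "undetected"
EXCLUDE_ONE_GROUP = "one_group_only"
EXCLUDE_SINGLE_SAMPLE = "single_sample_group"


@dataclass
class RunConfig:
    """Parameters of one analysis run; defaults match the study protocol.

    50-residue segments, a 95% minimum identification probability and the
    0.05/0.01/0.001 star thresholds are the protocol's stated values.
    """

    fasta: str
    peptide_tables: tuple[str, ...]
    out_dir: str
    nominal_size: int = 50
    min_probability: float = 0.95
    alpha: float = FLAG_ALPHA
    tail_mode: str = "actual"  # "actual" | "nominal"
    occurrence_policy: str = "first"
    abundance_list: str | None = None
    annotation_table: str | None = None

    def validate(self) -> None:
        if not Path(self.fasta).is_file():
            raise ConfigError(f"FASTA not found: {self.fasta}")
        for t in self.peptide_tables:
            if not Path(t).is_file():
                raise ConfigError(f"peptide table not found: {t}")
        if self.nominal_size < 1:
            raise ConfigError(f"nominal_size must be >= 1, got {self.nominal_size}")
        if not 0.0 <= self.min_probability <= 1.0:
            raise ConfigError("min_probability must lie in [0, 1]")
        if self.tail_mode not in ("actual", "nominal"):
            raise ConfigError(f"unknown tail_mode {self.tail_mode!r}")
        if self.occurrence_policy not in ("first", "all", "error"):
            raise ConfigError(f"unknown occurrence_policy {self.occurrence_policy!r}")


@dataclass
class RegionResult:
    """Everything the analysis produced for one tissue region."""

    region: str
    tests: dict[str, list[SegmentTestResult]]
    summaries: dict[str, GroupSummary]
    profiles: dict[str, DifferenceProfile]
    exclusions: dict[str, str]  # accession -> reason code
    flagged: frozenset[str]


@dataclass
class StudyResult:
    """Per-region results plus the cross-region set comparison."""

    regions: dict[str, RegionResult]
    region_sets: RegionSets | None
    composite: dict[str, dict[str, np.ndarray]]  # accession -> region -> scaled profile

    @property
    def flagged_union(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for r in self.regions.values():
            out |= r.flagged
        return out


def analyze_region(
    located: Sequence[LocatedPeptide],
    proteins: Mapping[str, ProteinEntry],
    region: str,
    design: Mapping[str, Sequence[SampleKey]] | None = None,
    nominal_size: int = 50,
    tail_mode: str = "actual",
    alpha: float = FLAG_ALPHA,
) -> RegionResult:
    """Run the full per-region fingerprinting analysis.

    Produces per-segment test results, difference profiles and the flagged
    set for one tissue region, recording every excluded protein with a
    reason code (undetected / present in one group only / a group reduced
    to a single sample).
    """
    region_peps = [p for p in located if p.region == region]
    matrices = build_segment_counts(
        region_peps, proteins, nominal_size=nominal_size, design=design
    )
    tests: dict[str, list[SegmentTestResult]] = {}
    summaries: dict[str, GroupSummary] = {}
    profiles: dict[str, DifferenceProfile] = {}
    exclusions: dict[str, str] = {}

    for (acc, _), matrix in sorted(matrices.items()):
        nm = normalize_matrix(matrix)
        if not nm.samples:
            exclusions[acc] = EXCLUDE_UNDETECTED
            continue
        summary = group_average(nm)
        if summary is None:
            exclusions[acc] = EXCLUDE_ONE_GROUP
            continue
        summaries[acc] = summary
        profiles[acc] = difference_profile(summary, tail_mode, nominal_size)
        if not summary.testable:
            exclusions[acc] = EXCLUDE_SINGLE_SAMPLE
            logger.warning(
                "%s/%s: a group retains a single sample; difference profile "
                "kept but protein is untestable",
                acc,
                region,
            )
            continue
        tests[acc] = test_segments(nm)

    all_results = [r for rs in tests.values() for r in rs]
    flagged = frozenset(flag_significant_proteins(all_results, alpha))
    return RegionResult(
        region=region,
        tests=tests,
        summaries=summaries,
        profiles=profiles,
        exclusions=exclusions,
        flagged=flagged,
    )


def analyze_study(
    proteins: Mapping[str, ProteinEntry],
    records: Iterable[PeptideRecord],
    design: Mapping[str, Sequence[SampleKey]] | None = None,
    nominal_size: int = 50,
    tail_mode: str = "actual",
    occurrence_policy: str = "first",
    alpha: float = FLAG_ALPHA,
) -> StudyResult:
    """Locate peptides, analyse every region, and intersect the flagged sets.

    Composite (cross-region, max-|value|-scaled) difference profiles are
    produced for every protein profiled in at least two regions.
    """
    located = locate_peptides(records, proteins, occurrence_policy)
    region_labels = sorted({p.region for p in located})
    results = {
        region: analyze_region(
            located,
            proteins,
            region,
            design={region: design[region]} if design else None,
            nominal_size=nominal_size,
            tail_mode=tail_mode,
            alpha=alpha,
        )
        for region in region_labels
    }
    region_sets = (
        intersect_regions({r: res.flagged for r, res in results.items()})
        if len(results) >= 2
        else None
    )

    composite: dict[str, dict[str, np.ndarray]] = {}
    accs = sorted({acc for res in results.values() for acc in res.profiles})
    for acc in accs:
        per_region = {
            region: res.profiles[acc]
            for region, res in results.items()
            if acc in res.profiles
        }
        if len(per_region) >= 2:
            composite[acc] = composite_scale(per_region)

    return StudyResult(regions=results, region_sets=region_sets, composite=composite)


# ---------------------------------------------------------------------------
# disk-facing runner


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _segment_table(result: RegionResult) -> pd.DataFrame:
    rows = []
    for acc in sorted(result.profiles):
        profile = result.profiles[acc]
        tested = {r.segment.index: r for r in result.tests.get(acc, [])}
        for j, seg in enumerate(profile.segments):
            r = tested.get(seg.index)
            rows.append(
                {
                    "accession": acc,
                    "segment": seg.index,
                    "start": seg.start,
                    "end": seg.end,
                    "mean_young": r.mean_young if r else result.summaries[acc].mean_young[j],
                    "mean_aged": r.mean_aged if r else result.summaries[acc].mean_aged[j],
                    "sd_young": r.sd_young if r else np.nan,
                    "sd_aged": r.sd_aged if r else np.nan,
                    "raw_p": r.raw_p if r else np.nan,
                    "corrected_p": r.corrected_p if r else np.nan,
                    "stars": r.stars if r else "",
                    "difference": profile.values[j],
                }
            )
    return pd.DataFrame(rows)


def _protein_table(result: RegionResult, alpha: float) -> pd.DataFrame:
    rows = []
    accs = sorted(set(result.profiles) | set(result.exclusions))
    for acc in accs:
        tests = result.tests.get(acc, [])
        min_p = min((r.corrected_p for r in tests), default=np.nan)
        rows.append(
            {
                "accession": acc,
                "n_segments": len(result.profiles[acc].segments)
                if acc in result.profiles
                else 0,
                "n_testable": len(tests),
                "min_corrected_p": min_p,
                "flagged": acc in result.flagged,
                "exclusion_reason": result.exclusions.get(acc, ""),
            }
        )
    return pd.DataFrame(rows)


def run_plf(config: RunConfig) -> StudyResult:
    """Read inputs, run the analysis, write the result bundle and manifest.

    Outputs per region: ``<region>_segments.csv`` and ``<region>_proteins.csv``;
    cross-region: ``venn_partitions.csv``, composite profiles, and
    ``plf_unique.txt`` when an abundance-significant list is supplied. On
    failure every partially written output is removed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        proteins = read_fasta(config.fasta)
        records: list[PeptideRecord] = []
        for t in config.peptide_tables:
            records.extend(read_peptide_table(t, config.min_probability))
        study = analyze_study(
            proteins,
            records,
            nominal_size=config.nominal_size,
            tail_mode=config.tail_mode,
            occurrence_policy=config.occurrence_policy,
            alpha=config.alpha,
        )

        for region, result in sorted(study.regions.items()):
            p = out_dir / f"{region}_segments.csv"
            _segment_table(result).to_csv(p, index=False, float_format="%.10g")
            written.append(p)
            p = out_dir / f"{region}_proteins.csv"
            _protein_table(result, config.alpha).to_csv(
                p, index=False, float_format="%.10g"
            )
            written.append(p)

        if study.region_sets is not None:
            rows = []
            for cell, members in sorted(
                study.region_sets.venn_cells().items(),
                key=lambda kv: tuple(sorted(kv[0])),
            ):
                rows.append(
                    {
                        "regions": "&".join(sorted(cell)),
                        "count": len(members),
                        "accessions": ";".join(sorted(members)),
                    }
                )
            p = out_dir / "venn_partitions.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            written.append(p)

        comp_rows = []
        for acc in sorted(study.composite):
            for region in sorted(study.composite[acc]):
                vals = study.composite[acc][region]
                for j, v in enumerate(vals, start=1):
                    comp_rows.append(
                        {"accession": acc, "region": region, "segment": j, "scaled": v}
                    )
        p = out_dir / "composite_profiles.csv"
        pd.DataFrame(
            comp_rows, columns=["accession", "region", "segment", "scaled"]
        ).to_csv(p, index=False, float_format="%.10g")
        written.append(p)

        if config.abundance_list:
            abundance = {
                line.strip()
                for line in Path(config.abundance_list).read_text().splitlines()
                if line.strip()
            }
            unique = plf_unique(study.flagged_union, abundance)
            p = out_dir / "plf_unique.txt"
            p.write_text("".join(f"{a}\n" for a in sorted(unique)))
            written.append(p)

        if config.annotation_table:
            # pass-through: attach user-supplied class labels to the flagged union
            ann = pd.read_csv(config.annotation_table)
            ann = ann[ann.iloc[:, 0].isin(study.flagged_union)]
            p = out_dir / "flagged_annotations.csv"
            ann.to_csv(p, index=False)
            written.append(p)

        manifest = {
            "package_version": __version__,
            "parameters": {
                "nominal_size": config.nominal_size,
                "min_probability": config.min_probability,
                "alpha": config.alpha,
                "tail_mode": config.tail_mode,
                "occurrence_policy": config.occurrence_policy,
            },
            "inputs": {
                "fasta": {"path": str(config.fasta), "sha256": _sha256(config.fasta)},
                "peptide_tables": [
                    {"path": str(t), "sha256": _sha256(t)}
                    for t in config.peptide_tables
                ],
                "abundance_list": str(config.abundance_list)
                if config.abundance_list
                else None,
            },
            "outputs": [p.name for p in written],
        }
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return study


def load_manifest(path: str | Path) -> RunConfig:
    """Re-ingest a manifest into the RunConfig that reproduces the run."""
    data = json.loads(Path(path).read_text())
    params = data["parameters"]
    return RunConfig(
        fasta=data["inputs"]["fasta"]["path"],
        peptide_tables=tuple(
            t["path"] for t in data["inputs"]["peptide_tables"]
        ),
        out_dir=str(Path(path).parent),
        nominal_size=params["nominal_size"],
        min_probability=params["min_probability"],
        alpha=params["alpha"],
        tail_mode=params["tail_mode"],
        occurrence_policy=params["occurrence_policy"],
        abundance_list=data["inputs"]["abundance_list"],
    )
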