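"""The statistical core of peptide location fingerprinting.

Pipeline per (protein, region):

1. **Normalisation** — each sample's segment counts are rescaled so its
   whole-protein total equals the experiment-wide (both groups) median
   whole-protein spectrum count. This makes every downstream comparison
   independent of whole-protein abundance: only the *distribution* of
   spectra along the primary structure matters.
2. **Group averaging** — per-segment mean and sample SD within the young
   and aged groups. Proteins detected in only one group are excluded.
3. **Difference profile** — (mean aged − mean young) / segment length, the
   per-residue peptide-yield shift along the structure (positive = higher
   yield in aged).
4. **Per-segment testing** — an unpaired two-group comparison per segment
   (pooled-variance F test with one numerator df, the square of the pooled
   two-sample t), Bonferroni-corrected within the protein: each protein is
   its own family, m = its number of testable segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import CompositeScaleError, PLFError
from .segmentation import SampleKey, Segment, SegmentCountMatrix

#: star-annotation thresholds on the Bonferroni-corrected p-value
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

#: protein-level significance threshold (corrected p)
FLAG_ALPHA = 0.05


@dataclass
class NormalizedSegmentMatrix:
    """Segment counts rescaled so every retained sample sums to the median total."""

    accession: str
    region: str
    segments: list[Segment]
    samples: list[SampleKey]  # retained samples (positive whole-protein total)
    values: np.ndarray  # shape (n_retained, n_segments), floats
    median_total: float
    dropped_samples: list[SampleKey] = field(default_factory=list)

    def group_rows(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if s.group == group], dtype=int)


@dataclass(frozen=True)
class SegmentTestResult:
    """Two-group comparison of one testable segment."""

    accession: str
    region: str
    segment: Segment
    mean_young: float
    mean_aged: float
    sd_young: float
    sd_aged: float
    raw_p: float
    corrected_p: float
    stars: str


@dataclass
class GroupSummary:
    """Per-group, per-segment mean and sample SD after normalisation."""

    accession: str
    region: str
    segments: list[Segment]
    n_young: int
    n_aged: int
    mean_young: np.ndarray
    mean_aged: np.ndarray
    sd_young: np.ndarray  # NaN where n < 2
    sd_aged: np.ndarray

    @property
    def testable(self) -> bool:
        return self.n_young >= 2 and self.n_aged >= 2


@dataclass
class DifferenceProfile:
    """Per-segment (aged − young) normalised yield divided by segment length."""

    accession: str
    region: str
    segments: list[Segment]
    values: np.ndarray


def normalize_matrix(matrix: SegmentCountMatrix) -> NormalizedSegmentMatrix:
    """Rescale each sample row to the experiment-wide median whole-protein total.

    The anchor M is the standard median (midpoint average for even counts)
    of the positive row totals across all samples of *both* groups. Rows
    with a zero total carry no information about distribution along the
    structure and admit no scale factor; they are dropped and recorded as
    absences (presence/absence is handled by the one-group exclusion rule).
    """
    counts = matrix.counts.astype(float)
    totals = counts.sum(axis=1)
    keep = totals > 0
    retained = [s for s, k in zip(matrix.samples, keep) if k]
    dropped = [s for s, k in zip(matrix.samples, keep) if not k]
    if not retained:
        return NormalizedSegmentMatrix(
            accession=matrix.accession,
            region=matrix.region,
            segments=matrix.segments,
            samples=[],
            values=np.zeros((0, len(matrix.segments))),
            median_total=float("nan"),
            dropped_samples=dropped,
        )
    median_total = float(np.median(totals[keep]))
    values = counts[keep] * (median_total / totals[keep])[:, None]
    return NormalizedSegmentMatrix(
        accession=matrix.accession,
        region=matrix.region,
        segments=matrix.segments,
        samples=retained,
        values=values,
        median_total=median_total,
        dropped_samples=dropped,
    )


def group_average(nm: NormalizedSegmentMatrix) -> GroupSummary | None:
    """Per-group mean and sample SD per segment.

    Returns ``None`` when the protein is present in only one group — such
    proteins are excluded from the analysis entirely. A group retaining a
    single sample has undefined SD (NaN); the protein is then untestable
    but keeps a difference profile.
    """
    young = nm.group_rows("young")
    aged = nm.group_rows("aged")
    if len(young) == 0 or len(aged) == 0:
        return None

    def _stats(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vals = nm.values[rows]
        mean = vals.mean(axis=0)
        if len(rows) >= 2:
            sd = vals.std(axis=0, ddof=1)
        else:
            sd = np.full(vals.shape[1], np.nan)
        return mean, sd

    mean_y, sd_y = _stats(young)
    mean_a, sd_a = _stats(aged)
    return GroupSummary(
        accession=nm.accession,
        region=nm.region,
        segments=nm.segments,
        n_young=len(young),
        n_aged=len(aged),
        mean_young=mean_y,
        mean_aged=mean_a,
        sd_young=sd_y,
        sd_aged=sd_a,
    )


def difference_profile(
    summary: GroupSummary, tail_mode: str = "actual", nominal_size: int | None = None
) -> DifferenceProfile:
    """(mean aged − mean young) / segment length for every segment.

    ``tail_mode="actual"`` divides by each segment's true residue length
    (nominal for all but the final partial segment), avoiding deflation of
    C-terminal signal; ``"nominal"`` divides by ``nominal_size`` everywhere
    (the first segment's length when not given).
    """
    if tail_mode not in ("actual", "nominal"):
        raise ValueError(f"unknown tail_mode {tail_mode!r}")
    if tail_mode == "actual":
        lengths = np.array([s.length for s in summary.segments], dtype=float)
    else:
        nominal = nominal_size if nominal_size is not None else summary.segments[0].length
        lengths = np.full(len(summary.segments), float(nominal))
    values = (summary.mean_aged - summary.mean_young) / lengths
    return DifferenceProfile(
        accession=summary.accession,
        region=summary.region,
        segments=summary.segments,
        values=values,
    )


def star_annotation(corrected_p: float) -> str:
    """Map a corrected p-value onto the conventional significance stars."""
    for threshold, stars in STAR_LEVELS:
        if corrected_p <= threshold:
            return stars
    return ""


def test_segments(nm: NormalizedSegmentMatrix) -> list[SegmentTestResult]:
    """Per-segment unpaired two-group comparison with Bonferroni correction.

    Each segment with any signal (non-zero in at least one sample of either
    group) is testable; m = the number of testable segments of this protein
    is the Bonferroni family size (each protein is its own experiment).
    Returns one result per testable segment. Requires >= 2 retained samples
    per group.

    Degenerate segments where every value is identical across both groups
    get raw p = 1; zero pooled variance with differing means gives p = 0.
    """
    young = nm.group_rows("young")
    aged = nm.group_rows("aged")
    if len(young) < 2 or len(aged) < 2:
        raise PLFError(
            f"{nm.accession}/{nm.region}: need >= 2 retained samples per group "
            f"(have young={len(young)}, aged={len(aged)})"
        )
    y = nm.values[young]
    a = nm.values[aged]
    testable = ~(np.all(y == 0, axis=0) & np.all(a == 0, axis=0))
    m = int(testable.sum())
    if m == 0:
        return []

    # degenerate (constant) segments are re-assigned below; silence the
    # near-identical-data warnings scipy raises for them
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tt = sps.ttest_ind(a, y, axis=0, equal_var=True)
        raw_p = np.asarray(tt.pvalue, dtype=float)

    both = np.vstack([y, a])
    identical = np.all(both == both[0, :], axis=0)
    mean_diff = a.mean(axis=0) - y.mean(axis=0)
    zero_var = (y.var(axis=0) == 0) & (a.var(axis=0) == 0)
    raw_p[identical] = 1.0
    raw_p[zero_var & ~identical & (mean_diff != 0)] = 0.0

    results: list[SegmentTestResult] = []
    sd_y = y.std(axis=0, ddof=1)
    sd_a = a.std(axis=0, ddof=1)
    for j, seg in enumerate(nm.segments):
        if not testable[j]:
            continue
        p = float(raw_p[j])
        corrected = min(1.0, p * m)
        results.append(
            SegmentTestResult(
                accession=nm.accession,
                region=nm.region,
                segment=seg,
                mean_young=float(y[:, j].mean()),
                mean_aged=float(a[:, j].mean()),
                sd_young=float(sd_y[j]),
                sd_aged=float(sd_a[j]),
                raw_p=p,
                corrected_p=corrected,
                stars=star_annotation(corrected),
            )
        )
    return results


def flag_significant_proteins(
    results: Iterable[SegmentTestResult], alpha: float = FLAG_ALPHA
) -> set[str]:
    """Accessions with at least one segment significant after correction."""
    return {r.accession for r in results if r.corrected_p <= alpha}


def composite_scale(
    profiles: Mapping[str, DifferenceProfile | np.ndarray | Sequence[float]],
) -> dict[str, np.ndarray]:
    """Scale each region's difference profile to [-1, 1] for overlay plots.

    Each region's profile is divided by its own maximum absolute segment
    value, so profiles from regions with very different depths of coverage
    become visually comparable. All-zero profiles stay at zero.
    """
    if len(profiles) < 2:
        raise CompositeScaleError("composite requires >= 2 regions")
    scaled: dict[str, np.ndarray] = {}
    for region, prof in profiles.items():
        vals = np.asarray(prof.values if isinstance(prof, DifferenceProfile) else prof, dtype=float)
        peak = np.abs(vals).max() if vals.size else 0.0
        scaled[region] = vals / peak if peak > 0 else vals.copy()
    return scaled
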