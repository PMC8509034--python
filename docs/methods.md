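# Methods

## The model

Peptide location fingerprinting treats each protein, in each tissue
region, as its own experiment. The observable is a samples × segments grid
of summed peptide spectral counts; the claim tested is that the *shape* of
that grid along the primary structure differs between groups. The method
is deliberately blind to whole-protein abundance: each sample's row is
rescaled to the experiment-wide median whole-protein count before any
comparison, so a protein that is simply more abundant in one group — with
peptides released in the same proportions — produces a null fingerprint.

Assumptions worth keeping in mind:

* Spectral counts are semi-quantitative. Segment sums behave roughly like
  overdispersed counts; the per-segment test is a normal-theory comparison
  of 2–3 replicates per group and inherits the usual small-sample caveats.
* Peptides are assumed exclusive to their parent protein (the upstream
  identification filter); a peptide occurring at several positions within
  one protein is placed at its first occurrence by default, since counting
  each occurrence would multiply its spectra.
* Coordinates are 1-based and inclusive throughout.

## Statistical choices

**Per-segment test.** We use a per-segment, unpaired, pooled-variance
two-group comparison (the 1-df F statistic, i.e. the squared pooled t)
with protein-wise Bonferroni correction. With exactly two groups, 2–3
replicates each, and per-segment significance stars as the reported
output, a genuine mixed repeated-measures model over segments is not
identifiable, and the per-segment formulation reproduces the reported
behaviour exactly. The Bonferroni family is the protein's *testable*
segments: segments with zero counts in every sample of both groups carry
no information and are excluded from m, so sparse proteins are not
over-penalised.

**Degenerate segments.** If every value in a segment is identical across
both groups, raw p is defined as 1. If both groups have zero within-group
variance but different means (possible only through exact ties after
normalisation), the pooled t is infinite and raw p is 0.

**Zero-total samples.** A sample whose whole-protein total is zero admits
no scale factor; it is dropped from the matrix (and the median anchor,
which is taken over positive totals only) and recorded as an absence.
Presence/absence itself is handled by the exclusion rule: proteins present
in only one group are excluded entirely; a group reduced to one retained
sample makes the protein untestable, though its difference profile is
still reported with a warning.

**Tail segments.** The final partial segment is kept as its own segment —
C-terminal signal (propeptide regions) is where key biology lives — and by
default its difference value is divided by its *actual* length, which
avoids deflating C-terminal signal. A strict mode divides by the nominal
size (50) everywhere for exact agreement with the published formula.

**Composite scaling.** For cross-region overlay, each region's difference
profile is divided by its own maximum absolute value, mapping it onto
[−1, 1]; the anchor-free shape is what is comparable across regions. No
published scheme exists for this normalisation; max-|value| is the
simplest one that preserves sign and shape.

**Abundance invariance, precisely.** Multiplying one sample's raw counts
by any constant c > 0 leaves the normalised matrix unchanged *up to the
experiment-wide anchor M*: the sample's own normalised row is exactly
unchanged unless its total determines the median, in which case every row
rescales by the common factor M′/M — which cancels in every group
statistic, difference-profile shape and p-value. Tests assert this exact
form.

## The synthetic-data generator

The generator emulates the statistical structure of a two-group,
multi-region spectral-counting study so the pipeline can be validated
end-to-end without real data. Per protein: in-silico tryptic digestion
(cleave after K/R unless followed by P; up to 2 missed cleavages; products
kept in a 7–35-residue detectability window), a seeded per-peptide
detection draw and uniform detectability weight (uneven coverage without
claiming an ionisation model), a log-normal whole-protein total across
proteins, and negative-binomial replicate counts. Implanted effects
multiply the expected counts of every peptide overlapping a designated
residue interval in one group — wholesale, with no partial-overlap
proration, mirroring how a structural modification blocks (fold < 1) or
enhances (fold > 1) release of the whole peptide. Effects can optionally
be restricted to particular tissue regions to emulate locally acting
mechanisms.

Defaults (the study conditions): two groups × three regions × 3 vs 3
replicates (a 3 vs 2 override emulates the unbalanced posterior design);
median whole-protein total 800 spectra with log-SD 0.6; detection
probability 0.7; NB dispersion k = 150, giving individual peptide counts a
replicate CV near 20 % at typical per-peptide means (CV² = 1/μ + 1/k);
random proteomes with ~11 % K/R so tryptic products have realistic
lengths.

What it does **not** emulate: ionisation physics, retention time, spectrum
quality, PTMs, shared peptides across proteins, or correlated biological
covariation between proteins. Passing tests therefore demonstrate that the
*pipeline arithmetic and statistics* behave as specified under the assumed
count model — not that the biological interpretation of any real-data
fingerprint is correct.

## Validation scenarios and problem sizes

* **Null calibration:** 500 effect-free proteins, 3 vs 3; the per-protein
  family-wise flag rate at corrected p ≤ 0.05 stays within binomial error
  of 0.05 (measured ≈ 0.034–0.042).
* **Recovery:** a 4-fold aged suppression over a segment-aligned
  100-residue interval, 3 vs 3, in abundant proteins (median total 3000
  over ~50 detectable peptides, so segment baselines far exceed 20 counts)
  with dispersion k = 30 (per-peptide replicate CV ≈ 20 % at those means);
  500 affected + 500 effect-free proteins. A closed-form noncentral-t
  pilot oracle puts per-segment power near 1 (ncp ≈ 16 against a critical
  t ≈ 5.8); the pipeline detects ≈ 96 % of affected segments, with
  effect-free proteins flagged at the null rate.
* **Abundance immunity:** a uniform 3-fold whole-protein shift, evaluated
  under biological-replicate noise (k = 12, scale-free CV ≈ 29 %,
  dominating counting noise — the realistic regime for cadaveric
  between-disc replicates): flag rates match the null.

**Known limitation.** When counting (Poisson) noise dominates replicate
variation — low per-peptide counts and little biological overdispersion —
a strong whole-protein abundance shift makes the two groups' variances
unequal after normalisation (the larger counts carry relatively less
counting noise), and the pooled test becomes mildly anti-conservative:
family-wise flag rates of 0.06–0.08 instead of ~0.04 under a 3-fold shift
in that regime. This is a property of the published test formulation, not
of this implementation; interpret flags on proteins with large abundance
differences and low counts with care.

## Numerical conventions

Median = standard midpoint median; sample SD uses ddof 1; normalisation
conservation is exact to 1e-9 relative; Bonferroni caps at 1; star
thresholds are closed (≤). All randomness flows from a single integer
seed through `numpy.random.default_rng`; identical seed + configuration
reproduces byte-identical tables and result bundles (the run manifest
records parameters and input checksums and can be re-ingested to repeat a
run).
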