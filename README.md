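# plfkit — peptide location fingerprinting for spectral-count proteomics

Long-lived extracellular-matrix proteins (collagens, proteoglycans,
elastic-fibre proteins) accumulate structural damage with age — glycation,
oxidation, protease cleavage — that need not change how *much* of the
protein is present, only *where* along its structure trypsin can release
detectable peptides. **Peptide location fingerprinting (PLF)** turns that
into a statistic: it compares the distribution of peptide spectral counts
along each protein's primary structure between two groups (here young vs
aged intervertebral-disc tissue, per anatomical region), independent of
whole-protein abundance. Proteins whose regional peptide yield differs
significantly are candidates for age-associated structural change and for
biomarker discovery.

This package is for proteomics analysts who already have per-sample peptide
lists (exported from PSM-scoring software such as Scaffold) and protein
sequences, and want a tested, scriptable implementation of the whole PLF
workflow, plus a synthetic-data generator that makes every stage verifiable
without any real mass-spectrometry data.

## The method

For each protein (accession *i*, length *L*) and each tissue region,
analysed independently:

1. **Segmentation.** The sequence is tiled into ⌈*L*/50⌉ consecutive
   50-residue segments (the last may be shorter). Each located peptide adds
   its full spectral count to every segment its coordinates overlap — a
   peptide spanning two adjoining segments is counted in both.
2. **Normalisation.** Sample *s*'s segment counts are rescaled by
   *M*/*T*ₛ, where *T*ₛ is the sample's whole-protein count and *M* the
   experiment-wide (young + aged) median of the positive totals. Every
   retained sample then sums to *M*, so downstream comparisons are
   independent of whole-protein abundance.
3. **Difference profile.** Per segment, (mean aged − mean young) / segment
   length; positive values mean higher peptide yield in aged.
4. **Testing.** Per segment, an unpaired two-group comparison (pooled-
   variance F test with one numerator df — the square of the pooled
   two-sample t), Bonferroni-corrected within the protein: corrected
   p = min(1, p·m), m = the protein's testable segments. Stars follow the
   usual convention (\* ≤ 0.05, \*\* ≤ 0.01, \*\*\* ≤ 0.001). A protein is
   *flagged* in a region when any segment reaches corrected p ≤ 0.05.
   Proteins detected in only one group are excluded.
5. **Region comparison.** Flagged sets are intersected across regions
   (shared vs region-exclusive structural changes) and differenced against
   an abundance-based significant list (proteins unique to PLF).

## Worked example

The numbered scripts under `analysis/` form a complete synthetic study.
`analysis/01_simulate_study.py` generates a 60-protein, three-region
young-vs-aged study (posterior unbalanced 3 vs 2, as in real disc designs)
with known implanted effects; `02` runs the analysis; `03` compares
regions against the ground truth:

```text
$ python analysis/01_simulate_study.py
simulated 60 proteins, 83644 peptide rows across 3 regions
17 implanted effects (12 suppressions, 5 abundance shifts)

$ python analysis/02_run_plf.py
anterior: 60 proteins tested, 8 flagged, 0 excluded
left_lateral: 60 proteins tested, 10 flagged, 0 excluded
posterior: 60 proteins tested, 9 flagged, 0 excluded
shared across all three regions: ['SYN0002', 'SYN0003', 'SYN0004', 'SYN0005']

$ python analysis/03_compare_regions.py
...
shared in all regions: ['SYN0002', 'SYN0003', 'SYN0004', 'SYN0005']
implanted tissue-wide suppressions recovered there: 4/6
exclusive to posterior: ['SYN0007', 'SYN0008', 'SYN0026', 'SYN0043', 'SYN0045']
exclusive to left_lateral: ['SYN0009', 'SYN0010', 'SYN0039', 'SYN0040', 'SYN0050']
exclusive to anterior: ['SYN0006', 'SYN0011', 'SYN0012']
```

Reading this: of the six 4-fold aged suppressions implanted in all three
regions, four are recovered in every region (the other two reach
significance in two of three — the unbalanced posterior design has the
least power); the region-specific implants (SYN0007–SYN0012) flag in their
own regions, and the five proteins given only a 3-fold whole-protein
abundance shift are not flagged at all — abundance alone leaves no
fingerprint. `analysis/04_operating_characteristics.py` quantifies this:
null family-wise flag rate 0.053 (300 proteins, nominal 0.05), 95.6% of
implanted-suppression segments detected, abundance-shift flag rate 0.047.

The same workflow is available as a CLI (`plf simulate`, `plf run`,
`plf compare`) for real exports: a FASTA plus delimited peptide tables with
columns `sample_id, group, region, accession, peptide_seq, spectral_count`
and optional `probability` (rows below 0.95 are dropped, matching the
upstream identification filter).

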