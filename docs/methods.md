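# Methods

## Problem setting

Bone proteomes are dominated by a small set of highly expressed genes
(collagens and a handful of non-collagenous proteins), and protein sequence
databases for those genes vary wildly in completeness across mammalian
taxa.  Assigning a species to an MS raw file by counting peptide or
protein-group hits therefore favors well-annotated species.  `taxopep`
instead converts peptide evidence to amino-acid observations at *global
alignment sites* and decides every species-vs-species comparison only on
the sites where the two species genuinely differ, so database completeness
cancels out of each comparison.

## Database model

The database is a gene-wise multiple sequence alignment: per gene, one
aligned sequence per species over the 20 amino acids plus `-`.  The default
gene panel is 20 abundant bone-proteome genes (collagens COL1A1/COL1A2/
COL3A1/COL5A1/COL5A2/COL11A1 and major non-collagenous proteins such as
AHSG, ALB, BGN, CHAD, DCN, FN1, IBSP, LUM, OMD, PCOLCE, SERPINC1, SPP1,
VIM, APOA1); the panel is configurable and parsing rejects records whose
`GN=` tag is outside it.  Headers may be UniProt or the pipe-separated
pseudo-UniProt dialect with `OS = … OX = … GN = …` tags.

Ingest decisions:

- **Isoform collapse.** Several records per (species, gene) are collapsed
  to a per-column majority consensus; a column with gaps in more than half
  of the isoforms becomes a gap; amino-acid ties break alphabetically.  A
  single representative per species per gene is required for the
  difference matrix to be well defined.
- **Character hygiene.** Sequences are upper-cased; characters outside the
  20 amino acids and `-` (X, B, Z, U, …) become gaps with a logged count —
  they cannot support a site difference.
- **I→L.** All isoleucines in database and peptide sequences are rewritten
  to leucine before any matching; the two are isobaric and
  indistinguishable by MS.
- **Coordinates.** Genes are concatenated in alphabetical order and
  columns numbered 1..L (closed, 1-based).  On the published 20-gene
  mammalian database this yields L = 25,550; synthetic defaults yield
  L = 3,000.
- **Gene-count filter.** Species lacking more than `max_missing` (default
  5) of the genes covered by the database are removed before inference —
  too many missing genes make a species unassignable and bias competition.
  The filter is idempotent and exempts decoys.

## Decoy species

Species-level FDR is estimated with chimeric decoys: the global alignment
is cut into 500-column slices (the final partial slice is kept) and each
decoy copies every slice — gaps included — from a target species drawn
uniformly with replacement.  Decoy count defaults to the target count.
Slicing operates on global coordinates, so a slice may span a gene
boundary; per-gene decoy sequences are re-derived from the chimera, and a
gene whose slice content is all gaps is treated as missing for that decoy
(decoys are generated after the gene-count filter and exempt from it).  A
decoy identical to a target (exact aligned-string equality) is
regenerated; with random slice sources this only triggers on degenerate,
near-zero-divergence databases.  Decoys enter the difference matrix and
the competition exactly like targets.

## Evidence model

A **precursor** is a unique (raw file, modified sequence, charge); a
**peptide** is the unique stripped sequence.  Duplicate precursor rows are
merged (intensity summed, score maximized) before anything else.  Missing
intensities are kept as 0 — DDA tables legitimately contain identified-but-
unquantified rows, which still contribute counts and scores.  Records with
a precursor q-value above 1% are dropped; records without a q column
(MaxQuant evidence, already engine-filtered at 1%) pass.

Annotation re-matches stripped sequences against the database by exact
substring search rather than trusting the search engine's protein-ID
column: it is self-contained and dialect-independent.  No missed-cleavage
or semi-tryptic modeling happens at annotation time — enzyme specificity
already lives in the upstream search.  Precursors matching a contaminant
entry are excluded from site evidence entirely; protease (trypsin/LysC)
precursors in particular are treated as a spike-in abundance standard, so
they are excluded from species scoring *even if* their sequence also
occurs in a target protein, but always retained in intensity totals.

## J-score

Per (raw file, global site, amino acid): precursor count, peptide count,
log₁₀ of the summed intensity when the sum exceeds 1 (else 0), and the
maximum search score, each divided by its maximum over the amino acids at
that site *in that file*; the four scaled metrics are multiplied and the
product rescaled by the per-site maximum.  Numerical choices:

- A metric whose per-site maximum is 0 (all intensities ≤ 1, all scores
  ≤ 0) is neutral (factor 1 for every amino acid) instead of producing
  0/0 — ranking information from the remaining metrics survives.
- Negative search scores are clamped to 0 before scaling.
- If every amino acid at a site ends with raw product 0 (possible when
  different metrics zero different amino acids), all J at that site are 0;
  otherwise the per-site maximum J is exactly 1.
- A precursor matched to several species contributes to the union of its
  covered (site, amino-acid) pairs once, not once per species.

The J-score weights amino acids by the strength of their underlying
evidence; it is deliberately not calibrated to an amino-acid posterior
probability.

## Competition and fine-grouping

For each pair {A, B}, J-scores of A's variants at the pair's
discriminating sites are summed against B's.  Larger sum wins; equal sums
— including 0 vs 0 when no discriminating site was observed — make both
species winners, so data-free pairs penalize neither side and
indistinguishable sets remain representable.  Best match = all species
attaining the maximum win count.  Fine-grouping applies only when the best
match intersects a marker group; each candidate is scored by the *sum* of
its detected marker-peptide intensities (the natural reading of
intensity-based scoring), ties return all top candidates, no detection
returns the best match unchanged, and the output never leaves the
intersecting groups' candidate set.

## Confidence thresholds

- **Signal.** Relative protease intensity = protease intensity / total
  intensity (clamped to [0, 1]; 0 when the file has no intensity).  The
  cutoff is the upper quartile (linear-interpolation percentile, the
  common default) of the laboratory blanks; with no blanks the run aborts
  unless a manual cutoff is configured.  Files at or above the cutoff are
  `signal_too_low`; the comparison carries a 1e-9 tolerance so files whose
  ratios are identical by construction are not split by summation-order
  jitter.
- **Species FDR.** Files are ranked by decreasing site count — the number
  of distinct global sites whose observed amino acid matches the assigned
  species (any member of an indistinguishable set counts: the set is one
  taxonomic claim).  The raw q at a site-count cutoff is the fraction of
  decoy-only assignments among files at or above it; tied site counts
  stand or fall together; q-values are monotonized by a cumulative minimum
  from the lowest-coverage rank upward so that the 1% flag corresponds to
  a single site-count cutoff.  A set mixing targets and decoys counts as a
  target identification (a decoy tie should not inflate the FDR); this is
  a documented, configurable convention.
- **Threshold order.** The signal threshold is applied first and
  signal-failed files are excluded from the q-value ranking (their q is
  NaN).  This ordering is what makes the 1% guarantee hold by
  construction: let K* be the worst-ranked file with monotonized
  q ≤ 1%; the minimum defining q(K*) ranges over ranks ≥ K*, and any rank
  beyond K* achieving it would itself have q ≤ 1%, contradicting the
  maximality of K* — so q(K*) equals the raw decoy fraction of the kept
  set, which is therefore ≤ 1%.  Ranking signal-failed blanks too would
  pad the zero-coverage tail, let boundary files ride the diluted tail
  fraction, and break exactly this argument.
- Both raw and monotonized q are reported.

Per-sample consensus sequences take, per covered site, the amino acid with
maximal J (ties alphabetical).  Deamidation fractions (deamidated N or Q
occurrences over all N or Q occurrences across precursors, NaN when a
residue type is absent) are reported as a damage QC metric; the
modification parser understands the short `(de)` and the long
`(Deamidation (NQ))`/`[Deamidated (NQ)]` notations, including nested
parentheses.

## Synthetic data

The simulator exists so that both FDR mechanisms and the full pipeline are
testable with no external data.  Defaults were chosen once as
field-realistic study conditions:

| parameter | default | rationale |
|---|---|---|
| species | 30 | cohort-scale roster with clade structure |
| genes × columns | 8 × 375 (L = 3,000) | bone-panel-like total coverage at desk scale |
| divergence | 0.04/branch (×U(0.5, 1.5)) | percent-level protein divergence between relatives |
| missing-gene rate | 0.03 | occasional absent annotations |
| digest | cleave after K/R not before P, ≤2 missed cleavages, length 7–30 | trypsin+LysC search settings |
| semi-tryptic fraction | 0.3 | degraded bone yields substantial semi-tryptic peptides |
| intensity | lognormal(ln 1e6, 1.2) | MS1 intensity spread over ~3 decades |
| score | N(100, 30) clamped ≥ 40 | Andromeda-like score range with a minimum identification score |
| deamidation prob. | 0.1/N or Q | moderate damage level |
| protease share | 0.1 | visible autolysis background in real samples |

A random bifurcating topology is generated by recursive splitting; each
branch substitutes sites independently and uniformly (no rate
heterogeneity — enough to create discriminating sites of tunable density).
Alignments contain no insertions, so gaps arise only from missing genes;
gap handling itself is exercised by hand-built and random toy databases in
the tests.  Evidence generation samples the true species' digest pool
until a target number of distinct sites is covered (log-uniform per-file
targets create a preservation gradient in cohorts), held-out "novel"
species files exercise the decoy mechanism, and protease autolysis
intensities are rescaled so the realized relative protease intensity
equals the configured share.  Blanks contain protease precursors with
intensity plus spurious unmatched identifications carried as
identified-but-unquantified rows (intensity 0), so a blank's relative
protease intensity is exactly 1 and the upper-quartile calibration
excludes every blank.  Deamidation is simulated as an annotation on the
modified sequence only — it never alters matching, because annotation uses
stripped sequences.  Because intensities and scores are idealized and no
spectrum-level physics is modeled, passing synthetic tests demonstrates
the correctness of the inference logic, not search-engine performance on
real spectra.

## Sizes used in the validation suite

The test suite and `scripts/acceptance.py` use desk-scale protocols chosen
as adequate sampling for the properties under test: a 200-file cohort
(150 database-species samples, 30 novel, 20 blanks) over 30 species + 30
decoys for FDR control; 100 single-sample runs at ≥ 1,000 covered sites
for true-species recovery; 50 runs at ≥ 3,000 covered sites with a sister
species differing at 12 sites for sister exclusion; 50 random toy
databases (≤ 6 species, ≤ ~300 sites) for exact brute-force oracle
equivalence; 10⁴ randomized sites for the J-score invariants.

## Known limitations and open points

- A species absent from the database is assigned to its nearest database
  relative when coverage is high; the decoy q-value only bounds the rate
  of decoy-only assignments, mirroring the method's design.
- The pairwise-comparison count over the full target+decoy roster is
  n(n−1)/2 for n = targets + decoys; published material sometimes counts
  target-sized grids (156² = 24,336), a convention this implementation
  does not follow.
- Hybrid detection from dual marker intensities is out of scope; marker
  intensities are reported, not interpreted.
- Fine-grouping candidate scoring uses summed intensities; max-based
  scoring is a defensible alternative and trivially swappable.
- The exact-equality decoy regeneration check cannot detect a decoy that
  differs from a target only at sites where one of the two has a gap.
- Incremental (per-file) inference is deliberately absent: q-values are
  cohort-dependent, so a study must be processed together.
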