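# Methods

## Scope and model

The package compares the peptide products of two proteolytic conditions
(typically a stand-alone 20S proteasome core particle versus the 26S
holoenzyme) digesting a known substrate.  Its inputs are downstream of
spectral identification: tables of non-tryptic peptides with per-sample
PSM counts, substrate sequences, and optional per-residue disorder tracks.
Database searching, FDR control and PTM localization are upstream tools'
responsibilities; this package maps, filters, integrates and tests.

Coordinates are 1-based inclusive.  Cleavage site `j` is the bond between
residues `j` and `j+1`; residue `j` is the P1 position of that bond, and a
window around the bond is labelled P4..P1 | P1'..P4' from N- to C-terminal.

### Assumptions

* Each identified peptide is an exact substring of its substrate (the
  optional I/L equivalence collapses the one isobaric pair a fragment-mass
  search cannot resolve).  Mass-tolerant or mutated matching is out of
  scope.
* PSM counts are additive evidence: duplicate rows for the same
  (sample, peptide, branch) key are summed at ingest.
* An internal product evidences **two** cleavage events, so its count is
  credited to both bounding sites; products touching a substrate terminus
  credit their single internal bound.  An N-terminal-only crediting mode
  exists for sensitivity analysis.  Multi-mapping peptides are excluded
  from site integration by default (a fractional 1/k mode is available),
  since crediting every occurrence would double-count evidence.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_replicates` | 2 (of 3) | replicates | a peptide must appear in two of three replicates of a condition to count; set to 1 for sparse in-vivo peptidomes |
| `pseudo_value` | 0.1 | PSMs | substituted for zero integrated counts so one-sided sites yield a finite log2 ratio |
| `fold_threshold` | 2.0 | fold | a two-fold ratio in either direction flags a site preference |
| `min_sample_psms` | 50 | PSMs | samples shallower than this carry too little depth for the occupancy matrix |
| `top_n_peptides` | 100 | peptides | sample ordination uses the most intense peptides by per-peptide maximum CPM |
| `detection_floor` | 7 | residues | non-specific searches do not reliably identify shorter products; the simulator censors below it |

The pseudo-value is applied to raw integrated counts; an optional CPM mode
normalizes each condition to counts-per-million first, which changes what
0.1 means — output headers echo the mode.  Sites with zero counts in both
conditions are reported NA rather than log2(0.1/0.1)=0, to avoid
fabricating "no preference" at unobserved bonds.

## Occupancy matrix and ordination

PSM counts form a sample × peptide matrix restricted to mapped peptides.
Samples with fewer than `min_sample_psms` raw mapped PSMs are dropped,
then peptides observed in a single retained sample.  Counts become CPM of
each sample's mapped total, and each peptide column is rescaled to its
maximum (so retained columns peak at exactly 1; the maxima are kept as the
side-bar values).  Columns are ordered by the peptide's N-terminal residue,
then length, then lexicographically.

Sample distances are Euclidean on log2(CPM+1) over the top-`n` peptides.
Ordination is classical (Torgerson) multidimensional scaling — double
centering of squared distances and the leading eigenpairs — rather than a
stress-minimizing MDS, because the classical solution is deterministic and
has no iteration to seed.  Reflections are fixed by requiring the first
sample's coordinates to be non-negative.  Ward linkage is computed on the
2-D MDS coordinates.  This replaces the leading-log-fold-change distance
of edgeR's `plotMDS`; distances, not their flavor, drive the clustering,
and the replacement is exact to rerun.

## Composition logos and the differential test

Windows P4..P4' around each used site are weighted by the site's
integrated count, so the composition reflects usage (an unweighted mode
exists).  Positions off a terminus are excluded from that position's
denominator.  Information content follows the sequence-logo convention
`IC(pos) = log2(20) − H(pos)` with letter heights `f × IC` and no
small-sample correction by default.

The differential comparison reports signed frequency differences per
(position, residue) and a per-position chi-square test of homogeneity on
the weighted counts, pooling residue categories whose expected count falls
below 1.  Because eight positions are scanned per comparison, the
*flagging* rule (`flag_positions`) applies a Bonferroni correction across
positions by default, the convention of differential-logo tooling; raw
per-position p-values are always returned for users who prefer their own
control.  Under a matched-composition null (two multinomial site-usage
draws of 1000 events from the same log-uniform site law) the corrected
rule flags nothing in ~99% of runs, whereas raw per-position α=0.01 would
flag in ~5% — the measured family-wise rate of eight correlated tests.

## Lengths, tests, disorder

Length summaries follow the boxplot convention: quartiles by linear
interpolation (R type 7, numpy's default) and whiskers at the most extreme
observations within 1.5 IQR of the quartiles.  The default weighting
counts each distinct peptide once (`per_peptide`); `per_psm` repeats
lengths by their counts, since either reading of a "product size
distribution" is defensible.  Products below the detection floor in real
tables are kept as-is — the floor is a property of the identification
strategy, not of the analysis.

Pairwise tests are the two-sided Mann–Whitney U (exact null when both
n ≤ 8 without ties, otherwise the tie- and continuity-corrected normal
approximation) and Welch's unequal-variance t.  Protein disorder scores
are plain means of per-residue predictions in [0,1]; condition-unique
protein sets are set differences of evidence, with their score vectors
passed to the tests above.

## Ubiquitin remnants and branched peptides

Remnants are C-terminal suffixes of ubiquitin (GG, RGG, LRGG by default,
configurable to the full length).  The canonical orientation is N→C
("RGG"); the outward lysine-first notation ("GGR") is accepted on input
and converted by reversal.  Remnant masses are sums of monoisotopic
residue masses (no extra water: an isopeptide bond condenses one water
exactly as a backbone bond does), from an embedded residue-mass table
cross-checked in tests against pyteomics.  A reported branched peptide is
valid iff its remnant is a ubiquitin suffix, its backbone maps uniquely to
the substrate, and the branch lysine coincides with a declared anchor;
failures carry machine-readable reasons.  Peptides overlapping two or more
construct segments are classified chimeric.

## The digestion simulator

The simulator emulates the *statistical shape* of replicated two-condition
digestion data, not enzymology.  Each detected product event draws a left
and a right boundary independently from a categorical distribution over
{N-terminus, internal sites, C-terminus} — internal sites weighted by
per-site weights, termini by the mean positive site weight — and pairs are
rejected until the product length falls inside the condition's window
(defaults 7–35 aa for a 20S-like enzyme, 7–25 aa for a 26S-like one,
reflecting the longer products of the stand-alone core particle).  Events
shorter than the detection floor are censored but counted, so observed +
censored = depth per replicate.  Identical products aggregate into PSM
counts.  Replicate r uses seed `model.seed + r`.  Products covering a
declared anchor lysine can gain an isopeptide branch with probability
`branch_prob` (default 0; remnant drawn GG 0.5 / RGG 0.3 / LRGG 0.2,
di-glycine being the most commonly observed stub), with counts split
binomially.

What it does **not** emulate: processive translocation (boundaries are
independent draws; a processivity parameter is a natural extension hook),
product re-entry and re-processing, ionization/detectability bias by
sequence, chromatographic co-elution, or search-engine scoring.  Passing
recovery tests therefore demonstrates that the analysis inverts this
generative family — site preferences recovered with Spearman ρ ≈ 0.99 at
depth 5×10⁴ over 50 sites, null preferences centered at |median| ≈ 0.02 —
not that real instruments behave this way.  Simulator parameters are
stand-ins and never estimates of real enzymes.

## Packaged fixtures

Two substrate fixtures ship with the package: the 88-residue disordered
cyclin B1 N-terminal region (15 lysines, destruction-box degron at
42–50, K64 anchor) and its K64-only variant (every other lysine replaced
by arginine), the form used for site-specific chemical ubiquitination, on
which the branched peptide ARLPLPKE maps uniquely with its lysine at
residue 64.  Both are synthetic transcriptions: sequences constructed to
satisfy the documented properties of the constructs (length, lysine count
and positions, degron, anchor context) rather than copies of a database
record, and they are labelled as such in their FASTA headers.  Human
ubiquitin (76 aa) is included verbatim.

## Problem sizes

Defaults for simulation-backed checks are 50-site substrates at depth
5×10⁴ events per replicate with 3 replicates for preference recovery,
depth 10⁴ for the length signature, 200 draws of 10³ events for the
composition null, and 2×10⁴ events for branch-injection recovery — deep
enough that recovery statistics stabilize while a full verification run
completes in well under a minute.

## Known limitations

* Exact-substring mapping cannot place peptides from mutated or modified
  substrate regions; they land in the unmapped table.
* Both-termini crediting of site counts induces correlation between
  adjacent sites' usage estimates; the preference statistic treats sites
  independently.
* The chi-square differential test is asymptotic; with very shallow usage
  (effective weights of a few counts) its calibration degrades despite
  pooling.
* Classical MDS on non-Euclidean distance structures clips negative
  eigenvalues; with few samples the 2-D embedding is faithful, but Ward
  heights are computed in embedded space, not on raw distances.
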