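# Methods

This note documents the models and procedures implemented in `sixtm`,
the parameters that matter, the synthetic data the tests rest on, and
the choices made where the design was genuinely open.

## Coordinates and formats

All in-memory coordinates are 1-based closed intervals (the
GTF/genome-browser convention); BED and bedGraph input (0-based
half-open) is converted at the parsing boundary.  Transcript exon lists
are stored in transcription order, so minus-strand models hold exons in
descending genomic order and spliced sequences always read 5'→3'.
Genomes may contain `N`; codons containing `N` are untranslatable and
terminate ORF scanning at that point.  Exon variants such as 5'
extensions are modelled as distinct labelled intervals, not as edits of
a parent exon.  Conservation score tracks are sparse per-base maps;
scores outside [0, 1] are rejected at load time.

Isoform record sets carry a canonical receptor protein with exactly
seven annotated TM domains — the GPCR contract — plus splice isoforms
with a database-fragment flag.  A converter from real UniProt flat files
is a documented extension point, not part of the core.

## Transcript topology classification

**ORF enumeration.**  Every qualifying start codon opens one reading
frame translated with the standard genetic code to its first stop.  Two
start policies exist: `aug_only` (default) and `aug_gug_cug`, which adds
the near-cognate starts CUG and GUG; the initiator is always reported as
Met, which is how near-cognate initiation decodes in vivo.  The default
is conservative; the near-cognate policy exists because some 6TM-coding
transcripts (extended exon 2 variants) initiate at CUG.

**Helix prediction.**  Single-sequence transmembrane helix prediction
uses mean Kyte–Doolittle hydropathy over a sliding window (default
window 19, threshold 1.6, minimum reported length 15 — conventional
values for TM scans; all configurable).  A residue is a *qualifying
center* when its full window mean is ≥ threshold.  Each maximal run of
qualifying centers is one helix, reported over the run's span; where a
run abuts the first or last valid center it is extended to the sequence
terminus, since no centers exist beyond that point to delimit it.
Overlapping spans are merged; a hydrophobic run of ~20 residues flanked
by hydrophilic loops of ≥ 12 residues is therefore reported as exactly
one helix covering approximately the run.  HMM-based predictors would
additionally model topology (in/out orientation) and signal peptides;
those are out of scope, and concordance with any particular external
predictor's output is not claimed.

**Product calls.**  The primary ORF is the one opening at the 5'-most
qualifying start.  Its translation is helix-typed and aligned to the
canonical receptor (see the screen below) to decide TM coverage:

* 7 helices covering TM1..TM7 → 7TM product;
* 6 helices, TM1 absent, TM2..TM7 covered → 6TM product;
* exactly 1 helix with the ORF ending at a PTC → 1TM fragment, after
  which reinitiation is modelled: only the first AUG lying downstream of
  the PTC and at/after the second exon's start is tested, and yields a
  6TM product when its translation has six helices covering TM2..TM7.
  Restricting reinitiation to a single downstream AUG reflects how
  ribosomes resume scanning after a short upstream ORF, and matches the
  observation that in these loci translation of the 6TM frame can restart
  only in exon 2.

A stop codon is premature when its last base lies upstream of the final
exon–exon junction.  **NMD candidacy** uses the classical 50-nt rule —
flagged when the stop lies ≥ 50 nt upstream of the last junction — with
the threshold configurable; single-exon transcripts are never flagged.
Ties between equal-length ORFs are broken toward the 5'-most start.
Classification is fully deterministic.

## Isoform truncation screen

Each isoform is globally aligned to its canonical receptor with
BLOSUM62 and affine gaps (open 10, extend 1) via Biopython's
`PairwiseAligner`; of co-optimal alignments the aligner's first
enumeration is taken, making results deterministic.  Canonical TM
domains are transferred through the alignment: a helix is **present**
when ≥ 50% of its canonical residues align to non-gap isoform residues
(`coverage_min`, configurable).  Fractional coverage tolerates
splice-boundary shifts inside a helix while rejecting whole-helix
deletions; the exact criterion used by curation pipelines is ambiguous,
and this parameter exposes that ambiguity.  Lowering `coverage_min` can
only turn absent helices present (monotonicity), which the tests check.

Where a helix is absent, the *replaced segment* — the maximal
isoform-only (insertion) run of alignment columns adjacent to the
missing helix — is checked with the same hydropathy predictor; a
replacement that itself forms a helix **rescues** the position, and the
isoform is not counted as truncated there.  Note that a same-length
hydrophobic replacement typically aligns residue-to-residue rather than
as an insertion (BLOSUM62 scores hydrophobic substitutions near zero or
positive, far above two gap opens), in which case coverage alone already
marks the helix present; the explicit rescue path matters for
length-mismatched replacements that the aligner pushes into insertion
columns.

Categories follow the effective presence vector: `full_7TM`,
`N_trunc_6TM`, `C_trunc_6TM`, `N_trunc_5TM`, `C_trunc_5TM`, `other`,
with `excluded_fragment` for database fragments removed before analysis.
**Selection** keeps calls with ≥ 4 helices missing TM1 or TM7.  The
6TM/5TM labels derive from the helix count after rescue.

## Exon divergence and conservation

**Substitution counting.**  Over a pairwise exon alignment, transitions
(A↔G, C↔T) and transversions (everything else) are counted over columns
where both sequences have a non-gap, non-N base (`lenA`); ungapped
lengths `lenQ`/`lenS` count all residues including N.  Treating N like a
gap for counting keeps ambiguous bases out of both numerator and
denominator.  Whether gap-containing columns should enter the aligned
length at all is a convention, asserted here rather than inferred.

**Kimura two-parameter distance.**  With P = transitions/lenA and
Q = transversions/lenA,

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)],

the exact closed form; inputs with `1 - 2P - Q <= 0` or `1 - 2Q <= 0`
raise a saturation error rather than returning a number.  K ≥ P + Q
always, with equality only at zero divergence.  UTR and coding exons
(K_u vs K_e) use the same computation under different region labels.
Alignments are consumed as inputs (aligned FASTA) or generated
synthetically; a basic global nucleotide aligner (match +1, mismatch −1,
gap −2) is included for small demonstrations only.  Inputs are assumed
repeat-masked upstream when repeat exclusion is desired; no masking is
performed here.

**Conservation summaries.**  The conservation score of an exon is the
mean of its per-base scores, reported with the standard error of the
mean (sample SD / √n; the SD itself is also reported, and a single
scored position yields SEM 0).  The customary 100-nt flank describes
retrieval context only and never enters the mean; unscored positions are
skipped and the scored count is reported.

## Enrichment statistics

For m receptor genes, an n-gene disorder set and k genes in both within
an N-gene genome (N defaults to 19,020 in the bundled universes):

    fold = prob(R ∩ D) / [prob(R) · prob(D)] = k·N / (m·n)

reported to one decimal (stored at full precision), with significance
from the exact one-sided upper binomial tail P(X ≥ k),
X ~ Binomial(n, m/N) — the expected frequency of receptor genes in the
genome against their observed frequency in the disorder set.  The
one-sided upper-tail convention is pinned down by recomputation: from
the counts (12; 7/4/3; 800/1383/383; 19,020) it reproduces the reported
significances 1.04e-6, 0.01 and 0.002 exactly, which a two-sided or
lower-tail reading does not.  The tail is summed directly with log-space
terms (lgamma), giving full relative precision even at ~1e-31; tests
cross-check against exact rational enumeration (n ≤ 30) and
`scipy.stats.binom.sf`.  Symbols match case-insensitively with no alias
resolution; duplicate symbols within a set are an error; no
multiple-testing correction is applied (raw binomial p-values are the
convention here).  A hypergeometric/Fisher variant is deliberately not
the default — the binomial model is the method being reproduced.

## Synthetic data: what it emulates and what it does not

All generators take an integer seed and are byte-deterministic.

**Receptor loci** mirror the shared architecture of opioid-receptor
genes: exon 1 encodes the N-tail and TM1 (configurable, up to TM3), exon
2 opens with an in-frame AUG inside the first cytosolic loop and encodes
through TM4, exon 3 encodes TM5–TM7 and the stop; an optional cassette
exon between exons 1 and 2 carries an in-frame premature stop.  Helices
are random Leu/Ile/Val/Phe runs (21 residues by default), loops and
tails random Ser/Thr/Asn/Gly runs (15 by default).  Coding sequence uses
a restricted codon table (no codon starts with "TG" or ends with "AT")
and UTRs/introns are drawn from {C, A} only, so the only AUG/CUG/GUG
trigrams in any transcript are the planted initiators — upstream ORFs
never arise by accident.  Each generated protein set is verified against
the package's own helix predictor (7, 7−n and n helices for the
canonical, skipped and PTC products) with loops redrawn on violation (at
most 100 times).  Real loci differ in nearly every sequence property:
codon usage, splice signals, loop composition, helix amphipathicity,
upstream ORFs and IRES elements are not modelled.  Passing the planted
tests therefore demonstrates the classifier's internal consistency on
unambiguous architectures, not concordance with experimental receptor
annotation.

**Isoform benchmarks** plant whole-TM deletions with ≥ 5 residues of
flanking loop removed alongside, so category recovery is unambiguous by
construction; real isoform boundaries often cut helices mid-span, which
is exactly the regime the `coverage_min` parameter exists for.  The
expected call for a TM1-replacement ("rescue") isoform is a full 7-helix
receptor whichever detection path fires (direct coverage or insertion
rescue), and the truth labels record that.

**Two-parameter pairs** substitute per site independently — transition
with probability P, transversion with probability Q (the two transversion
targets equiprobable), identity otherwise — parameterised by realized-
proportion targets rather than rate × time, so the closed form
K(P_target, Q_target) is the exact expectation oracle with no CTMC
machinery.  No indels are introduced.

**Enrichment universes** plant an exact overlap k, or draw it from the
null hypergeometric for calibration runs.  The bundled
`synthetic_disorder_universe()` combines the curated 12-gene
truncated-6TM list with synthetic placeholder symbols for the 824-gene
GPCR set and the 800/1383/383-gene disorder sets; overlaps are planted
at 7/4/3 (truncated-6TM) and 119/93/17 (all GPCR — the addiction overlap
sits at its chance level of ≈ 16.6).  Only counts drive the statistics,
so this stand-in reproduces the arithmetic of a run on curated lists
with the same counts; it carries no information about which genes
overlap.

## Problem sizes and tolerances in the test suite

Parameter recovery uses 200 pairs of 10 kb at (P, Q) = (0.05, 0.02),
asserting the mean estimate within 2% of the closed form 0.0741 (the
per-mean standard error is ≈ 0.3%, so the band is ≈ 7 SE wide).
Substitution counting is checked against a per-column brute-force
recount on 1,000 random alignments, and the helix predictor against an
independent direct-recomputation oracle on 1,000 random proteins.  The
screen is checked on 20 seeded 10-gene benchmarks (100% category
recovery required), topology on 50 seeded loci (canonical must be
perfect; the skipped and cassette calls must reach 95%, with failures
logged — in practice they are also perfect under the default
parameters).  Null calibration of the binomial p-value uses 5,000
hypergeometric draws, requiring the empirical CDF never to exceed the
uniform CDF by more than twice the Monte-Carlo error: the binomial tail
is slightly conservative against the hypergeometric null because it
ignores the finite-universe variance reduction.

## Known limitations

- The hydropathy predictor has no orientation model, no signal-peptide
  handling, and makes no claim of concordance with HMM-based tools.
- Reinitiation is a single-candidate model; leaky scanning and multiple
  reinitiation events are not represented.
- The screen's replaced-segment definition is alignment-dependent; a
  different gap parameterisation can move a replacement between the
  substitution and insertion regimes.
- Divergence handles substitutions only (no indel model), and repeat
  masking is assumed done upstream.
- Gene-set enrichment treats gene symbols as opaque strings; alias
  resolution and annotation versioning are out of scope.
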