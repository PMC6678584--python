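# Methods

## Read preprocessing

A raw read passes the quality gate iff every one of its first 25 base
qualities is at least `q_min` (default 30, Phred+33); reads shorter than
25 nt fail, since they cannot demonstrate 25 clean leading bases. The 3'
adapter (default `TGGAATTCTCGAGTGCCAAGGAACTCC`) is trimmed at the leftmost
run of ≥ 6 bases identical to an adapter prefix that extends through the
full adapter or to the read end; matching is exact, which keeps trimming
byte-stable. Trimmed reads are collapsed to unique sequences with summed
counts, and sequences of 18 nt or shorter are dropped. Genomic coordinates
are 1-based inclusive throughout (GFF3 convention).

## Hairpin folding

`fold_hairpin` minimizes free energy over nested structures in which every
base pair encloses at most one directly-nested pair — unbranched helices
ending in terminal loops, any number of stem-loops side by side at the outer
level. Multiloops are excluded: pre-miRNA hairpins are single stems, and the
restriction keeps the structure class exhaustively enumerable, which is how
the optimizer is validated (exact energy agreement with enumeration for all
sequences up to 18 nt).

Energy terms: Watson–Crick and G·U pairs; approximate Turner-style
nearest-neighbor stacking free energies (kcal/mol at 37 °C, module constant,
swappable); hairpin-loop, bulge and internal-loop initiation penalties with
logarithmic extrapolation beyond tabulated sizes. Interior loops are capped
at 12 total unpaired bases in the dynamic program (the cap cannot bind for
n ≤ 18, so oracle comparisons are exact). Energies are handled as integer
hundredths of a kcal/mol; ties break toward more pairs, then toward pairs
opening as far 5' as possible. Minimum hairpin loop is 3 nt.

The precursor gates — energy < −40 kcal/mol, ≥ 18 paired nucleotides, at
most one terminal loop — are evaluated on this model's energy scale. The
−40 threshold originates from a full-featured folding model; on our
simplified scale it is configurable (`HairpinCriteria.mfe_max`) rather than
rescaled by guesswork. One structural consequence: a hairpin with fewer than
18 paired nucleotides (≤ 8 pairs) cannot reach −40 kcal/mol under any
physically scaled stacking table, so the paired-count gate can only fail
together with the energy gate at the default threshold.

Mature-placement quality counts, within the mature span: bulged nucleotides
(unpaired on one strand of a loop whose other strand is fully paired),
mismatched/asymmetrically unpaired nucleotides (internal loops, terminal
loops, exterior bases), and the longest run of consecutive unpaired bases;
the gates are ≤ 2, ≤ 5 and ≤ 3. The duplex-overhang check measures, for each
arm, how far the partner arm's 3' end extends beyond the pairing partner of
this arm's 5' end; both overhangs must be within a tolerance (default ±1) of
the canonical 2 nt.

## Alignment and cross-mapping correction

Reads align to precursors end-to-end, substitutions only, after splitting
off a maximal non-templated 3' suffix of up to 3 nt (the trailing run of
template-mismatching bases); the templated portion tolerates one internal
mismatch, mirroring a `-v 1`-style mapper. Indels are not modeled because
editing calls are substitution-based. Candidate placements come from two
exact seeds inside the guaranteed-templated prefix (pigeonhole: one mismatch
can spoil at most one seed), verified exhaustively; the seeded search is
provably equivalent to a sliding-window scan and is tested against one.

Genome alignment reports all loci on both strands within the mismatch
budget (1 for editing analysis, 2 for discovery/blocklist subtraction, per
the respective contracts). Cross-mapping correction assigns a multi-mapped
read sequence to its candidate loci in proportion to each locus's
mismatch-free read support, uniformly when no candidate has perfect support;
weights sum to one per read, so weighted tallies conserve counts. The
reassignment is single-pass: with expression estimated from perfect reads
only, the iterative fixed point coincides with the single pass.

## Editing-site statistics

Per precursor position, weighted depth and per-alternative support are
tallied from templated bases; soft-tail bases are tallied separately at the
positions just past the templated end (tail bases beyond the precursor
terminus have no reference base and are not reported as sites). The test is
a one-sided exact binomial tail against the sequencing-error null,
P(X ≥ ⌈k⌉) with X ~ Binomial(round(n), e) and e = 10^(−30/10)/3 — an error
occurs at ≤ Q30 rate and lands on one of three alternatives. Weighted
fractional support is rounded up (conservative). Benjamini–Hochberg
correction is applied across all (position, alternative) tests within one
sample; BH was chosen over Bonferroni as the field standard and the
correction method is configurable. Significant sites further satisfy level
≥ 5% and support ≥ 10 reads, applied per sample (combination across samples
then records per-site detection and significance flags).

Classification order: Pseudo (supporting reads carry ≥ 50% cross-map weight
on other loci — a majority-origin rule, configurable); non-templated tail
sites by tail nucleotide (A → 3'-A, U → 3'-U, otherwise 3'-Other; each tail
position is reported as its own single-nucleotide site, matching the site-id
convention); substitutions at or ≤ 2 nt 5' of a mature start → 5' site;
A→G → A-to-I; C→T → C-to-U; anything else → Other with the substitution
subtype recorded. SNP labels are assigned only against a variant table:
same genomic position, same alleles (strand-aware complementing), and a
level of 100% in at least one sample. Cross-species conservation matches
sites on (normalized family key, mature position, substitution), so
precursors of different lengths can share a site.

## Quantification and targets

RPTM is expanded as reads per ten million: count × 10⁷ / (reads mapped to
the mature miRNA set in the sample). The denominator convention is not
universal; it is the package default and can be replaced by a genome-mapped
total. Expressed miRNAs satisfy mean RPTM ≥ 5 and sample standard deviation
(n−1) ≥ 1 across profiles.

A 3'UTR window is a predicted target iff, aligned antiparallel to miRNA
positions 1–8, it forms ≥ 7 consecutive Watson–Crick pairs (G:U not
counted); any such run necessarily covers the seed (positions 2–8), which
reconciles the two common seed conventions. Target sets are compared at the
transcript level; percent shared is the Jaccard percentage (two empty sets
share 0 by convention). Enrichment is a generic hypergeometric upper tail
over a user-supplied term → gene annotation with BH correction — no external
pathway database is consulted.

## Synthetic data

The simulator plants stem-loop precursors in a random background genome,
alternating strands. Each stem is fully paired with a G·U wobble roughly
every 7 rungs — as real pre-miRNA stems have — which keeps folding energies
far below the gate while making the two arms non-complementary enough that
arm reads cannot cross-map onto the opposite arm (a perfect stem would make
every 5p read an exact antisense match to the 3p arm). Mature spans are
placed so the duplex carries exact 2-nt 3' overhangs. Reads are drawn from
both arms with independent uniform {−2..+2} end jitter; planted edits are
applied per covering read with probability equal to the true level (SNPs
always); tails are appended with their configured fraction, with the bases
just past the 5p mature end forced to differ from the tail's first
nucleotide so the tail is genuinely non-templated; sequencing errors hit
each insert base with probability 10^(−Q/10); the literal 3' adapter is then
appended error-free and quality strings are constant at Q — which makes the
quality gate and the error null analytically checkable. Decoy loci are
composition-preserving shuffles redrawn until they fail the hairpin gates.
Everything derives from one integer seed, bit-reproducibly, and a truth
manifest records every locus, site, and read provenance.

The discovery validation study uses an A/C-only background (A and C cannot
pair with each other), so candidate windows fold on the planted locus alone
and each decoy isolates one filter clause: a weak A/U stem (energy), a
short strong stem (paired count — necessarily accompanied by the energy
clause, see above), twin strong stems (terminal-loop count), a 64%
accumulation layout, and a 9-read locus.

What the simulator does not model: ligation bias, PCR duplicates, realistic
tissue expression distributions, indels, or quality-score variation along
the read. Passing tests therefore demonstrate contract correctness of the
analysis chain on data with known truth, not robustness to every artifact of
real libraries.

## Validation measurements and problem sizes

The acceptance computations use 50 precursors at coverage 500 with planted
levels {0.05, 0.10, 0.30, 0.60} under Q30 noise (~50,000 reads per study),
an edit-free study of the same size for false-call control, a 4-precursor
study at coverage 300 for the SNP clauses, the discovery study above, 200
random sequences (≤ 18 nt) for the folding oracle, all 495 (n ≤ 30, k ≤ n)
cases for the binomial oracle, and 50 random multi-mapping configurations
for weight conservation.

Recall is measured over *recoverable* planted sites: those whose sampled
reads — as recorded in the truth manifest, independent of the pipeline —
satisfy the level and support criteria among reads the contract admits
(longer than 18 nt, at most one total deviation so a one-mismatch aligner
can place them). A site planted exactly at the 5% gate whose binomial draw
landed below it is not recoverable by any faithful implementation; about
10–20% of boundary-level sites are in this situation at coverage 500, and
folding them into the denominator would measure sampling noise rather than
pipeline fidelity.

## Known limitations

- The folding model is deliberately reduced (no multiloops, no dangling
  ends, no coaxial stacking, approximate parameters); energies are on the
  model's own scale, and the −40 kcal/mol gate should be re-calibrated if
  the stacking table is swapped.
- Cross-mapping weights are locus-granular; two overlapping loci on the
  same strand are not disambiguated further.
- Tail classification is per tail nucleotide; a mixed tail (e.g. AG)
  contributes one 3'-A site and one 3'-Other site rather than a single
  composite event.
- The SNP level clause uses an exact 100% test; a single discordant read at
  a true homozygous site (possible at low quality) defeats it, as the
  clause demands.
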