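# Methods

This note documents the models and conventions behind trfkit: what each
stage computes, the defaults and why, the numerical choices at the edges,
what the simulator does and does not emulate, and the known limitations.

## Coordinates and the reference model

All coordinates are 0-based half-open. The canonical axis is *mature-tRNA
space*: position 0 is the first base of the spliced, flank-trimmed
transcript; 5'-flank positions are negative; positions ≥ L (the mature
length) are the 3' flank, or the CCA on the mature+CCA variant; intron
positions carry a sentinel and never map to mature space.

Four variants per gene — unspliced precursor with flanks, spliced precursor
with flanks, mature, mature+CCA — cover the molecule's processing states so
that each read can be matched with the fewest post-transcriptional
assumptions. Intronless genes still emit all four (two identical) so the
per-gene count is constant; duplicates are removed at alignment-index time,
not at build time. Minus-strand genes are stored sense-strand; flanks are
cut from the genomic strand and reverse-complemented, so no later stage sees
strand. The flank width (60 bp) and the gene filters (tRNAscan-SE score
≥ 30, pseudogenes out, mitochondrial genes in a separate partition rather
than dropped) are the method's standard settings.

Families group genes with identical mature sequences; the family identifier
reuses the member symbol that sorts first under a natural-number-aware
ordering of the symbol fields, making the id deterministic for any member
order. The six hierarchy levels (amino acid, isoacceptor, isodecoder,
family, gene, transcript) are nested by construction when isodecoder
numbering follows sequence identity, as in GtRNAdb-style symbol sets and in
the toy generator; the nesting is property-tested on generated sets.

## Read assignment

Identity is matches / read length over an ungapped end-to-end placement of
the read within a variant; indels are not modeled (tRFs are contiguous
cleavage products, and gaps would blur the class boundaries). A placement is
retained when identity ≥ 0.96, reads shorter than 18 nt are counted and
skipped, and only placements tied at the maximal identity survive.

Candidates come from a 12-mer index with exhaustive verification. The seed
is exact for this contract: a length-L read may carry at most
floor(0.04 · L) mismatches, which by pigeonhole always leaves one intact
12-mer for L ≥ 18 — so seed-and-extend finds every admissible placement
(verified against a brute-force scan in the tests).

Within a gene, a read contained in several variants collapses to the one
requiring the fewest assumptions: mature when no flank/CCA bases are used,
mature+CCA when CCA bases are used, otherwise the precursor (spliced
preferred). Reads matching several genes keep one hit per gene at weight
1/k; family-level statistics re-aggregate those weights, so family totals
are stable while gene-level tables remain honest about ambiguity.

One special case: a read carrying both a 5' addition and the 3' CCA fits no
single variant; it places on the precursor with the CCA as an apparent 3'
overhang. The aligner recognizes an overhang of ≤ 3 bases as CCA when the
bases read CCA *and* at least one mismatches the genomic trailer — the same
untemplated-signature logic used for 5' additions.

## Fragment classification

Classification is a first-match rule list on the fragment's span, making the
taxonomy a deterministic total function (exhaustive enumeration over a
flanked precursor yields exactly the 12 labels):

1. no overlap with the mature span → `other` (pure flank fragments);
2. reaches both boundary regions → `Full_U_tRNA` if it extends into a
   flank, else `Full_tRNA`;
3. anchored at the 5' terminus: ends inside the anticodon window →
   `5_tRNA_halves` (`5_U_...` if flank-extending); ends before the window →
   `5_tRFs` / `5_U_tRF`;
4. mirrored rules at the 3' side (CCA counts as the mature terminus);
5. everything else → `i_tRFs`.

Two tolerances make the rules robust to real read ends. A fragment end
matches a terminus within ±2 nt; at the 5' side, negative offsets are where
untemplated additions live, so when additions detection has run, the
addition bases are stripped and the remaining (templated) start must lie in
[0, +2] — a *templated* 1–2 nt overhang then classifies as a flank
("U") class. When templating is unknown (pure interval classification), the
raw start tolerance is [-2, +2]. The anticodon window extends one base
beyond the triplet on each side, because cleavage concentrates around, not
strictly inside, the anticodon loop. 5'-anchored fragments ending well past
the anticodon (and the 3' mirror case) fall through to `i_tRFs`; the
taxonomy defines no long-half class.

Identifiers `tRF#<Len>-<SeqCODE>` pack the sequence 2 bits per base,
big-endian, emitted 5 bits per character over a fixed 32-character alphabet
(digits + uppercase minus I, L, O, Q), zero-padded in the final chunk; a
23-nt fragment therefore always yields a 10-character code. The codec is
injective and reversible given the length field; identity with any external
database's encoding is not guaranteed and not relied upon.

Retention requires > 500 reads in at least one sample; the high-confidence
flag requires > 1000 reads in at least two samples; both are strict
inequalities, and the 18-nt length floor applies throughout.

## Quantification

NR = M × 10⁹ / N, with N counted from the FASTQ *before* trimming and
mapping — filtered-out reads still scale the denominator. Weighted
(fractional) M is allowed and used. NR is additive by construction, so the
per-sample total at every hierarchy level equals
(total mapped weight) × 10⁹ / N; the tests assert this conservation law.
Sample similarity is r² of log10(NR+1) profiles at the family level
(tRF-level profiles are available as an option); constant profiles are
assigned r² = 0 against everything and flagged rather than raising. The
average-linkage clustering on 1 − r² orders the matrix for display only.

## Modification calling

Pileups are family-level (members are sequence-identical; gene-level is an
option), weighted, in mature coordinates; flank and intron positions are
excluded. MR = mismatching / covering weight. A candidate site needs
MR > 0.8 and coverage > 200; "supporting reads" is interpreted as coverage
at the position, since MR already encodes the mismatch fraction and coverage
is the natural confidence weight. Canonical tRNA position labels (9, 26, 34,
37, 58, ...) are an optional annotation input, never inferred from sequence.

The treated/untreated contrast labels each called site `control_only`
(alkylation-sensitive methylation removed by the demethylase),
`treated_only` (modifications whose RT signature appears only after
demethylation), or `both` (treatment-resistant, e.g. inosine at the wobble
position). Two diagnostics accompany the calls: the per-sample fraction of
mapped reads with ≥ 1 mismatch, and the MR histogram, whose two-peak shape
(near 0 and near 1) separates sequencing noise from near-stoichiometric
modifications.

## 5' additions

For a read starting k ∈ {1,2,3} bases 5' of the mature start, the overhang
is compared with the templated upstream bases; an addition is recorded iff
the −1 base mismatches. A dinucleotide whose −2 base happens to match is
still an addition ("UG" on an "NG" template would otherwise be undercounted).
Longer overhangs are treated as flank-templated or left unmapped. Fractions
are read-weighted per (class group, sample), with class groups full /
5'-halves / 3'-halves / all. Strings under 50 weighted reads in a sample are
flagged low-confidence unless they recur in ≥ 2 samples — recurrence, not
raw depth, is what separates additions from sequencing error.

Note the identity interaction: an addition costs one mismatch against the
precursor variant, so very short fragments with additions (< 25 nt) fall
below the 96% identity floor and are not recoverable; at typical half/full
lengths the cost is negligible.

## Cleavage profiling

Cut coordinates are between-base boundaries; each mapped fragment
contributes one 5' and one 3' boundary at its alignment weight, so per
family and sample the two sides sum identically (asserted). CCA-terminated
fragments end at the terminus L, and terminal boundaries (0 and L) are
reported but excluded from site calling — termini are processing ends, not
cleavage. Boundary b of a length-L family projects to virtual-axis bin
min(floor(b·70/L), 69); counts are summed unnormalized over families and
samples, with frequencies computed at the end, and total mass is conserved.

Sites need ≥ 1000 reads in ≥ 2 samples (inclusive thresholds); no further
background model is applied — random degradation is separated from true
sites by frequency alone. Under template-switch chemistry, 5'-side sites are
suppressed by default since early RT stops are indistinguishable from 5'
cleavage. Flank export takes the 7-base context split 3 bases 5' + 4 bases
3' of the cut (an odd window cannot be centered; the convention is fixed and
documented), from the family representative's flanked precursor, N-padded at
edges, deduplicated by sequence.

## The simulator

The simulator emulates exactly the observables the pipeline measures:
fragment populations drawn per class (defaults put full-length molecules at
15% — real tRNA pools carry roughly 14–23% full-length — with halves and
3'-tRFs dominating and small flank-overlapping and flank-only fractions);
per-site mismatch emission and RT early stops as independent Bernoulli
events (many modifications misread without stopping, and vice versa); 5'
additions at configured per-string rates on fragments starting at the mature
start; uniform per-base substitution sequencing error; and the two library
chemistries — template_switch truncates a stopped read 5' of the stop site,
a_tailing loses it entirely.

Determinism: one RNG stream per (seed, sample index), so adding samples
never perturbs earlier ones, and identical configurations yield
byte-identical FASTQ (gzip mtime pinned). Default depth is 10⁴ reads per
sample and two samples — large enough that binomial recovery tests at
programmed rates resolve within 3 standard deviations, small enough that the
whole suite runs in seconds. Reads are 100 nt; fragments shorter than the
read length are emitted whole and adapter-free by default (the pipeline's
input contract is adapter-trimmed FASTQ), with an optional 3' adapter+poly-A
fill for exercising the internal trimmer. The toy gene generator fixes the
two bases upstream of every gene to "AA" so that configured G/T additions
are untemplated by construction.

What the simulator does *not* model — and what passing tests therefore do
not demonstrate about real data: PCR duplicates, indel errors, realistic
quality strings, coverage bias along the molecule, secondary-structure-
dependent RT behavior, partial demethylation, or genomic repeats outside the
tRNA loci. Recovery results on simulation bound implementation correctness,
not biological sensitivity.

## Known limitations

- Ungapped alignment only; `allow_indels` is reserved and raises.
- Classification of intron-retaining fragments follows the mature span of
  their endpoints; there is no intron-specific class.
- Multi-intron genes are supported by the coordinate maps, but flank
  placement for them follows the single-intron convention (flanks attach to
  the unspliced gene body).
- The MR statistic cannot see modifications that neither misread nor stop
  (e.g. most 2'-O-methylations).
- Addition detection requires the fragment to reach the mature 5' start;
  additions on internal cleavage products are out of scope.
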