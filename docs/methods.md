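# Methods

## Model

`strandscan` treats an assembled, strand-oriented transcript as the
observation sequence of a hidden Markov model with 20 atomic states in two
mutually exclusive modules plus an idle start state.

**Sense module.** `UTR_S` (self-looping untranslated sequence), `START_S`
(a 3-nt start-codon signal), six match states `M1…M6`, and `STOP_S` (a 3-nt
stop-codon signal) which returns to `UTR_S`. The six match states form a
six-periodic cycle over di-codons: the first body codon after the start is
emitted by `M1 M2 M3`, the second by `M4 M5 M6`, and so on, so codon
positions in odd and even codons carry separate parameters. Each match
emission is conditioned on the *k* preceding observed bases (*k* ∈ {0, 1, 2},
default 2), which captures dependence across the di-codon without enlarging
the state space. The codon cycle can be left for `STOP_S` only at codon
boundaries (`M3` or `M6`), so gene lengths are multiples of 3 by
construction. `STOP_S → UTR_S → START_S` cycles encode operons.

**Antisense module.** An antisense gene reads reverse-complemented along the
transcript-forward axis, so the module's axis order is `UTR3_A → STOP_A →
M1A…M6A → START_A → UTR5_A`: the mirrored stop codon is met first, the
mirrored start last. Emissions are the exact reverse-complement mirror of
the sense module: `MiA` carries the emission of `M(7−i)` with complemented
bases, conditioned on the *k* *following* axis bases (the mirror image of
"preceding"); the mirrored signal states emit the reverse complements of the
configured start/stop codons. The two antisense UTR states are distinct, and
`UTR5_A` is absorbing, so no path can contain a second antisense ORF —
antisense RNAs typically cover part of a single gene. `STOP_A` may enter the
codon cycle at `M1A` or `M4A` and `START_A` is reachable from `M3A` or
`M6A`, so both parities of the codon count are representable. An option used
only for symmetry testing (`restrict_antisense=False`) adds
`UTR5_A → STOP_A`, making the module cyclic like the sense one.

**Initiation and termination.** The idle state starts a path either in
`UTR_S` (probability 0.5) or in any antisense state (0.05 each): a sense
transcript must begin with untranslated sequence on its forward strand,
whereas an antisense transcript may be truncated anywhere inside the
mirrored gene. No end state is imposed; a path may stop anywhere, which is
what lets edge-truncated ORFs surface as partials.

**Signal scoring.** Start and stop signals are scored as *joint* codon
distributions supported exactly on the configured codon sets (defaults:
starts {ATG, GTG, TTG}, stops {TAA, TAG, TGA}). A column-factorised PWM
cannot restrict its support to a codon *set* (the {TAA, TAG, TGA} columns
would also admit TGG), which would let decoded genes end in a non-stop
trigram; the joint form makes "begins with a start codon, ends with a stop
codon" true by construction. The wider 15-column matrices (6 nt of flank on
each side of the codon) are still trained and serialised as descriptive
objects — their codon columns are the joint model's marginals — but the
decoder's per-position scoring uses the joint codon term only: on the
synthetic corpora the flanking columns carry almost no information, and
keeping emissions strictly per-position preserves exact path-score
semantics for the brute-force optimality checks.

**Decoding.** The 20 atomic states expand to 27 dynamic-programming states
(each 3-nt signal becomes three phase states traversed with forced
transitions); the codon emission is charged at phase 0. Viterbi runs in
natural-log space with −∞ for impossible events; ties are broken toward the
lowest state index in a fixed order (sense before antisense), making output
deterministic. Ambiguous bases (N) emit 1/4 under every state; a match
context containing N (or truncated by the sequence edge) falls back to the
state's context-averaged emission; a signal codon containing N is
marginalised over compatible codons at 1/4 per ambiguous position.

**Gene extraction.** Maximal coding runs of the decoded path become gene
calls when the start and stop signals are complete and the run is at least
120 nt *including* the stop codon (the threshold is read as inclusive; the
same value doubles as the minimum transcript length, chosen so a transcript
spans at least two overlapping ~100-nt reads). Runs truncated at a
transcript edge go to a separate partial channel — they are real biological
signal (a gene the transcript does not fully cover) but are excluded from
the scored gene set, mirroring how partial 5′ predictions are excluded from
evaluation. Antisense calls report transcript-forward coordinates with the
gene-oriented sequence (reverse complement) attached; if several complete
antisense ORFs survive (possible only with the restriction disabled) the
highest-scoring is kept. The per-gene score is an emission log-odds: path
emissions over the run minus the UTR background over the same span. This
score is strand-symmetric, which is what the mirror-consistency test
asserts; whole-path scores cannot be exactly symmetric because the
time-reversal of a locally normalised Markov chain is not obtained by
renaming edges.

## Parameters and training

All probabilities live in a `ParameterLibrary` keyed by integer GC percent
(default range 26–70 %, 1 % bins). A transcript selects the bin containing
`round(100·GC)`, clamped to the range. The GC dependence is realised by
*training* one parameter set per populated bin (records grouped by rounded
GC, pooled with ±1 % neighbours for stability) and filling unpopulated bins
from the nearest populated one — a self-contained stand-in for regressing
parameters on GC, with the same behaviour: parameters follow the input's
GC, no per-dataset training.

Estimators (Laplace pseudocount, default 1.0, everywhere):

* **Match emissions** — counts of body-codon bases per periodic state and
  preceding-*k* context. Start and stop codons belong to the signal states
  and are excluded from match counts; minus-strand genes are
  reverse-complemented into sense orientation first; genes failing the
  start/stop/length-divisible-by-3 rules are skipped and counted. With
  *k* = 2 the third-codon-position states can see the codon's first two
  bases, so stop-codon completions are hard-zeroed after normalisation:
  decoded genes can then never read through an in-frame stop. (With
  *k* < 2 the ban cannot be expressed exactly and is omitted.)
* **Transitions** — geometric rates. The UTR self-loop *q* comes from
  intergenic (post-stop) gaps only: a gap of *g* nt contributes *g* − 1
  self-loops and one exit, so the modelled mean gap is 1/(1 − *q*); leading
  and trailing UTR flanks are not used, which makes a corpus of single-gene
  records (pseudocount 0) yield a re-entry probability of exactly 0. The
  coding continuation comes from body lengths in codons. `STOP_S → UTR_S`
  is the only stop exit and has probability 1.
* **Signals** — joint codon frequencies over the configured sets, plus the
  15-column PWMs from windows around annotated starts/stops (windows
  hanging over a record edge are skipped).
* **UTR composition** — base frequencies of non-genic record sequence.

The antisense half is always derived by `mirror_parameters`
(reverse-complement symmetry); the operation is idempotent and preserves
validity and normalisation (all conditional distributions sum to 1 within
1e-9, checked by `validate_parameters`). Libraries serialise to a canonical,
version-tagged JSON (sorted keys, `repr`-exact floats): identical inputs
give byte-identical files, and load→save round trips are byte-exact.

## Transcript assembly

Given stranded paired-end alignments, pairs are partitioned by mate-1
orientation: FR chemistry maps "mate 1 forward" to the reference's plus
strand, RF (the dUTP protocol, default) to the minus strand. Both
conventions are implemented because the upstream protocol varies by kit;
the choice is a single flag. Unpaired, improper or unmapped records are
discarded and counted; secondary/supplementary alignments are ignored at
parse time. Covered regions (union of aligned intervals; abutting intervals
merge, gaps ≥ 1 nt split — no gap bridging) of ≥ 120 nt become transcripts,
the minus-strand set reverse-complemented, provenance recorded as
`ref:start-end:strand` (0-based half-open). Sense and antisense coverage may
overlap on the genome; the two classes are processed independently.

## Evaluation

Matching happens on transcript coordinates; projected annotations may
extend outside `[0, L)` to mark genes the transcript truncates. An
annotated gene enters the sensitivity denominator only when fully contained
in a transcript. A prediction is a true positive when it overlaps an
annotated gene in the same frame and strand — completely (mode `complete`)
or by ≥ 80 % of the *annotated* gene's length (mode `overlap80`).
Predictions whose stop matches an annotated gene in frame but whose start
lies mid-gene because the transcript truncates the gene's 5′ end are
excluded from both TP and FP (the start was unknowable from the data).
False positives are the predictions that fail even the 80 % criterion, and
precision in *either* mode is TP_mode/(TP_mode + FP) over that shared FP
set — a prediction that covers ≥ 80 % of a gene in frame but not all of it
is simply not credited under `complete`, not penalised twice. This is the
accounting that reconciles a benchmark's per-mode precision with its total
prediction count, and it is the one this package reports.

Operon comparison: a predicted operon (ordered, non-overlapping member
intervals) matches completely when its gene set equals a known operon's;
it matches at 80 % when its genomic span shares ≥ 80 % of *its own* length
with a known span (the denominator is the prediction — curated operons are
often longer than the transcribed fragment); "contained" and "spanning"
(≥ 2 known operons) describe the non-complete remainder. Antisense
transcripts are classified against annotated genes as: partial overlap with
exactly one opposite-strand gene and none on their own strand (plausible
asRNA); fully containing an annotated gene (likely a mis-stranded mRNA);
other.

## Synthetic data

The generator emulates exactly the structure the model exploits: background
sequence at a target GC; codon-biased genes (start codon, body from
per-state context-conditioned emission tables, stop codon) grouped into
transcription units on both strands — half the units are operons of 2–4
genes with 5–50 nt internal gaps, units are separated by 120–400 nt;
sense transcripts are unit spans with 20–60 nt UTR flanks; antisense
transcripts cover 30–80 % of one gene from its 3′ side plus a short
extension, placed only where no other gene intrudes; stranded paired-end
reads use the 101-nt / 300-nt read/insert geometry of current Illumina
mock data, FR or RF.

The coding tables are drawn from a symmetric Dirichlet (concentration 0.35
— strongly biased, as the recovery and benchmark conditions require) keyed
by a `table_seed` separate from the layout seed, so disjoint "genomes" share
one codon-usage model the way related community members do. Tables zero
stop-codon completions at third positions (no in-frame stops by
construction) and are then exponentially retilted so that the *stationary*
GC of the coding chain — computed by power iteration over the
(state, context) chain — hits the target GC; with the background exact, a
100-kb genome realises its target within ±0.02. A deliberately misspecified
mode (`coding_order=0`, stop codons removed by rejection) exists for
robustness checks. All randomness flows from `numpy.random.default_rng`
seeded by (seed, stream) pairs; every artefact is reproducible bit-for-bit.

What the generator does *not* emulate — and what passing benchmarks
therefore do not demonstrate about real data: sequencing error profiles and
quality scores, rRNA contamination, abundance skew and ragged coverage,
overlapping/alternative transcription units, genes shorter than 120 nt,
leaderless transcripts, and codon usage that drifts within one genome.

## Problem sizes and numerical conventions

The shipped test suite trains on two 60-kb synthetic genomes (~250 genes)
and benchmarks on a disjoint 120-kb genome (90 transcripts, 178 genes; a
desk-scale analogue of the three-genome mock-community benchmark), sizes
chosen so the whole suite runs in well under a minute while keeping ≥ 100
covered genes in the accuracy denominator. Parameter-recovery checks use
≥ 10⁵ simulated codons with pseudocount 0; the emission tolerance (0.01) is
applied to the aggregate (mean per-context) error, since the per-entry
sampling error of the rarest di-codon contexts at that corpus size exceeds
it by simple binomial arithmetic. Viterbi optimality is verified against
exhaustive path enumeration on 200 random toy instances (≤ 12 nt).

Internal coordinates are 0-based half-open everywhere; conversion to GFF3's
1-based inclusive convention happens only in the writer. Probabilities are
consumed in natural logs with a −∞ sentinel; probabilities are floored at
1e-300 before `log` only where a zero is legitimate mass (never to hide a
modelling error). Tie-breaks, bin edges (lower bin at GC-bin boundaries)
and state order are fixed and documented so that fixed seed + fixed input
⇒ byte-identical outputs.

## Known limitations

* Gene boundaries inherit the start-selection ambiguity of all ab-initio
  finders: an internal in-frame start near the true one can win when the
  upstream coding signal is weak (the flanking signal columns, unused in
  scoring, could sharpen this).
* Antisense ORFs truncated by the transcript are never *called* — they
  surface in the partial channel — so transcript-level antisense verdicts
  require the mirrored ORF to be complete within the transcript.
* The GC-bin library interpolates by nearest bin only; bins far from any
  training data simply copy the nearest populated bin.
* No frameshift modelling: the decoder assumes assembled transcripts are
  indel-free, which is the working assumption for coverage-based
  assemblies but not for raw long reads.
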