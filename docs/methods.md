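# Methods

## The problem

Single-molecule long reads (PacBio CLR-class) reach kilobases but carry
~15% raw error, dominated by insertions and deletions and concentrated in
homopolymer runs, where the sequencer misjudges run lengths.  Short reads
(Illumina-class, ~75 bp) are far more accurate (~2% substitutions) and far
deeper.  `hccorrect` corrects long reads (LRs) with short reads (SRs) by
aligning the SRs *to the LRs* and replacing each LR position with the SR
consensus — hybrid error correction for, e.g., full-length cDNA reads where
no trustworthy reference exists per read.

## The pipeline

1. **Homopolymer compression (HC).**  Every run of identical bases is
   replaced by one base; per-position run lengths are retained, so the
   transform is lossless.  In compressed space, run-length errors — the
   dominant LR error mode — vanish, and SR-LR alignment becomes far more
   sensitive.  The cost is information content: adjacent compressed bases
   must differ, so each position carries 3 rather than 4 degrees of
   freedom, and a compressed read of length L locates a position like a
   regular read of length `L·log4(3) ≈ 0.79 L`.  A 75 bp SR compresses to
   ~48 bp (genomic sequence compresses to ~0.65 of its length; i.i.d.
   sequence to 0.75), i.e. roughly a regular 40 bp read — still specific
   enough outside repeats.
2. **SR quality control.**  Compressed SRs with fewer than 40 non-N bases
   or more than one N are dropped (both counts on the compressed sequence;
   an N run compresses to a single N).  Both thresholds are configurable.
3. **Reference construction and alignment.**  Compressed LRs are
   concatenated into chromosome-sized chunks separated by poly-N spacers
   whose length equals the original SR length, so no SR can align across
   two LRs; an index maps global positions back to (LR, offset).
   Compressed SRs are aligned to this reference either by any external
   SAM-emitting aligner (`--aligner-cmd`) or by the built-in test-scale
   aligner (below).  Alignments overlapping a spacer are discarded;
   minus-strand SRs are reverse-complemented (run lengths reversed) so all
   evidence is in LR orientation.
4. **Consensus correction.**  Evidence is stacked per compressed LR
   position.  Four correction-point types are handled: HC points (run
   lengths), point mismatches, deletions, and insertions.  At each covered
   column the covering SRs' runs are decompressed and the plurality
   outcome (a run string, or column deletion) replaces the column; each
   column is treated independently.  An insertion between two columns is
   applied only when strictly more than half of the covering SRs carry an
   insertion there, taking the plurality inserted string.
5. **Decompression and trimming.**  Uncorrected columns are decompressed
   from the LR's own run lengths, and the output (the ecLR) spans the
   left-most to right-most SR-covered point.  The same span of the *raw*
   LR (the rLR) is emitted as the paired uncorrected baseline.

## Consensus details (choices where the procedure is under-determined)

* **Ties** at a column (including base-evidence vs deletion ties) keep the
  LR's own decompressed run: never edit without a strict plurality.
  Insertion-string ties break lexicographically (which also prefers the
  shorter of a prefix pair).  These rules make output byte-deterministic
  and order-invariant in the pileup.
* **Terminal SR columns.**  A homopolymer run truncated by a read
  boundary reports only a lower bound on its length.  A terminal *match*
  therefore contributes coverage but abstains from the run-length vote,
  and insertions involving terminal SR positions (read-end overhangs) are
  dropped; terminal *mismatches* still testify, since base identity is
  informative even when run length is not.  Without this rule,
  boundary-truncated runs measurably outvote correct interior evidence.
  Consequently `depth[i] >= |evidence[i]| + deletions[i]`, with equality
  away from read boundaries.
* **Coverage** means a match/mismatch/deletion event at the position;
  insertions alone confer none.  The minimum depth to edit is 1
  (configurable floor): even a single aligned SR reduces error markedly.

## The built-in aligner

Production use should delegate alignment to a dedicated SR aligner; the
built-in aligner exists so the pipeline runs end-to-end at desk scale with
no external dependency, and it is exact enough to be oracle-tested.

* Scoring: match +1, mismatch −2, gap open −3, gap extend −1 (a gap of
  length k costs 3+k), fixed for reproducibility.
* `align_builtin` (pairwise): optimal affine local alignment of one
  compressed SR against one compressed LR, both orientations; ties break
  toward the lowest LR start, then the + strand.  Verified against an
  independent unbanded brute-force dynamic programme.
* Reference mapping: exact 12-mer seeds grouped into diagonal clusters; a
  window extending `band` (default 20) positions around each cluster is
  aligned **end-to-end on the read** (glocal: free target ends, penalized
  read gaps).  End-to-end alignment mirrors production SR aligners and
  matters here: a purely local alignment clips at LR error clusters,
  leaving coverage gaps selected *for* high error.  Reads with no 12-mer
  placement are retried with 8-mer seeds requiring ≥2 supporting hits —
  at 15% LR error a substantial minority of reads have every 12-mer
  interrupted while remaining confidently alignable.
* `min_score` default 6: on a ~48 bp compressed read this accepts up to
  roughly 25% compressed-space divergence, the plausible envelope under a
  15% clustered raw error rate; beyond that the common-source assumption
  of correction is itself doubtful.  Raise it (and use an external
  aligner) for large references.
* Only primary placements feed correction by default;
  `keep_multimapped = true` admits secondary placements.

## Evaluation metrics

* **Sequence identity I** of a read against its source: matches over all
  alignment columns (matches + mismatches + gap bases on both sides), via
  edit-distance alignment in infix mode (read inside the longer truth).
  A span-based alternative (matches / aligned read length) is selectable;
  every report records which formula produced it.
* **SP** (SR-covered percentage): covered output bases / output length.
* **SCD** (SR-covered depth): per output base, the number of SR alignments
  overlapping its source column; accuracy is reported per SCD bin
  (0..7, >7), mirroring the expectation that accuracy rises with depth and
  plateaus near SGS accuracy around depth 8.

## The simulator

The generator emulates the target data regime rather than any specific
instrument: transcripts of 500–8,000 bp with geometric homopolymer run
lengths (`hp_run_p = 0.65`, giving an HC ratio ≈ 0.65, matching genomic
sequence); long reads with mismatch/insertion/deletion rates
0.01/0.08/0.06 (total 0.15, indel-dominated) where indel rates inside
runs ≥3 are `hp_bias = 3` times the outside rates — outside rates are
rescaled so the *overall* expected rates stay at their stated values;
short reads of fixed 75 bp at configurable mean depth with 2% substitution
error and occasional Ns.  Every read carries provenance to its source
transcript, so evaluation never depends on re-alignment for truth.
Everything is deterministic under one integer seed.

What the simulator does **not** model: chimeras, adapters, quality-score
structure, expression-driven (non-uniform) SR coverage, instrument-specific
error motifs, or splicing structure (correction operates on contiguous
cDNA; isoform analysis is downstream of this tool).  Passing tests
therefore demonstrate algorithmic correctness under the stated error
model, not instrument realism.

## Problem sizes used in tests and in `scripts/acceptance.py`

The end-to-end evaluation uses 20 transcripts (~85 kb of truth), one LR
per transcript at 15% error, and SR depth 5 at 2% error — about 5–6
thousand short reads — which runs in about a minute and gives tight enough
counts for the asserted properties.  Compression statistics use 100
replicates of 10 kb i.i.d. sequence; the aligner oracle comparison uses
500 random instances with reads ≤60 bp against targets ≤300 bp.

## Known limitations

* Per-column independent consensus cannot resolve alignment-ambiguous
  repeats: when equal-scoring alignment paths place the same bases in
  different columns, evidence splits and a spurious copy or a dropped base
  can survive even with error-free SRs (observed at the 0.3% level on
  benign sequence, a few percent across dense LR error clusters where
  coverage also collapses).
* Uncovered-region accuracy is *adversely selected* under uniform SR
  sampling: positions remain uncovered mostly where alignment failed,
  i.e. precisely at the worst LR stretches, so uncovered-region identity
  sits at or below the raw error level and varies noticeably between
  seeds.  With real, expression-driven coverage the uncovered set is
  closer to a random sample of the read.
* Identity measured by optimal realignment slightly under-counts
  clustered indel errors (≈0.02–0.035 absolute at 15% error): chance
  matches inside error clusters are recovered by the aligner.  1−I
  therefore tracks, but does not exactly equal, the generative error rate.
* The built-in aligner indexes the reference in memory and is intended
  for desk-scale data; large-scale runs should configure an external
  aligner.
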