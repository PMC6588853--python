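# Methods

This note documents the generative model, the estimation conventions, the
numerical choices, and what the synthetic-data tests do and do not show.

## The profile as a generative model

One `SequencingProfile` holds everything needed to generate subreads:

* **Pass/length model.** Pass numbers are integers ≥ 1 with empirical
  frequencies; conditional on the pass number, the polymerase read length
  has a binned empirical distribution (default bin width 100 bases —
  real length supports are near-continuous, so storing per-value masses
  would be noise). Sampling draws a bin, then a uniform offset inside it.
* **Unaligned-ratio model.** Head and tail unaligned fractions of the
  polymerase read, binned at 0.01 over [0, 1). A sampled (head, tail)
  pair is rejected and redrawn while head + tail ≥ 0.9; without the guard
  a draw could leave no aligned core. Rejection preserves the marginals
  approximately; realistic profiles place almost no mass near the guard.
* **Context table.** 64 trinucleotide rows of event probabilities
  (match, insertion, deletion, substitution), each summing to 1 within
  1e-9.
* **Size model.** Per-type event-size distributions over integers ≥ 1,
  capped at 20 with the tail lumped into the cap bin (indel sizes are
  overwhelmingly small; the cap keeps tables compact). Substitution sizes
  default to a point mass at 1.
* **Insertion-base table** (per-context frequencies of the inserted base)
  and the **12-category substitution matrix** (each reference base to the
  three alternatives).
* **End error rate**, default 0.4: the per-base error-event rate applied
  inside the presumed-unaligned segments.

Profiles serialize to versioned JSON (schema_version 1) with
full-precision floats; loading validates every invariant and the
k ↔ row-count consistency.

## Event conventions (estimation ≡ simulation)

The estimator and the simulator must share one event algebra or a profile
cannot round-trip. The conventions are:

* A *merged event* is a maximal run of one error op; every matched base
  is its own event. Denominators are event counts, so a context row is
  "events of each type among events anchored at this context".
* An event's **context** is the reference 3-mer whose *last* base is the
  event's first reference base; an insertion, which consumes no reference
  base, anchors at the base immediately preceding the inserted run. This
  makes homopolymer-interior positions carry homopolymer contexts and is
  computable in one left-to-right scan. Contexts are always read on the
  reference forward strand; the first k−1 positions of a contig (or any
  window touching an ambiguous base) get the `NOCTX` sentinel and are
  tallied into a separate marginal bucket.
* Coordinates are 0-based half-open throughout; SAM's 1-based convention
  is converted at the I/O boundary. Only primary alignments are counted
  (secondary/supplementary records would double-count bases). `M` CIGAR
  ops are resolved into =/X via the MD tag when present, otherwise via
  the reference.

## The error walk

Naively drawing one event per template position from the context row and
emitting it does **not** reproduce the row in re-estimation, for two
reasons: insertions need an anchoring match on a consumed base (which a
profiler counts as an extra match event, deflating error rates by
1/(1+p_i)), and independently drawn adjacent deletions merge into one
larger event (deflating deletion rates and distorting the size law). The
walk therefore decouples the draws:

1. At template position *i* with row (m, p_i, p_d, p_s), the
   base-consuming event is drawn from (m, p_d, p_s) renormalized.
2. After the consumed base, an insertion run is emitted with probability
   p_i/(1−p_i). Insertions then constitute a fraction p_i of all anchored
   events, exactly, and the anchor is the preceding consumed base — the
   estimator's insertion convention.
3. A deletion drawn immediately after a deletion event (with no match or
   insertion between) would be merged by any profiler, so it is excluded
   and the split renormalized; to cancel the resulting deficit the nominal
   deletion probability is boosted to d/(1 − d(1 − p_i/(1−p_i))), which
   makes the stationary merged deletion frequency equal the row value.
   Adjacent substitution runs are allowed to merge: substitution sizes are
   not part of the indel size law, and the bias is O(p_s²).

Residual deviations between a profile and its re-estimate from simulated
data are second-order (interior bases of multi-base events host no
insertion opportunity; multi-base events anchor at their first base but
donate their insertion opportunity at their last). Empirically, a 30×
simulation over 1 Mb under a profile with homopolymer contexts at twice
the error rate re-estimates every context row within ±0.01 absolute, and
indel size histograms within 3 binomial SE per bin; the test suite asserts
exactly this.

Both one-uniform decisions per position are taken from a precomputed
six-cell cumulative partition per context, with buffered uniforms; the
walk covers ~0.5 Mb/s/core in pure Python, which sets the problem sizes
used in the tests (30 Mb for the round trip, a few Mb elsewhere).

* **Strand handling.** Pass 0 reads the template as drawn; each later pass
  flips strand. Error decisions are always made on the reference-forward
  slice and the subread is reverse-complemented afterwards, so generated
  contexts coincide with the (reference-forward) contexts the estimator
  assigns. Deciding errors in template orientation instead would fold each
  context with an anchor-shifted reverse complement and break round-trip
  recovery for any strand-asymmetric table.
* **End segments.** The drawn head/tail fractions are mapped to planned
  polymerase coordinates (template length × pass count) and intersected
  with each pass; inside them each template base independently suffers an
  error event with the preset probability (0.4 by default, chosen by
  comparison of candidate presets in the source analyses), with the type
  split taken from the profile's marginal row, and sizes/bases from the
  same models. Insertions there keep the anchor-match form so that one
  event consumes one base, making "error events per segment base" equal
  the preset rate with size-1 models.
* **Template length** is `target_polymerase_length // n_pass`: all passes
  are full passes, matching the observed trade-off between template
  length and pass count. The realized polymerase length then drifts from
  the target by the indel balance; the length model is binned, so this is
  accepted.
* Deletions and substitutions are truncated at region and sequence
  boundaries; contigs are linear (no wrap-around); adapters, CCS
  consensus and chimeric artifacts are not modeled.
* FASTQ qualities are a constant Phred score (default 12) because
  per-base QVs carry no error information on the target platform; FASTA
  output is available.
* Read naming is `movie/zmw/qstart_qend` with the ZMW as the running read
  index and q-coordinates accumulated over emitted subread lengths
  (adapters are not modeled, so passes abut).

## Estimation details

* Event-rate denominators are event counts under the convention above;
  per-base rates (error bases per aligned reference base) are also
  recorded in the profile metadata and are exactly the planted per-base
  rates for any generator, merged or not.
* Context rows with zero observations receive the context-averaged
  marginal row and are flagged in `fallback_contexts`, so the simulator
  never meets an undefined context; likewise insertion-base rows.
* Reads whose names do not parse as subread names are skipped and counted
  unless `--single-pass` is given, in which case each becomes a 1-pass
  polymerase read — this lets the profiler run on non-PacBio-named data
  without silently corrupting the pass model.
* The estimator streams records and is deterministic: identical inputs
  produce a bit-identical profile.
* Pass numbers count subreads present in the input; the unaligned span of
  a polymerase read runs from `qstart + clip_head` of its first aligned
  subread to `qend − clip_tail` of its last, in polymerase coordinates.

## Synthetic data: what it shows and what it does not

`fixtures.random_genome` draws i.i.d. bases at a chosen GC fraction;
`fixtures.oracle_reads` plants errors with one categorical draw per
template base (size always 1, context-free), deliberately sharing no code
with the simulator's walk so profiler round-trip tests are not
self-confirming; `fixtures.truth_to_sam` emits the ground truth as primary
SAM records with =/X/I/D CIGARs, as if an external aligner had been run.
Under the merged-event convention the oracle's planted per-base rates
(p_i, p_d, p_s) imply event frequencies
(m + p_i, p_i, p_d(1−p_d), p_s(1−p_s)) (normalized), since each planted
insertion leaves an anchoring match and adjacent same-type errors merge;
tests compare context rows against this closed form, and mean per-base
rates against the planted values directly.

Random genomes have no repeats, no isochores and uniform coverage, and
the oracle has no context dependence, so passing these tests demonstrates
the correctness of the estimation/simulation algebra — not that any
bundled profile matches a particular instrument. Real-data profiles
depend on the aligner used to produce the input alignments, which is
outside this package's scope (alignments are consumed, never produced).

## Known limitations

* Errors are drawn independently per pass; real multi-pass data has
  molecule-level error correlations, so pass-consensus experiments on
  simulated data will look slightly better than reality.
* The error rate is positionally homogeneous outside the end segments
  (a single-interval model); the mild U-shape of real per-position error
  rates is not reproduced.
* k is fixed at 3; the profile schema records k, but the estimator and
  simulator only implement trinucleotide contexts.
* The unaligned-ratio guard (head + tail < 0.9) slightly reshapes
  pathological ratio models.
* `--threads` parallelizes read generation with per-read generators
  derived from (seed, read index); output is byte-identical to the
  single-threaded run, and in CPython the benefit is modest since the
  walk is GIL-bound.
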