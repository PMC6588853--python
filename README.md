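# smrtsim

Simulation of PacBio/SMRT multi-pass sequencing reads, with
alignment-based estimation of the sequencing-error profile.

Single-molecule real-time sequencing reads a circular template several
times; the full output of one ZMW (the *polymerase read*) splits into
*subreads* that alternate between the forward and reverse strands of the
template. Raw subreads carry ~15% errors dominated by indels, the error
rate depends strongly on local sequence context (homopolymer-adjacent
trinucleotides in particular), the noisy read ends often fail to align at
all, and on the Sequel platform the per-base quality values are constant
and carry no error information. Tools for long-read analysis — aligners,
assemblers, SV callers — need simulated reads with known ground truth that
reproduce all of these properties. `smrtsim` is for developers and
evaluators of such tools.

## The model

A **sequencing profile** is the full generative model, estimated from
alignments of real subreads to a reference and stored as versioned JSON:

| component | content |
|---|---|
| pass/length model | distribution of pass numbers `n`, and for each `n` a binned distribution of polymerase read lengths (long templates cycle fewer times) |
| unaligned-ratio model | distributions of the head/tail fractions of a polymerase read that fail to align |
| context table | for each of the 4³ = 64 reference trinucleotides, the probabilities (m, p_i, p_d, p_s) of the four event types: match, insertion, deletion, substitution |
| size model | per error type, the distribution of event sizes (a maximal run of one error op is a single event) |
| insertion bases | per context, the frequencies of the inserted base |
| substitution matrix | the 12 ordered ref→read base categories |
| end error rate | preset per-base error-event rate inside the presumed-unaligned ends (default **0.4**) |

**Estimation** scans primary alignments left to right: every matched base
is one event, every maximal run of one error op is one event with a size,
and each event is keyed by the reference 3-mer ending at its first
reference base (insertions anchor at the base preceding the inserted run).
Per-context event frequencies give the context table directly.

**Simulation** inverts this convention exactly. A template of length
`target_length // n_pass` is sampled uniformly from the reference (strand
uniform, Ns replaced); each pass walks the template and draws events so
that the *merged-event frequencies a profiler would count reproduce the
context row* — the consuming event comes from (m, p_d, p_s) renormalized
and an insertion run follows the consumed base with probability
p_i/(1−p_i); see `docs/methods.md` for why. Positions falling in the
presumed-unaligned head/tail segments instead get errors at the preset
0.4 rate. Every subread ships with a ground-truth edit script that
reproduces it byte-exactly from the reference.

## Worked example

Everything below runs offline from synthetic data:

```sh
# 1. a 50 kb random genome plus "real" reads with planted per-base error
#    rates (10% insertion, 4% deletion, 1% substitution), aligned as SAM
smrtsim fixtures --out fix --length 50000 --n-reads 60 --read-length 4000 \
    --passes 2 --rates 0.1,0.04,0.01 --seed 7

# 2. estimate a profile from those alignments
smrtsim profile --alignments fix.sam --reference fix.genome.fasta \
    --out est.json --report est.tsv

# 3. simulate 5x coverage under the estimated profile
smrtsim simulate --reference fix.genome.fasta --profile est.json \
    --depth 5 --seed 11 --out sim
# -> 60 subreads from 30 polymerase reads; realized depth 5.08, error rate 0.1514

# 4. summarize the simulated corpus from its ground truth
smrtsim eval --truth sim.truth.tsv --reference fix.genome.fasta --out eval
head -3 eval.rates.tsv
```

```
# rates are error bases per template (reference) base
mode    aligned_rate_read  aligned_rate_base  error_rate  insertion  deletion   substitution
truth   1                  1                  0.151359    0.101202   0.0400041  0.0101525
```

The planted per-base rates (0.10, 0.04, 0.01) survive the full loop —
estimation, re-simulation, ground-truth recount — to three decimals. The
`est.tsv` report holds the 64-row per-trinucleotide event counts and rates;
`sim.fastq` carries constant quality characters (Phred 12 by default,
because QVs are non-informative on the target platform), `sim.maf` the
pairwise ground-truth alignments, and `sim.truth.tsv` one row per subread
with template coordinates, strand, pass index, presumed-unaligned extents
and the complete edit script.

`ks_statistic`, `length_distribution`, `error_size_distribution` and
`per_kmer_error_rates` in `smrtsim.evaluate` provide the two-sample
Kolmogorov–Smirnov statistic and the histogram comparisons used to judge
simulated against real corpora.

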