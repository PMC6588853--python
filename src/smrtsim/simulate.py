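"""Multi-pass polymerase read simulation under a sequencing profile.

A polymerase read is generated by (1) drawing a pass number and a target
polymerase read length from their joint model, (2) sampling an error-free
template of length ``target // n_pass`` uniformly from the reference
(strand uniform, Ns replaced at random), and (3) walking the template once
per pass, alternating strands, while introducing errors.

Two error regimes apply within one polymerase read. Template positions
mapped into the presumed-unaligned head/tail segments (fractions drawn once
per read from the unaligned-ratio model) receive errors at a flat preset
rate (default 0.4) with the error-type split taken from the profile's
marginal row. All other positions draw their event from the context row of
the reference 3-mer ending at the current position. Event sizes, inserted
bases and substitution outcomes come from the profile's size model,
insertion-base table and substitution matrix.

Error decisions are made on the reference-forward strand of every pass and
the emitted subread is reverse-complemented afterwards for reverse-strand
passes. This keeps the realized per-context event rates identical to the
rates an alignment-based profiler measures (contexts in reference-forward
orientation), so estimation and simulation invert each other.

The context walk is constructed so that the *merged-event* frequencies a
profiler counts reproduce the context row exactly. At each template
position with row (m, p_i, p_d, p_s): the base-consuming event is drawn
from (m, p_d, p_s) renormalized, and independently an insertion run is
emitted after the consumed base with probability p_i / (1 - p_i) (so that
insertions make up a fraction p_i of all anchored events). A consuming event
immediately following a deletion with no intervening match or insertion
cannot be another deletion — a profiler would merge such neighbours into
one larger event and distort the size law — so the walk excludes it and
renormalizes, an order-p^2 perturbation of the nominal rates. Adjacent
substitution runs are allowed to merge: substitution sizes are not part of
the indel size law and the resulting bias is also order p^2.

Every subread carries a ground-truth record with its edit script; applying
the script to the oriented template reproduces the subread byte-exactly.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .edits import Script, flip_script, revcomp, script_error_counts
from .profile import (
    BASE_INDEX,
    BASES,
    SUBSTITUTION_ALTS,
    PassLengthModel,
    SequencingProfile,
    kmer_codes,
    marginal_event_distribution,
)


class SimulationError(ValueError):
    """Invalid simulation configuration or infeasible request."""


@dataclass
class SimulationConfig:
    """Run-level knobs; exactly one of ``depth`` / ``n_reads`` must be set."""

    n_reads: int | None = None
    depth: float | None = None
    seed: int | None = None
    #: overrides the profile's preset end-segment error rate when set
    end_error_rate: float | None = None
    min_length: int = 100
    max_length: int = 200_000
    quality: int = 12
    movie: str = "msim0"
    threads: int = 1

    def validate(self) -> None:
        if (self.n_reads is None) == (self.depth is None):
            raise SimulationError("exactly one of n_reads and depth must be set")
        if self.n_reads is not None and self.n_reads < 1:
            raise SimulationError("n_reads must be >= 1")
        if self.depth is not None and self.depth <= 0:
            raise SimulationError("depth must be > 0")
        if not (0 < self.min_length < self.max_length):
            raise SimulationError("length caps must satisfy 0 < min < max")
        if self.end_error_rate is not None and not (0 <= self.end_error_rate < 1):
            raise SimulationError("end_error_rate must be in [0, 1)")
        if not (0 <= self.quality <= 93):
            raise SimulationError("quality must be a Phred value in [0, 93]")
        if self.threads < 1:
            raise SimulationError("threads must be >= 1")


@dataclass
class TemplateDraw:
    """An error-free template sampled from the reference (Ns replaced)."""

    contig: str
    start: int
    end: int
    strand: str
    sequence: str


@dataclass
class TruthRecord:
    """Ground truth for one emitted subread.

    ``script`` is in read orientation: applied to the oriented template of
    this pass (the template if ``strand == template_strand``, else its
    reverse complement) it reproduces ``read`` exactly. ``head_len`` /
    ``tail_len`` are the presumed-unaligned extents at the start/end of the
    subread, in template positions, read orientation.
    """

    name: str
    contig: str
    start: int
    end: int
    strand: str
    template_strand: str
    pass_index: int
    n_pass: int
    head_len: int
    tail_len: int
    script: Script = field(default_factory=list)
    read: str | None = None


# ---------------------------------------------------------------------------
# runtime tables

def _joint_cells(rows: np.ndarray, exclude: int | None = None) -> np.ndarray:
    """Map event rows (m, p_i, p_d, p_s) to the cumulative six-cell partition
    deciding the consuming event and the insertion flag with one uniform.

    Cells, in order: (match, del, sub) without a following insertion, then
    the same three with one; the consuming split is (m, p_d, p_s)
    renormalized (with deletion excluded, for the same-type-adjacency rule,
    when ``exclude`` is set) and the insertion probability is
    p_i / (1 - p_i), which makes insertions a fraction p_i of all merged
    events a profiler would count.

    Because a deletion drawn right after a deletion (with no insertion
    between) is suppressed, the nominal deletion probability in the
    unexcluded table is boosted to d / (1 - d (1 - odds)); the stationary
    frequency of deletion events among consuming draws then equals d
    exactly, cancelling the exclusion bias.
    """
    rows = np.atleast_2d(rows)
    base = rows[:, [0, 2, 3]].copy()
    base_sum = base.sum(axis=1, keepdims=True)
    base[(base_sum == 0)[:, 0], 0] = 1.0  # no consuming mass at all: match
    base_sum[base_sum == 0] = 1.0
    cons = base.copy()
    if exclude is not None:
        cons[:, exclude] = 0.0
    s = cons.sum(axis=1, keepdims=True)
    # nothing left to draw after the exclusion: allow the adjacency
    degenerate = (s == 0)[:, 0]
    cons[degenerate] = base[degenerate]
    s[s == 0] = base_sum[s == 0]
    cons = cons / s
    pi = np.clip(rows[:, 1], 0.0, 0.999999)
    odds = np.clip(pi / (1.0 - pi), 0.0, 1.0)[:, None]
    if exclude is None:
        # exclusion-bias compensation for deletions (see docstring)
        d = cons[:, 1:2]
        beta = 1.0 - odds
        d_new = np.clip(d / np.clip(1.0 - d * beta, 1e-9, None), 0.0, 0.999999)
        other = 1.0 - d
        scale = np.where(other > 0, (1.0 - d_new) / np.where(other > 0, other, 1.0), 0.0)
        cons = np.concatenate([cons[:, 0:1] * scale, d_new, cons[:, 2:3] * scale], axis=1)
    cells = np.concatenate([cons * (1.0 - odds), cons * odds], axis=1)
    return np.cumsum(cells / cells.sum(axis=1, keepdims=True), axis=1)


class _Runtime:
    """Cumulative-probability tables precomputed from a profile for the walk."""

    def __init__(self, profile: SequencingProfile, end_rate: float):
        self.end_rate = float(end_rate)
        m = profile.context_table.matrix()  # (64, 4): match, ins, del, sub
        marg = np.atleast_2d(marginal_event_distribution(profile))
        # six-cell tables per context, and variants excluding deletion /
        # substitution for the same-type-adjacency rule
        self.cells = _joint_cells(m)
        self.cells_nodel = _joint_cells(m, exclude=1)
        self.marg_cells = _joint_cells(marg)[0]
        self.marg_cells_nodel = _joint_cells(marg, exclude=1)[0]

        # flat-rate regime: error-type split from the marginal row
        err = marg[0, 1:4].copy()
        if err.sum() <= 0:
            err = np.full(3, 1.0 / 3.0)
        err = err / err.sum()
        self.usplit = np.cumsum(err)
        e = err.copy()
        e[1] = 0.0
        self.usplit_nodel = np.cumsum(e / e.sum()) if e.sum() > 0 else self.usplit

        self.size_support: dict[str, np.ndarray] = {}
        self.size_cum: dict[str, np.ndarray] = {}
        for t in ("insertion", "deletion", "substitution"):
            d = profile.sizes.dist(t)
            self.size_support[t] = d.support.astype(np.int64)
            self.size_cum[t] = np.cumsum(d.probabilities)

        self.ins_cum = np.cumsum(profile.insertion_bases.matrix(), axis=1)
        self.marg_ins_cum = np.cumsum(profile.insertion_bases.matrix().mean(axis=0))
        self.sub_cum = [np.cumsum(profile.substitutions.rows[b]) for b in BASES]
        self.sub_alts = [SUBSTITUTION_ALTS[b] for b in BASES]

    def draw_size(self, error_type: str, u: float) -> int:
        cum = self.size_cum[error_type]
        i = min(int(np.searchsorted(cum, u, side="right")), cum.size - 1)
        return int(self.size_support[error_type][i])


# ---------------------------------------------------------------------------
# the error walk

def _walk(seq: str, codes: np.ndarray, regions, rt: _Runtime, rng: np.random.Generator):
    """Left-to-right error walk over ``seq``.

    ``regions`` is a list of ``(start, end, rate)`` tiles covering the
    sequence in order; ``rate=None`` selects the context regime, a float the
    flat-rate regime. Deletions and substitutions are truncated at region
    (hence sequence) boundaries. Returns ``(read, script)`` with the script
    in the walked orientation.
    """
    out: list[str] = []
    script: Script = []
    BUF = 8192
    buf = rng.random(BUF)
    bi = 0
    last = 0  # 2 when a deletion event immediately precedes, else 0

    def take() -> float:
        nonlocal bi, buf
        if bi >= BUF:
            buf = rng.random(BUF)
            bi = 0
        v = buf[bi]
        bi += 1
        return v

    def emit_match(a: int, b: int) -> None:
        if b > a:
            if script and script[-1][0] == "=":
                script[-1] = ("=", script[-1][1] + (b - a), "")
            else:
                script.append(("=", b - a, ""))
            out.append(seq[a:b])

    def emit_insertion(anchor: int, contextual: bool) -> None:
        # inserted run placed right after the consumed base at ``anchor``,
        # where a profiler anchors its context
        s = rt.draw_size("insertion", take())
        c = codes[anchor] if (contextual and anchor >= 0) else -1
        icum = rt.ins_cum[c] if c >= 0 else rt.marg_ins_cum
        chars = []
        for _ in range(s):
            u2 = take()
            chars.append(BASES[0 if u2 < icum[0] else 1 if u2 < icum[1] else 2 if u2 < icum[2] else 3])
        script.append(("I", s, "".join(chars)))
        out.append("".join(chars))

    def emit_substitution(i: int, rend: int) -> int:
        s = min(rt.draw_size("substitution", take()), rend - i)
        chars = []
        for j in range(i, i + s):
            bc = BASE_INDEX[seq[j]]
            scum = rt.sub_cum[bc]
            u2 = take()
            chars.append(rt.sub_alts[bc][0 if u2 < scum[0] else 1 if u2 < scum[1] else 2])
        script.append(("X", s, "".join(chars)))
        out.append("".join(chars))
        return s

    for rs, rend, rate in regions:
        i = rs
        run = i
        while i < rend:
            if bi >= BUF:
                buf = rng.random(BUF)
                bi = 0
            uu = buf[bi]
            bi += 1
            if rate is None:
                # one uniform decides the consuming event and whether an
                # insertion run follows the consumed base (six cells)
                c = codes[i]
                if c >= 0:
                    cells = (rt.cells_nodel if last == 2 else rt.cells)[c]
                else:
                    cells = rt.marg_cells_nodel if last == 2 else rt.marg_cells
                if uu < cells[0]:  # plain match, the common case
                    i += 1
                    last = 0
                    continue
                want_ins = uu >= cells[2]
                cons = (0 if uu < cells[0] else 1 if uu < cells[1] else 2) if not want_ins \
                    else (0 if uu < cells[3] else 1 if uu < cells[4] else 2)
                if cons == 0:
                    i += 1
                    emit_match(run, i)
                    anchor = i - 1
                    last = 0
                elif cons == 1:
                    emit_match(run, i)
                    s = min(rt.draw_size("deletion", take()), rend - i)
                    script.append(("D", s, ""))
                    i += s
                    anchor = i - 1
                    last = 2
                else:
                    emit_match(run, i)
                    s = emit_substitution(i, rend)
                    i += s
                    anchor = i - 1
                    last = 0
                if want_ins:
                    emit_insertion(anchor, contextual=True)
                    last = 0  # the inserted run separates same-type neighbours
                run = i
            else:
                # flat-rate regime: one error event per template base with
                # probability ``rate``; an insertion keeps its anchor base
                # as a match so the event still consumes one base
                if uu >= rate:
                    i += 1
                    last = 0
                    continue
                split = rt.usplit_nodel if last == 2 else rt.usplit
                u2 = take()
                ev = 1 if u2 < split[0] else 2 if u2 < split[1] else 3
                emit_match(run, i)
                if ev == 1:
                    i += 1
                    emit_match(i - 1, i)
                    emit_insertion(i - 1, contextual=False)
                    last = 0
                elif ev == 2:
                    s = min(rt.draw_size("deletion", take()), rend - i)
                    script.append(("D", s, ""))
                    i += s
                    last = 2
                else:
                    s = emit_substitution(i, rend)
                    i += s
                    last = 0
                run = i
        emit_match(run, rend)
    return "".join(out), script


# ---------------------------------------------------------------------------
# sampling operations

def sample_pass_and_length(
    model: PassLengthModel,
    rng: np.random.Generator,
    min_length: int | None = None,
    max_length: int | None = None,
) -> tuple[int, int]:
    """Draw a pass number, then a polymerase length from that pass's
    distribution, clipped to the configured caps."""
    n = int(model.pass_distribution.sample(rng))
    length = int(round(model.length_by_pass[n].sample(rng)))
    if min_length is not None:
        length = max(length, min_length)
    if max_length is not None:
        length = min(length, max_length)
    return n, max(length, n)


def replace_ns(sequence: str, rng: np.random.Generator) -> str:
    """Replace every N with a uniformly random base; other letters rejected."""
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise SimulationError(f"sequence contains non-ACGTN letters: {sorted(bad)}")
    if "N" not in sequence:
        return sequence
    chars = list(sequence)
    for i, ch in enumerate(chars):
        if ch == "N":
            chars[i] = BASES[int(rng.integers(4))]
    return "".join(chars)


def sample_template(
    reference: Mapping[str, str],
    target_length: int,
    n_pass: int,
    rng: np.random.Generator,
) -> TemplateDraw:
    """Sample an error-free template of length ``target_length // n_pass``.

    The contig is chosen with probability proportional to its number of
    eligible start positions, the start uniformly among them, and the strand
    uniformly; reverse-strand templates are reverse-complemented so the
    stored sequence is in template orientation.
    """
    t_len = max(1, target_length // n_pass)
    names = sorted(reference)
    weights = np.array([max(0, len(reference[c]) - t_len + 1) for c in names], dtype=float)
    if weights.sum() == 0:
        raise SimulationError(
            f"no contig can hold a template of length {t_len} "
            f"(target polymerase length {target_length}, {n_pass} passes)")
    probs = weights / weights.sum()
    ci = int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))
    ci = min(ci, len(names) - 1)
    contig = names[ci]
    start = int(rng.integers(0, int(weights[ci])))
    end = start + t_len
    seq = reference[contig][start:end]
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        seq = revcomp(seq)
    seq = replace_ns(seq, rng)
    return TemplateDraw(contig=contig, start=start, end=end, strand=strand, sequence=seq)


def apply_context_errors(
    sequence: str, profile: SequencingProfile, rng: np.random.Generator
) -> tuple[str, Script]:
    """Walk a sequence under the context-specific error model."""
    rt = _Runtime(profile, profile.end_error_rate)
    codes = kmer_codes(sequence)
    return _walk(sequence, codes, [(0, len(sequence), None)], rt, rng)


def apply_uniform_errors(
    sequence: str, rate: float, profile: SequencingProfile, rng: np.random.Generator
) -> tuple[str, Script]:
    """Walk a sequence at a flat error-event rate (the end-segment regime)."""
    if not (0 <= rate < 1):
        raise SimulationError(f"rate {rate!r} must be in [0, 1)")
    rt = _Runtime(profile, rate)
    codes = kmer_codes(sequence)
    return _walk(sequence, codes, [(0, len(sequence), rate)], rt, rng)


def generate_polymerase_read(
    template: TemplateDraw,
    n_pass: int,
    profile: SequencingProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    zmw: int = 1,
    runtime: _Runtime | None = None,
) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Emit the subreads of one polymerase read, with ground truth.

    Pass 0 reads the template as drawn; each subsequent pass flips strand.
    The head/tail unaligned fractions are drawn once per polymerase read and
    mapped onto each pass's template positions; those stretches are walked
    at the preset end-segment rate, the rest under the context model.
    """
    rate = config.end_error_rate if config.end_error_rate is not None else profile.end_error_rate
    rt = runtime if runtime is not None else _Runtime(profile, rate)
    forward = template.sequence if template.strand == "+" else revcomp(template.sequence)
    codes = kmer_codes(forward)
    t_len = len(forward)
    planned = t_len * n_pass
    h_ratio, t_ratio = profile.unaligned.sample_pair(rng)
    head = int(round(h_ratio * planned))
    tail = int(round(t_ratio * planned))

    subreads: list[tuple[str, str]] = []
    truths: list[TruthRecord] = []
    qstart = 0
    for i in range(n_pass):
        head_in = min(max(head - i * t_len, 0), t_len)
        tail_in = min(max((i + 1) * t_len - (planned - tail), 0), t_len)
        if head_in + tail_in > t_len:
            tail_in = t_len - head_in
        strand = "+" if (template.strand == "+") == (i % 2 == 0) else "-"
        if strand == "-":
            a, b = tail_in, t_len - head_in  # read head sits at the forward-slice end
        else:
            a, b = head_in, t_len - tail_in
        regions = [r for r in ((0, a, rate), (a, b, None), (b, t_len, rate)) if r[1] > r[0]]
        read_f, script_f = _walk(forward, codes, regions, rt, rng)
        if strand == "-":
            read, script = revcomp(read_f), flip_script(script_f)
        else:
            read, script = read_f, script_f
        qend = qstart + len(read)
        name = f"{config.movie}/{zmw}/{qstart}_{qend}"
        subreads.append((name, read))
        truths.append(TruthRecord(
            name=name, contig=template.contig, start=template.start, end=template.end,
            strand=strand, template_strand=template.strand, pass_index=i, n_pass=n_pass,
            head_len=head_in, tail_len=tail_in, script=script, read=read,
        ))
        qstart = qend
    return subreads, truths


# ---------------------------------------------------------------------------
# run driver

def _read_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_run(
    reference: Mapping[str, str],
    profile: SequencingProfile,
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[TruthRecord], dict]:
    """Simulate a full run; returns (reads, truths, report).

    All randomness for polymerase read ``i`` flows from a generator derived
    from ``(config.seed, i)``, so output is independent of threading and
    chunking; with ``depth`` set, reads are emitted in index order until the
    walked template bases reach ``depth * total reference length``.
    """
    config.validate()
    genome_size = sum(len(s) for s in reference.values())
    if genome_size == 0:
        raise SimulationError("reference is empty")
    rate = config.end_error_rate if config.end_error_rate is not None else profile.end_error_rate
    rt = _Runtime(profile, rate)
    seed = config.seed if config.seed is not None else 0

    def make(index: int):
        rng = _read_rng(seed, index)
        n_pass, length = sample_pass_and_length(
            profile.pass_length, rng, config.min_length, config.max_length)
        template = sample_template(reference, length, n_pass, rng)
        subs, truths = generate_polymerase_read(
            template, n_pass, profile, config, rng, zmw=index + 1, runtime=rt)
        walked = (template.end - template.start) * n_pass
        return subs, truths, walked

    def run_chunk(indices):
        if config.threads > 1:
            with ThreadPoolExecutor(max_workers=config.threads) as pool:
                return list(pool.map(make, indices))
        return [make(i) for i in indices]

    results = []
    if config.n_reads is not None:
        results = run_chunk(range(config.n_reads))
    else:
        target = config.depth * genome_size
        walked_total = 0
        index = 0
        while walked_total < target:
            chunk = run_chunk(range(index, index + 32))
            for item in chunk:
                results.append(item)
                walked_total += item[2]
                if walked_total >= target:
                    break
            index += 32

    reads: list[tuple[str, str]] = []
    truths: list[TruthRecord] = []
    template_bases = 0
    counts = {"ins_bases": 0, "del_bases": 0, "sub_bases": 0, "read_bases": 0}
    for subs, trs, walked in results:
        reads.extend(subs)
        truths.extend(trs)
        template_bases += walked
        for tr in trs:
            c = script_error_counts(tr.script)
            for key in counts:
                counts[key] += c[key]
    err_bases = counts["ins_bases"] + counts["del_bases"] + counts["sub_bases"]
    report = {
        "n_polymerase_reads": len(results),
        "n_subreads": len(truths),
        "template_bases": template_bases,
        "read_bases": counts["read_bases"],
        "realized_depth": template_bases / genome_size,
        "insertion_bases": counts["ins_bases"],
        "deletion_bases": counts["del_bases"],
        "substitution_bases": counts["sub_bases"],
        "error_rate": err_bases / template_bases if template_bases else 0.0,
    }
    return reads, truths, report
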