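"""Estimate a sequencing profile from primary alignments of real reads.

The estimator consumes pairwise alignments (SAM/BAM) of subreads named by
the PacBio convention ``movie/zmw/qstart_qend`` plus the reference FASTA,
and produces a :class:`~smrtsim.profile.SequencingProfile`:

* subreads are grouped by ZMW hole; the pass number is the subread count
  and the polymerase length the maximal ``qend``, giving the joint
  pass-number / read-length model;
* the unaligned head/tail fractions of each polymerase read are measured in
  polymerase coordinates (``qstart`` of the first aligned subread plus its
  head clip, and symmetrically at the tail);
* every alignment is scanned left to right: each matched base is one match
  event, and each maximal run of one error op is one event with a size.
  An event's context is the reference 3-mer whose last base is the event's
  first reference base; an insertion (which consumes no reference base) is
  anchored at the base immediately preceding the inserted run. Contexts are
  always read on the reference forward strand. The first two positions of a
  contig (and any window touching an ambiguous base) get the ``NOCTX``
  sentinel and are tallied into a separate marginal bucket.

Per-context event-type frequencies form the 64-row context table; event
sizes (pooled over contexts, capped) the size model; inserted bases per
context the insertion-base table; and ref-to-read base pairs inside
substitution events the twelve-cell substitution matrix. Contexts with zero
observations receive the context-averaged marginal row and are flagged, so
a simulator never meets an undefined context.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import io as sio
from .edits import AlignmentRecord
from .profile import (
    BASES,
    BASE_INDEX,
    DEFAULT_END_ERROR_RATE,
    DEFAULT_LENGTH_BIN,
    DEFAULT_RATIO_BIN,
    DEFAULT_SIZE_CAP,
    KMERS,
    NOCTX,
    SUBSTITUTION_ALTS,
    ContextErrorTable,
    EmpiricalDistribution,
    InsertionBaseTable,
    PassLengthModel,
    SequencingProfile,
    SizeModel,
    SubstitutionMatrix,
    UnalignedRatioModel,
    kmer_codes,
)

log = logging.getLogger(__name__)

_NAME_RE = re.compile(r"^(?P<movie>[^/]+)/(?P<zmw>\d+)/(?P<qstart>\d+)_(?P<qend>\d+)$")


class ReadNameError(ValueError):
    """A read name does not follow the movie/zmw/qstart_qend convention."""

    def __init__(self, name: str, reason: str = "not of the form movie/zmw/qstart_qend"):
        self.name = name
        super().__init__(f"cannot parse read name {name!r}: {reason}")


class EstimationError(ValueError):
    """Estimation is impossible (e.g. no usable alignments)."""


def parse_read_name(name: str) -> tuple[str, int, int, int]:
    m = _NAME_RE.match(name)
    if not m:
        raise ReadNameError(name)
    qstart, qend = int(m["qstart"]), int(m["qend"])
    if qstart >= qend:
        raise ReadNameError(name, f"qstart {qstart} >= qend {qend}")
    return m["movie"], int(m["zmw"]), qstart, qend


@dataclass
class ZmwGroup:
    """All subreads observed from one ZMW hole."""

    movie: str
    zmw: int
    subreads: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_pass(self) -> int:
        return len(self.subreads)

    @property
    def polymerase_length(self) -> int:
        return max(qend for _, qend in self.subreads)


def group_by_zmw(names: Iterable[str]) -> tuple[list[ZmwGroup], list[str]]:
    """Group subread names by (movie, zmw); unparseable names are returned
    separately rather than raised."""
    groups: dict[tuple[str, int], ZmwGroup] = {}
    skipped: list[str] = []
    for name in names:
        try:
            movie, zmw, qstart, qend = parse_read_name(name)
        except ReadNameError:
            skipped.append(name)
            continue
        key = (movie, zmw)
        if key not in groups:
            groups[key] = ZmwGroup(movie=movie, zmw=zmw)
        groups[key].subreads.append((qstart, qend))
    for g in groups.values():
        g.subreads.sort()
    return list(groups.values()), skipped


def estimate_pass_length_model(
    groups: Iterable[ZmwGroup], bin_width: float = DEFAULT_LENGTH_BIN
) -> PassLengthModel:
    """Relative pass-number frequencies plus, per pass number, the binned
    distribution of polymerase read lengths."""
    lengths_by_pass: dict[int, list[int]] = defaultdict(list)
    for g in groups:
        lengths_by_pass[g.n_pass].append(g.polymerase_length)
    if not lengths_by_pass:
        raise EstimationError("no ZMW groups to estimate a pass/length model from")
    counts = {n: len(v) for n, v in lengths_by_pass.items()}
    return PassLengthModel(
        pass_distribution=EmpiricalDistribution.from_counts(counts),
        length_by_pass={
            n: EmpiricalDistribution.from_values(v, bin_width)
            for n, v in lengths_by_pass.items()
        },
    )


def estimate_unaligned_ratio(
    records: Iterable[AlignmentRecord],
    groups: Mapping[str, ZmwGroup],
    bin_width: float = DEFAULT_RATIO_BIN,
) -> UnalignedRatioModel:
    """Binned head/tail unaligned-fraction distributions over polymerase reads.

    The aligned span of a polymerase read, in polymerase coordinates, runs
    from ``qstart + clip_head`` of its first aligned subread to
    ``qend - clip_tail`` of its last; groups with no aligned subread are
    excluded (their ratio is undefined) and logged.
    """
    span: dict[tuple[str, int], list[int]] = {}
    for rec in records:
        try:
            movie, zmw, qstart, qend = parse_read_name(rec.read_name)
        except ReadNameError:
            continue
        lo = qstart + rec.clip_head
        hi = qend - rec.clip_tail
        key = (movie, zmw)
        if key in span:
            span[key][0] = min(span[key][0], lo)
            span[key][1] = max(span[key][1], hi)
        else:
            span[key] = [lo, hi]
    heads: list[float] = []
    tails: list[float] = []
    n_excluded = 0
    for key, g in _group_index(groups).items():
        if key not in span:
            n_excluded += 1
            continue
        plen = g.polymerase_length
        lo, hi = span[key]
        heads.append(min(max(lo / plen, 0.0), 1.0 - 1e-12))
        tails.append(min(max((plen - hi) / plen, 0.0), 1.0 - 1e-12))
    if not heads:
        raise EstimationError("no aligned polymerase reads for the unaligned-ratio model")
    if n_excluded:
        log.info("unaligned-ratio model: %d polymerase reads had no aligned subread", n_excluded)
    return UnalignedRatioModel(
        head=EmpiricalDistribution.from_values(heads, bin_width),
        tail=EmpiricalDistribution.from_values(tails, bin_width),
    )


def _group_index(groups) -> dict[tuple[str, int], ZmwGroup]:
    if isinstance(groups, Mapping):
        out = {}
        for g in groups.values():
            out[(g.movie, g.zmw)] = g
        return out
    return {(g.movie, g.zmw): g for g in groups}


# ---------------------------------------------------------------------------
# events

@dataclass
class ErrorEvent:
    """One merged alignment event with its reference 3-mer context."""

    type: str  # match | insertion | deletion | substitution
    size: int
    context: str  # a 3-mer over ACGT, or NOCTX
    ref_bases: str = ""
    read_bases: str = ""


def _context(ref_seq: str, pos: int) -> str:
    if pos < 2 or pos >= len(ref_seq):
        return NOCTX
    kmer = ref_seq[pos - 2:pos + 1]
    return kmer if all(b in BASES for b in kmer) else NOCTX


def alignment_to_events(rec: AlignmentRecord, ref_seq: str) -> list[ErrorEvent]:
    """Scan an alignment into ordered events (see module docstring for the
    context-anchoring convention). The record's edit script must be
    consistent with the reference slice."""
    if rec.ref_end > len(ref_seq):
        raise EstimationError(
            f"{rec.read_name}: alignment ends at {rec.ref_end} but reference "
            f"{rec.ref_name} has only {len(ref_seq)} bases")
    problems = rec.validate()
    if problems:
        raise EstimationError("; ".join(problems))
    events: list[ErrorEvent] = []
    r = rec.ref_start
    for op, length, bases in rec.script:
        if op == "=":
            for j in range(length):
                b = ref_seq[r + j]
                events.append(ErrorEvent("match", 1, _context(ref_seq, r + j), b, b))
            r += length
        elif op == "X":
            events.append(ErrorEvent(
                "substitution", length, _context(ref_seq, r),
                ref_seq[r:r + length], bases))
            r += length
        elif op == "D":
            events.append(ErrorEvent(
                "deletion", length, _context(ref_seq, r), ref_seq[r:r + length], ""))
            r += length
        elif op == "I":
            ctx = _context(ref_seq, r - 1) if r >= 1 else NOCTX
            events.append(ErrorEvent("insertion", length, ctx, "", bases))
        else:
            raise EstimationError(f"{rec.read_name}: unknown script op {op!r}")
    return events


# ---------------------------------------------------------------------------
# tallies

_TYPE_COL = {"match": 0, "insertion": 1, "deletion": 2, "substitution": 3}


class _EventCounts:
    """Accumulator shared by the event-stream and fast per-record tallies."""

    def __init__(self) -> None:
        self.ev = np.zeros((64, 4), dtype=np.int64)
        self.noctx = np.zeros(4, dtype=np.int64)
        self.sizes: dict[str, Counter] = {t: Counter() for t in ("insertion", "deletion", "substitution")}
        self.ins_bases = np.zeros((64, 4), dtype=np.int64)
        self.sub = np.zeros((4, 4), dtype=np.int64)
        self.base_counts = {"insertion": 0, "deletion": 0, "substitution": 0}
        self.template_bases = 0

    def total_events(self) -> int:
        return int(self.ev.sum() + self.noctx.sum())

    def add_event(self, etype: str, size: int, ctx_code: int, ref_bases: str, read_bases: str) -> None:
        col = _TYPE_COL[etype]
        if ctx_code >= 0:
            self.ev[ctx_code, col] += 1
        else:
            self.noctx[col] += 1
        if etype == "match":
            self.template_bases += 1
            return
        self.sizes[etype][size] += 1
        self.base_counts[etype] += size
        if etype == "insertion":
            if ctx_code >= 0:
                for b in read_bases:
                    self.ins_bases[ctx_code, BASE_INDEX[b]] += 1
        else:
            self.template_bases += size
        if etype == "substitution":
            for rb, qb in zip(ref_bases, read_bases):
                if rb in BASE_INDEX and qb in BASE_INDEX:
                    self.sub[BASE_INDEX[rb], BASE_INDEX[qb]] += 1


def _tally_record(counts: _EventCounts, rec: AlignmentRecord, kcode: np.ndarray, ref_seq: str) -> None:
    """Vectorized per-record tally equivalent to streaming the record's
    events through :meth:`_EventCounts.add_event`."""
    r = rec.ref_start
    match_slices: list[np.ndarray] = []
    for op, length, bases in rec.script:
        if op == "=":
            match_slices.append(kcode[r:r + length])
            r += length
        elif op == "X":
            counts.add_event(
                "substitution", length, int(kcode[r]), ref_seq[r:r + length], bases)
            r += length
        elif op == "D":
            counts.add_event("deletion", length, int(kcode[r]), "", "")
            r += length
        elif op == "I":
            ctx = int(kcode[r - 1]) if r >= 1 else -1
            counts.add_event("insertion", length, ctx, "", bases)
    if match_slices:
        conc = np.concatenate(match_slices)
        valid = conc >= 0
        counts.ev[:, 0] += np.bincount(conc[valid], minlength=64)
        counts.noctx[0] += int((~valid).sum())
        counts.template_bases += int(conc.size)


def tally_events(
    events: Iterable[ErrorEvent], size_cap: int = DEFAULT_SIZE_CAP
) -> tuple[ContextErrorTable, SizeModel, InsertionBaseTable, SubstitutionMatrix]:
    """Turn an event stream into the four error-model components."""
    counts = _EventCounts()
    kmer_index = {k: i for i, k in enumerate(KMERS)}
    for ev in events:
        code = kmer_index.get(ev.context, -1)
        counts.add_event(ev.type, ev.size, code, ev.ref_bases, ev.read_bases)
    return finalize_tallies(counts, size_cap)


def finalize_tallies(
    counts: _EventCounts, size_cap: int = DEFAULT_SIZE_CAP
) -> tuple[ContextErrorTable, SizeModel, InsertionBaseTable, SubstitutionMatrix]:
    if counts.total_events() == 0:
        raise EstimationError("zero events: nothing to estimate an error model from")

    totals = counts.ev.sum(axis=1)
    observed = totals > 0
    if not observed.any():
        raise EstimationError("no events carried a usable 3-mer context")
    freq = np.zeros((64, 4))
    freq[observed] = counts.ev[observed] / totals[observed, None]
    marginal = freq[observed].mean(axis=0)
    fallback = [KMERS[i] for i in np.nonzero(~observed)[0]]
    freq[~observed] = marginal
    table = ContextErrorTable(
        {KMERS[i]: freq[i] for i in range(64)}, fallback_contexts=tuple(fallback))

    def size_dist(t: str) -> EmpiricalDistribution:
        c = counts.sizes[t]
        if not c:
            return EmpiricalDistribution.point_mass(1.0)
        capped: Counter = Counter()
        for size, n in c.items():
            capped[min(size, size_cap)] += n
        return EmpiricalDistribution.from_counts(capped)

    sizes = SizeModel(
        insertion=size_dist("insertion"),
        deletion=size_dist("deletion"),
        substitution=size_dist("substitution"),
        cap=size_cap,
    )

    ins_totals = counts.ins_bases.sum(axis=1)
    ins_observed = ins_totals > 0
    ins_rows = np.full((64, 4), 0.25)
    if ins_observed.any():
        ins_rows[ins_observed] = counts.ins_bases[ins_observed] / ins_totals[ins_observed, None]
        ins_marginal = ins_rows[ins_observed].mean(axis=0)
        ins_rows[~ins_observed] = ins_marginal
    ins_fallback = tuple(KMERS[i] for i in np.nonzero(~ins_observed)[0])
    insertion_bases = InsertionBaseTable(
        {KMERS[i]: ins_rows[i] for i in range(64)}, fallback_contexts=ins_fallback)

    sub_rows = {}
    for b in BASES:
        i = BASE_INDEX[b]
        alts = [BASE_INDEX[a] for a in SUBSTITUTION_ALTS[b]]
        row = counts.sub[i, alts].astype(float)
        sub_rows[b] = row / row.sum() if row.sum() > 0 else np.full(3, 1.0 / 3.0)
    substitutions = SubstitutionMatrix(sub_rows)

    return table, sizes, insertion_bases, substitutions


# ---------------------------------------------------------------------------
# orchestration

def build_profile(
    alignments,
    reference,
    *,
    single_pass: bool = False,
    length_bin: float = DEFAULT_LENGTH_BIN,
    ratio_bin: float = DEFAULT_RATIO_BIN,
    size_cap: int = DEFAULT_SIZE_CAP,
    end_error_rate: float = DEFAULT_END_ERROR_RATE,
    report_path=None,
) -> SequencingProfile:
    """Estimate a full profile from a SAM/BAM file and its reference FASTA.

    Only primary alignments contribute events. Reads whose names do not
    parse as subread names are skipped (and counted) unless ``single_pass``
    is set, in which case each is treated as a 1-pass polymerase read.
    Estimation is deterministic: the same inputs yield a bit-identical
    profile.
    """
    if isinstance(reference, (str, Path)):
        reference = sio.read_fasta(reference)
    kcodes = {name: kmer_codes(seq) for name, seq in reference.items()}

    from types import SimpleNamespace

    counts = _EventCounts()
    stats: dict = {}
    names: list[str] = []
    aligned_records: list = []  # lightweight views: name + clips only
    n_unparsed = 0
    synth_zmw = 0

    mode = "rb" if str(alignments).endswith(".bam") else "r"
    import pysam

    with pysam.AlignmentFile(str(alignments), mode, check_sq=False) as fh:
        for key in ("used", "unmapped", "secondary", "supplementary"):
            stats.setdefault(key, 0)
        for raw in fh:
            if raw.is_secondary:
                stats["secondary"] += 1
                continue
            if raw.is_supplementary:
                stats["supplementary"] += 1
                continue
            name = raw.query_name
            parseable = _NAME_RE.match(name) is not None
            if not parseable and not single_pass:
                n_unparsed += 1
                continue
            if raw.is_unmapped:
                stats["unmapped"] += 1
                if parseable:
                    names.append(name)
                continue
            rec = sio.record_from_pysam(raw, reference)
            if rec.ref_name not in reference:
                raise EstimationError(f"reference is missing contig {rec.ref_name}")
            stats["used"] += 1
            if parseable:
                names.append(name)
            else:
                synth_zmw += 1
                synth = f"unnamed/{synth_zmw}/0_{rec.read_length}"
                rec.read_name = synth
                names.append(synth)
            _tally_record(counts, rec, kcodes[rec.ref_name], reference[rec.ref_name])
            aligned_records.append(SimpleNamespace(
                read_name=rec.read_name, clip_head=rec.clip_head, clip_tail=rec.clip_tail))

    if stats["used"] == 0:
        raise EstimationError(f"{alignments}: no usable primary alignments")

    groups, skipped = group_by_zmw(names)
    pass_length = estimate_pass_length_model(groups, bin_width=length_bin)
    unaligned = estimate_unaligned_ratio(
        aligned_records, {f"{g.movie}/{g.zmw}": g for g in groups}, bin_width=ratio_bin)
    table, sizes, insertion_bases, substitutions = finalize_tallies(counts, size_cap)

    event_totals = counts.ev.sum(axis=0) + counts.noctx
    profile = SequencingProfile(
        pass_length=pass_length,
        unaligned=unaligned,
        context_table=table,
        sizes=sizes,
        insertion_bases=insertion_bases,
        substitutions=substitutions,
        end_error_rate=end_error_rate,
        metadata={
            "source_alignments": str(alignments),
            "records_used": stats["used"],
            "records_unmapped": stats["unmapped"],
            "records_secondary": stats["secondary"],
            "records_supplementary": stats["supplementary"],
            "names_unparsed": n_unparsed + len(skipped),
            "n_zmw": len(groups),
            "event_counts": {t: int(event_totals[c]) for t, c in _TYPE_COL.items()},
            "noctx_events": int(counts.noctx.sum()),
            "error_base_counts": dict(counts.base_counts),
            "template_bases": int(counts.template_bases),
            "fallback_contexts": list(table.fallback_contexts),
        },
    )
    log.info(
        "profile: %d alignments, %d ZMWs, %d events (%d without context), %d unparsed names",
        stats["used"], len(groups), counts.total_events(), int(counts.noctx.sum()),
        n_unparsed)
    if report_path is not None:
        write_estimation_report(profile, counts, report_path)
    return profile


def write_estimation_report(profile: SequencingProfile, counts: _EventCounts, path) -> None:
    """64-row TSV of per-context event counts and rates, plus a NOCTX row."""
    import pandas as pd

    rows = []
    for i, kmer in enumerate(KMERS):
        c = counts.ev[i]
        total = c.sum()
        rows.append({
            "kmer": kmer,
            "match": int(c[0]), "insertion": int(c[1]),
            "deletion": int(c[2]), "substitution": int(c[3]),
            "match_rate": c[0] / total if total else np.nan,
            "insertion_rate": c[1] / total if total else np.nan,
            "deletion_rate": c[2] / total if total else np.nan,
            "substitution_rate": c[3] / total if total else np.nan,
        })
    nc = counts.noctx
    total = nc.sum()
    rows.append({
        "kmer": NOCTX,
        "match": int(nc[0]), "insertion": int(nc[1]),
        "deletion": int(nc[2]), "substitution": int(nc[3]),
        "match_rate": nc[0] / total if total else np.nan,
        "insertion_rate": nc[1] / total if total else np.nan,
        "deletion_rate": nc[2] / total if total else np.nan,
        "substitution_rate": nc[3] / total if total else np.nan,
    })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
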