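"""Comparison statistics for simulated corpora.

Length distributions, per-type error-size distributions, per-3-mer error
rates, realized error-rate tables and the two-sample Kolmogorov–Smirnov
statistic — the quantities used to judge whether a simulated corpus looks
like the data its profile was estimated from.

Rates in :class:`RateTable` are error bases per template (reference) base,
so the three per-type rates add up to the total error rate exactly; the
denominator convention is stated in every report header this module writes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .edits import flip_script, script_error_counts, script_read_length
from .profile import (
    DEFAULT_LENGTH_BIN,
    KMERS,
    NOCTX,
    EmpiricalDistribution,
)
from .profiler import ErrorEvent, alignment_to_events
from .edits import AlignmentRecord
from .simulate import TruthRecord


@dataclass
class RateTable:
    """Alignment-style summary rates (fractions, shared template-base
    denominator, so total = insertion + deletion + substitution)."""

    aligned_read_rate: float
    aligned_base_rate: float
    error_rate: float
    insertion: float
    deletion: float
    substitution: float

    def to_dict(self) -> dict:
        return {
            "aligned_read_rate": self.aligned_read_rate,
            "aligned_base_rate": self.aligned_base_rate,
            "error_rate": self.error_rate,
            "insertion": self.insertion,
            "deletion": self.deletion,
            "substitution": self.substitution,
        }


def ks_statistic(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample K-S statistic D = sup |ECDF_a - ECDF_b| with the standard
    asymptotic p-value."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("K-S statistic needs two non-empty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def polymerase_lengths(truths: Iterable[TruthRecord]) -> list[int]:
    """Polymerase read length per ZMW: summed subread lengths."""
    by_read: dict[str, int] = {}
    for tr in truths:
        key = tr.name.rsplit("/", 1)[0]
        by_read[key] = by_read.get(key, 0) + script_read_length(tr.script)
    return list(by_read.values())


def length_distribution(lengths: Iterable[float], bin_width: float = DEFAULT_LENGTH_BIN) -> EmpiricalDistribution:
    """Binned read-length distribution."""
    values = list(lengths)
    if not values:
        raise ValueError("length distribution needs at least one read")
    return EmpiricalDistribution.from_values(values, bin_width)


def error_size_distribution(source) -> dict[str, EmpiricalDistribution]:
    """Per-type error-size frequency tables from truth records or events."""
    sizes: dict[str, list[int]] = {"insertion": [], "deletion": [], "substitution": []}
    n = 0
    for item in source:
        if isinstance(item, TruthRecord):
            for op, length, _ in item.script:
                t = {"I": "insertion", "D": "deletion", "X": "substitution"}.get(op)
                if t:
                    sizes[t].append(length)
                    n += 1
        elif isinstance(item, ErrorEvent):
            if item.type != "match":
                sizes[item.type].append(item.size)
                n += 1
        else:
            raise TypeError(f"cannot take error sizes from {type(item).__name__}")
    if n == 0:
        raise ValueError("no error events to build size distributions from")
    return {
        t: EmpiricalDistribution.from_values(v)
        for t, v in sizes.items() if v
    }


def per_kmer_error_rates(events: Iterable[ErrorEvent]) -> pd.DataFrame:
    """64-row table of per-context event counts and rates by type.

    Events without a usable context are excluded from the rows and reported
    in ``df.attrs["noctx_events"]``.
    """
    counts = {k: np.zeros(4, dtype=np.int64) for k in KMERS}
    col = {"match": 0, "insertion": 1, "deletion": 2, "substitution": 3}
    noctx = 0
    for ev in events:
        if ev.context == NOCTX or ev.context not in counts:
            noctx += 1
            continue
        counts[ev.context][col[ev.type]] += 1
    rows = []
    for kmer in KMERS:
        c = counts[kmer]
        total = int(c.sum())
        rows.append({
            "kmer": kmer, "events": total,
            "match": int(c[0]), "insertion": int(c[1]),
            "deletion": int(c[2]), "substitution": int(c[3]),
            "insertion_rate": c[1] / total if total else np.nan,
            "deletion_rate": c[2] / total if total else np.nan,
            "substitution_rate": c[3] / total if total else np.nan,
        })
    df = pd.DataFrame(rows).set_index("kmer")
    df.attrs["noctx_events"] = noctx
    return df


def realized_rate_table(truths: Iterable[TruthRecord]) -> RateTable:
    """Exact rates from ground-truth edit scripts (no aligner involved;
    alignment rates are 1 by construction)."""
    total = {"ins_bases": 0, "del_bases": 0, "sub_bases": 0, "template_bases": 0}
    any_truth = False
    for tr in truths:
        any_truth = True
        c = script_error_counts(tr.script)
        for key in total:
            total[key] += c[key]
    if not any_truth or total["template_bases"] == 0:
        raise ValueError("no truth records with template bases")
    t = total["template_bases"]
    ins, dele, sub = total["ins_bases"] / t, total["del_bases"] / t, total["sub_bases"] / t
    return RateTable(
        aligned_read_rate=1.0, aligned_base_rate=1.0,
        error_rate=ins + dele + sub, insertion=ins, deletion=dele, substitution=sub,
    )


def rate_table_from_sam(path, reference: Mapping[str, str]) -> RateTable:
    """Rates recomputed from a user-supplied SAM of re-aligned reads
    (this module never invokes an aligner itself)."""
    from . import io as sio

    stats: dict = {}
    total = {"ins_bases": 0, "del_bases": 0, "sub_bases": 0, "template_bases": 0}
    aligned_read_bases = 0
    read_bases = 0
    for rec in sio.read_alignments(path, reference, stats):
        c = script_error_counts(rec.script)
        for key in total:
            total[key] += c[key]
        aligned_read_bases += c["read_bases"]
        read_bases += rec.read_length
    n_aligned = stats["used"]
    n_reads = n_aligned + stats["unmapped"]
    if n_aligned == 0 or total["template_bases"] == 0:
        raise ValueError(f"{path}: no aligned records")
    t = total["template_bases"]
    ins, dele, sub = total["ins_bases"] / t, total["del_bases"] / t, total["sub_bases"] / t
    return RateTable(
        aligned_read_rate=n_aligned / n_reads if n_reads else 0.0,
        aligned_base_rate=aligned_read_bases / read_bases if read_bases else 0.0,
        error_rate=ins + dele + sub, insertion=ins, deletion=dele, substitution=sub,
    )


def events_from_truth(
    truths: Iterable[TruthRecord], reference: Mapping[str, str]
) -> Iterable[ErrorEvent]:
    """Convert ground truth into the profiler's event stream (contexts in
    reference-forward orientation), for per-kmer evaluation."""
    for tr in truths:
        fwd = tr.script if tr.strand == "+" else flip_script(tr.script)
        rec = AlignmentRecord(
            read_name=tr.name,
            read_length=script_read_length(fwd),
            ref_name=tr.contig,
            ref_start=tr.start,
            ref_end=tr.end,
            strand=tr.strand,
            script=fwd,
        )
        yield from alignment_to_events(rec, reference[tr.contig])


def end_segment_error_rate(truths: Iterable[TruthRecord]) -> tuple[int, int, float]:
    """Error events per template base inside the presumed-unaligned
    head/tail segments; returns (events, bases, rate).

    An event is attributed to the segment containing its first template
    position (read orientation).
    """
    events = 0
    bases = 0
    for tr in truths:
        t_len = sum(l for op, l, _ in tr.script if op in "=XD")
        head, tail = tr.head_len, tr.tail_len
        bases += head + tail
        if head == 0 and tail == 0:
            continue
        pos = 0
        for op, l, _ in tr.script:
            if op != "=" and (pos < head or pos >= t_len - tail):
                events += 1
            if op in "=XD":
                pos += l
    if bases == 0:
        return 0, 0, float("nan")
    return events, bases, events / bases
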