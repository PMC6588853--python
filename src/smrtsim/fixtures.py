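"""Synthetic data with known structure, so everything is testable offline.

Three generators close the loop around the simulator and the profiler:

* :func:`random_genome` — i.i.d. random contigs at a chosen GC fraction;
* :func:`oracle_reads` — a deliberately *simple* read generator (one
  categorical draw per template base, all error sizes 1, no context
  dependence) whose planted per-base rates are known exactly. It shares no
  code with the simulator's error walk, so profiler round-trip tests
  against it are not self-confirming;
* :func:`truth_to_sam` — converts ground-truth records into primary SAM
  records with =/X/I/D CIGARs, as if an aligner had been run, letting the
  profiler consume simulator or oracle output.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from . import io as sio
from .edits import IntegrityError, Script, apply_script, flip_script, revcomp, script_to_cigar
from .profile import BASES
from .simulate import TruthRecord


class FixtureError(ValueError):
    """Invalid fixture specification."""


@dataclass
class FixtureSpec:
    """Parameters for a reproducible synthetic corpus."""

    genome_length: int = 100_000
    gc: float = 0.5
    n_contigs: int = 1
    rates: tuple[float, float, float] = (0.1, 0.04, 0.01)  # ins, del, sub
    n_reads: int = 100
    read_length: int = 9000
    passes: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length < 1 or self.n_contigs < 1:
            raise FixtureError("genome_length and n_contigs must be >= 1")
        if not (0.0 < self.gc < 1.0):
            raise FixtureError("GC fraction must be in (0, 1)")
        if self.seed is None:
            raise FixtureError("fixtures require an explicit seed")


def random_genome(spec: FixtureSpec) -> dict[str, str]:
    """Random ACGT contigs; each base independent with P(G or C) = gc."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    probs = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    base = spec.genome_length // spec.n_contigs
    lengths = [base] * spec.n_contigs
    lengths[-1] += spec.genome_length - base * spec.n_contigs
    genome: dict[str, str] = {}
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i, length in enumerate(lengths):
        if length < 1:
            raise FixtureError("contig length must be >= 1")
        draws = rng.choice(4, size=length, p=probs)
        genome[f"contig_{i + 1}"] = alphabet[draws].tobytes().decode()
    return genome


def oracle_reads(
    genome: dict[str, str],
    rates: tuple[float, float, float],
    n_reads: int,
    read_length: int,
    passes: int = 1,
    seed: int = 0,
    movie: str = "oracle0",
) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Reads with planted per-base error rates (independent oracle).

    Per template base exactly one categorical draw decides: insertion
    (emit the base, then one random base), deletion (emit nothing),
    substitution (emit one of the three other bases) or match. Error
    decisions are made on the reference-forward strand of each pass;
    reverse-strand passes emit the reverse complement.
    """
    p_ins, p_del, p_sub = rates
    if min(rates) < 0 or p_ins + p_del + p_sub >= 1.0:
        raise FixtureError("rates must be non-negative and sum to < 1")
    rng = np.random.default_rng(seed)
    names = sorted(genome)
    weights = np.array([max(0, len(genome[c]) - read_length + 1) for c in names], dtype=float)
    if weights.sum() == 0:
        raise FixtureError(f"no contig can hold a read of length {read_length}")
    cum = np.cumsum(weights / weights.sum())

    reads: list[tuple[str, str]] = []
    truths: list[TruthRecord] = []
    for z in range(n_reads):
        ci = min(int(np.searchsorted(cum, rng.random(), side="right")), len(names) - 1)
        contig = names[ci]
        start = int(rng.integers(0, int(weights[ci])))
        end = start + read_length
        forward = genome[contig][start:end]
        template_strand = "+" if rng.random() < 0.5 else "-"
        qstart = 0
        for p in range(passes):
            strand = "+" if (template_strand == "+") == (p % 2 == 0) else "-"
            out: list[str] = []
            script: Script = []

            def put(op: str, length: int, bases: str) -> None:
                if script and script[-1][0] == op:
                    prev = script[-1]
                    script[-1] = (op, prev[1] + length, prev[2] + bases)
                else:
                    script.append((op, length, bases))

            draws = rng.random(len(forward))
            for j, ch in enumerate(forward):
                u = draws[j]
                if u < p_ins:
                    ins = BASES[int(rng.integers(4))]
                    put("=", 1, "")
                    put("I", 1, ins)
                    out.append(ch + ins)
                elif u < p_ins + p_del:
                    put("D", 1, "")
                elif u < p_ins + p_del + p_sub:
                    alt = [b for b in BASES if b != ch][int(rng.integers(3))]
                    put("X", 1, alt)
                    out.append(alt)
                else:
                    put("=", 1, "")
                    out.append(ch)
            read_f = "".join(out)
            if strand == "-":
                read, script_r = revcomp(read_f), flip_script(script)
            else:
                read, script_r = read_f, script
            qend = qstart + len(read)
            name = f"{movie}/{z + 1}/{qstart}_{qend}"
            reads.append((name, read))
            truths.append(TruthRecord(
                name=name, contig=contig, start=start, end=end,
                strand=strand, template_strand=template_strand,
                pass_index=p, n_pass=passes, head_len=0, tail_len=0,
                script=script_r, read=read,
            ))
            qstart = qend
    return reads, truths


def truth_to_sam(truths, reference: dict[str, str], path) -> int:
    """Write one primary SAM record per subread; returns the record count.

    The read sequence is reconstructed from the edit script and the
    reference and must equal the stored subread (integrity check), so the
    reference must be the one the truth was generated from and free of
    ambiguous bases at the template locations.
    """
    header = sio.sam_header(reference)
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for tr in truths:
            fwd = tr.script if tr.strand == "+" else flip_script(tr.script)
            ref_slice = reference[tr.contig][tr.start:tr.end]
            seq = apply_script(fwd, ref_slice)
            if tr.read is not None:
                expected = tr.read if tr.strand == "+" else revcomp(tr.read)
                if seq != expected:
                    raise IntegrityError(
                        f"{tr.name}: script applied to {tr.contig}:{tr.start}-{tr.end} "
                        "does not reproduce the subread")
            rec = pysam.AlignedSegment(header)
            rec.query_name = tr.name
            rec.query_sequence = seq
            rec.flag = 16 if tr.strand == "-" else 0
            rec.reference_id = header.get_tid(tr.contig)
            rec.reference_start = tr.start
            rec.mapping_quality = 60
            rec.cigarstring = script_to_cigar(fwd)
            rec.query_qualities = pysam.qualitystring_to_array("~" * len(seq))
            out.write(rec)
            n += 1
    return n
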