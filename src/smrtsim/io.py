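"""Readers and writers for the standard formats the package touches.

FASTA/FASTQ via Biopython, SAM/BAM via pysam (primary records normalized to
:class:`~smrtsim.edits.AlignmentRecord` with M ops resolved into =/X),
pairwise MAF and a TSV sidecar for ground truth, and a JSON run manifest.
Coordinates are 0-based half-open everywhere in memory; SAM's 1-based
convention is converted at this boundary.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pysam
from Bio import SeqIO

from .edits import AlignmentRecord, Script, flip_script, merge_script, revcomp
from .simulate import TruthRecord
from . import edits

_NON_DNA = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}.

    Letters outside ACGTN are mapped to N with a warning.
    """
    records: dict[str, str] = {}
    mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = _NON_DNA.sub("N", seq)
        mapped += sum(1 for a, b in zip(seq, cleaned) if a != b)
        records[rec.id] = cleaned
    if mapped:
        warnings.warn(f"{path}: {mapped} non-ACGTN letters mapped to N")
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path, width: int = 80) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path, quality: int = 12) -> None:
    """Write reads with a constant Phred quality (per-base QVs carry no
    error information on the platform being modelled)."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qchar * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) % 4:
        raise FormatError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(lines), 4):
        name, seq, plus, qual = lines[i:i + 4]
        if not name.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{path}: malformed FASTQ record at line {i + 1}")
        if len(seq) != len(qual):
            raise FormatError(
                f"{path}: sequence/quality length mismatch at line {i + 1}")
        reads.append((name[1:].split()[0], seq.upper()))
    return reads


# ---------------------------------------------------------------------------
# SAM / BAM

def _expand_md(md: str) -> list[tuple[str, str]]:
    """Expand an MD tag into per-reference-base ('m'|'x'|'d', ref base)."""
    out: list[tuple[str, str]] = []
    for num, dele, sub in re.findall(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])", md):
        if num:
            out.extend(("m", "") for _ in range(int(num)))
        elif dele:
            out.extend(("d", b) for b in dele.upper())
        else:
            out.append(("x", sub.upper()))
    return out


def record_from_pysam(rec: pysam.AlignedSegment, reference: Mapping[str, str] | None) -> AlignmentRecord:
    """Normalize one mapped pysam record.

    M runs are resolved into =/X using the MD tag when present, otherwise the
    reference sequence; clips are reported in read orientation.
    """
    query = rec.query_sequence
    if query is None:
        raise FormatError(f"{rec.query_name}: record has no sequence")
    contig = reference.get(rec.reference_name) if reference else None
    md = _expand_md(rec.get_tag("MD")) if rec.has_tag("MD") else None
    md_pos = 0

    script: Script = []
    q = 0
    r = rec.reference_start
    clip_a = clip_b = 0
    seen_aligned = False
    for op, length in rec.cigartuples:
        if op in (4, 5):  # S, H
            if seen_aligned:
                clip_b += length
            else:
                clip_a += length
            if op == 4:
                q += length
            continue
        seen_aligned = True
        if op in (7,):  # =
            script.append(("=", length, ""))
            q += length
            r += length
        elif op == 8:  # X
            script.append(("X", length, query[q:q + length]))
            q += length
            r += length
        elif op == 1:  # I
            script.append(("I", length, query[q:q + length]))
            q += length
        elif op == 2:  # D
            script.append(("D", length, ""))
            r += length
        elif op == 0:  # M: resolve per base
            if contig is not None:
                ref_slice = contig[r:r + length]
            elif md is not None:
                cols = md[md_pos:md_pos + length]
                ref_slice = "".join(
                    rb if kind == "x" else query[q + j]
                    for j, (kind, rb) in enumerate(cols))
            else:
                raise FormatError(
                    f"{rec.query_name}: M op cannot be resolved without a reference or MD tag")
            for j in range(length):
                same = query[q + j] == ref_slice[j]
                script.append(("=", 1, "") if same else ("X", 1, query[q + j]))
            q += length
            r += length
        else:
            raise FormatError(f"{rec.query_name}: unsupported CIGAR op {op}")
        if md is not None and op in (0, 7, 8):
            md_pos += length
        elif md is not None and op == 2:
            md_pos += length

    read_length = rec.infer_read_length()
    if read_length is None:
        read_length = edits.script_read_length(script) + clip_a + clip_b
    strand = "-" if rec.is_reverse else "+"
    clip_head, clip_tail = (clip_b, clip_a) if rec.is_reverse else (clip_a, clip_b)
    record = AlignmentRecord(
        read_name=rec.query_name,
        read_length=read_length,
        ref_name=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=r,
        strand=strand,
        script=merge_script(script),
        clip_head=clip_head,
        clip_tail=clip_tail,
    )
    problems = record.validate()
    if problems:
        raise FormatError("; ".join(problems))
    return record


def read_alignments(path, reference: Mapping[str, str] | None = None, stats: dict | None = None):
    """Yield normalized primary alignments from a SAM/BAM file.

    Secondary/supplementary and unmapped records are skipped; counts go into
    ``stats`` when a dict is supplied (keys ``used``, ``unmapped``,
    ``secondary``, ``supplementary``).
    """
    if stats is None:
        stats = {}
    for key in ("used", "unmapped", "secondary", "supplementary"):
        stats.setdefault(key, 0)
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                stats["unmapped"] += 1
                continue
            if rec.is_secondary:
                stats["secondary"] += 1
                continue
            if rec.is_supplementary:
                stats["supplementary"] += 1
                continue
            stats["used"] += 1
            yield record_from_pysam(rec, reference)


def sam_header(reference: Mapping[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in sorted(reference.items())],
    })


# ---------------------------------------------------------------------------
# ground truth: TSV sidecar and MAF

_TRUTH_COLUMNS = (
    "name", "contig", "start", "end", "strand", "template_strand", "pass_index",
    "n_pass", "head_len", "tail_len", "read_length", "template_bases",
    "ins_bases", "del_bases", "sub_bases", "script",
)


def write_truth_tsv(truths: Iterable[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for tr in truths:
            counts = edits.script_error_counts(tr.script)
            row = (
                tr.name, tr.contig, tr.start, tr.end, tr.strand, tr.template_strand,
                tr.pass_index, tr.n_pass, tr.head_len, tr.tail_len,
                counts["read_bases"], counts["template_bases"],
                counts["ins_bases"], counts["del_bases"], counts["sub_bases"],
                edits.serialize_script(tr.script),
            )
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_truth_tsv(path) -> list[TruthRecord]:
    truths: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(_TRUTH_COLUMNS):
            raise FormatError(f"{path}: unexpected truth TSV header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            row = dict(zip(_TRUTH_COLUMNS, f))
            truths.append(TruthRecord(
                name=row["name"], contig=row["contig"],
                start=int(row["start"]), end=int(row["end"]),
                strand=row["strand"], template_strand=row["template_strand"],
                pass_index=int(row["pass_index"]), n_pass=int(row["n_pass"]),
                head_len=int(row["head_len"]), tail_len=int(row["tail_len"]),
                script=edits.parse_script(row["script"]), read=None,
            ))
    return truths


def _aligned_texts(script: Script, ref_slice: str, read: str) -> tuple[str, str]:
    ref_out: list[str] = []
    read_out: list[str] = []
    t = q = 0
    for op, l, b in script:
        if op == "=" or op == "X":
            ref_out.append(ref_slice[t:t + l])
            read_out.append(read[q:q + l])
            t += l
            q += l
        elif op == "I":
            ref_out.append("-" * l)
            read_out.append(read[q:q + l])
            q += l
        elif op == "D":
            ref_out.append(ref_slice[t:t + l])
            read_out.append("-" * l)
            t += l
    return "".join(ref_out), "".join(read_out)


def write_maf(truths: Iterable[TruthRecord], reference: Mapping[str, str], path) -> None:
    """One pairwise block per subread, both rows in reference-forward
    orientation; the read row carries the pass strand."""
    with open(path, "w") as fh:
        fh.write("##maf version=1 program=smrtsim\n")
        for tr in truths:
            if tr.read is None:
                raise FormatError("MAF output needs truth records with sequences")
            fwd_script = tr.script if tr.strand == "+" else flip_script(tr.script)
            fwd_read = tr.read if tr.strand == "+" else revcomp(tr.read)
            ref_slice = reference[tr.contig][tr.start:tr.end]
            ref_text, read_text = _aligned_texts(fwd_script, ref_slice, fwd_read)
            src_size = len(reference[tr.contig])
            fh.write("a score=0\n")
            fh.write(f"s {tr.contig} {tr.start} {tr.end - tr.start} + {src_size} {ref_text}\n")
            fh.write(f"s {tr.name} 0 {len(tr.read)} {tr.strand} {len(tr.read)} {read_text}\n\n")


# ---------------------------------------------------------------------------
# manifest

def file_md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, subcommand: str, options: dict, inputs: Iterable = (), seed=None) -> None:
    from . import __version__

    payload = {
        "tool": "smrtsim",
        "version": __version__,
        "subcommand": subcommand,
        "seed": seed,
        "options": {k: (str(v) if isinstance(v, Path) else v) for k, v in options.items()},
        "input_checksums": {str(p): file_md5(p) for p in inputs if p and Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
        fh.write("\n")
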