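"""Edit scripts and normalized pairwise alignments.

An edit script is an ordered list of ``(op, length, bases)`` runs that
transforms a template (reference-side) sequence into a read:

* ``"="``  — matched bases (``bases`` empty; copied from the template);
* ``"X"``  — substituted bases (``bases`` = the read bases);
* ``"I"``  — inserted bases (``bases`` = the inserted read bases);
* ``"D"``  — deleted template bases (``bases`` empty).

A maximal run of one error op is one *event* with a size; adjacent runs of
the same op are therefore always merged (:func:`merge_script`). Scripts are
orientation-specific; :func:`flip_script` converts between a script on a
sequence and the equivalent script on its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: ops that consume template (reference) bases / read bases
REF_OPS = frozenset("=XD")
READ_OPS = frozenset("=XI")

ScriptEntry = tuple[str, int, str]
Script = list[ScriptEntry]


class IntegrityError(ValueError):
    """An edit script is inconsistent with its sequences."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def script_read_length(script: Script) -> int:
    return sum(l for op, l, _ in script if op in READ_OPS)


def script_ref_length(script: Script) -> int:
    return sum(l for op, l, _ in script if op in REF_OPS)


def script_error_counts(script: Script) -> dict[str, int]:
    """Event and base tallies of a script (template_bases counts =, X, D)."""
    c = dict.fromkeys(
        ("ins_events", "del_events", "sub_events",
         "ins_bases", "del_bases", "sub_bases", "template_bases", "read_bases"), 0)
    for op, l, _ in script:
        if op == "=":
            c["template_bases"] += l
            c["read_bases"] += l
        elif op == "X":
            c["sub_events"] += 1
            c["sub_bases"] += l
            c["template_bases"] += l
            c["read_bases"] += l
        elif op == "I":
            c["ins_events"] += 1
            c["ins_bases"] += l
            c["read_bases"] += l
        elif op == "D":
            c["del_events"] += 1
            c["del_bases"] += l
            c["template_bases"] += l
    return c


def merge_script(script: Script) -> Script:
    """Merge adjacent runs of the same op (continuous errors are one event)."""
    out: Script = []
    for op, l, b in script:
        if l == 0:
            continue
        if out and out[-1][0] == op:
            pop, pl, pb = out[-1]
            out[-1] = (op, pl + l, pb + b)
        else:
            out.append((op, l, b))
    return out


def apply_script(script: Script, template: str) -> str:
    """Apply an edit script to its template, producing the read."""
    out: list[str] = []
    t = 0
    for op, l, b in script:
        if op == "=":
            out.append(template[t:t + l])
            t += l
        elif op == "X":
            out.append(b)
            t += l
        elif op == "I":
            out.append(b)
        elif op == "D":
            t += l
        else:
            raise IntegrityError(f"unknown script op {op!r}")
    if t != len(template):
        raise IntegrityError(
            f"script consumes {t} template bases but template has {len(template)}")
    return "".join(out)


def flip_script(script: Script) -> Script:
    """The same alignment viewed from the reverse-complemented sequences."""
    return [(op, l, revcomp(b)) for op, l, b in reversed(script)]


def script_to_cigar(script: Script, clip_head: int = 0, clip_tail: int = 0) -> str:
    parts: list[str] = []
    if clip_head:
        parts.append(f"{clip_head}S")
    for op, l, _ in merge_script(script):
        parts.append(f"{l}{op}")
    if clip_tail:
        parts.append(f"{clip_tail}S")
    return "".join(parts)


def serialize_script(script: Script) -> str:
    """Compact text form, e.g. ``=120,X:AG,D3,I:TT,=30``."""
    parts = []
    for op, l, b in script:
        if op in ("X", "I"):
            parts.append(f"{op}:{b}")
        else:
            parts.append(f"{op}{l}")
    return ",".join(parts)


def parse_script(text: str) -> Script:
    script: Script = []
    if not text:
        return script
    for token in text.split(","):
        if token[0] in ("X", "I") and len(token) > 1 and token[1] == ":":
            script.append((token[0], len(token) - 2, token[2:]))
        elif token[0] in ("=", "D"):
            script.append((token[0], int(token[1:]), ""))
        else:
            raise IntegrityError(f"bad script token {token!r}")
    return script


@dataclass
class AlignmentRecord:
    """A normalized primary pairwise alignment.

    The edit script is in reference-forward orientation (as stored in SAM);
    ``clip_head``/``clip_tail`` are soft/hard-clipped bases at the two ends
    of the read *in read orientation*, and ``read_length`` is the full read
    length including clips.
    """

    read_name: str
    read_length: int
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    script: Script = field(default_factory=list)
    clip_head: int = 0
    clip_tail: int = 0

    def validate(self) -> list[str]:
        v: list[str] = []
        if self.strand not in "+-":
            v.append(f"{self.read_name}: strand must be + or -")
        ref_len = script_ref_length(self.script)
        if ref_len != self.ref_end - self.ref_start:
            v.append(
                f"{self.read_name}: script consumes {ref_len} reference bases, "
                f"interval is {self.ref_end - self.ref_start}")
        read_len = script_read_length(self.script) + self.clip_head + self.clip_tail
        if read_len != self.read_length:
            v.append(
                f"{self.read_name}: script + clips consume {read_len} read bases, "
                f"read length is {self.read_length}")
        return v
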