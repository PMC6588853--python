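"""Sequencing-profile data model for multi-pass SMRT read simulation.

A :class:`SequencingProfile` is the complete generative model for one
sequencing platform/chemistry:

* a pass-number distribution with, for each pass number, a (binned)
  polymerase read-length distribution — long templates are cycled fewer
  times, so the two are modelled jointly;
* head/tail unaligned-fraction distributions — the noisy ends of a
  polymerase read that typically fail to align back to the reference;
* a 64-row trinucleotide context table giving, per reference 3-mer, the
  probabilities of the four event types (match, insertion, deletion,
  substitution);
* per-type error-size distributions (a maximal run of one error type is a
  single event with a size);
* context-dependent inserted-base frequencies;
* a twelve-cell substitution matrix (each reference base to the three
  non-identical read bases);
* a preset error rate applied inside the presumed-unaligned read ends
  (default 0.4).

All probability vectors must sum to one within ``PROB_TOL``; validation is
non-throwing (:func:`validate_profile` returns a list of violations) so a
profile can be inspected before use. Profiles serialize to a versioned JSON
schema for diffability.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
EVENT_TYPES = ("match", "insertion", "deletion", "substitution")
ERROR_TYPES = ("insertion", "deletion", "substitution")
K = 3
KMERS = tuple("".join(p) for p in itertools.product(BASES, repeat=K))
KMER_INDEX = {k: i for i, k in enumerate(KMERS)}
#: Sentinel context for events whose reference 3-mer is unavailable
#: (first k-1 positions of a contig, or ambiguous reference bases).
NOCTX = "NOCTX"

PROB_TOL = 1e-9
SCHEMA_VERSION = 1
DEFAULT_END_ERROR_RATE = 0.4
DEFAULT_LENGTH_BIN = 100
DEFAULT_RATIO_BIN = 0.01
DEFAULT_SIZE_CAP = 20


class ProfileError(ValueError):
    """Invalid profile content or profile file."""


def kmer_codes(seq: str) -> np.ndarray:
    """Per-position code of the 3-mer *ending* at each position.

    ``codes[i]`` is the lexicographic index (A=0..T=3, big-endian) of
    ``seq[i-2:i+1]``, or -1 where that 3-mer is unavailable (``i < 2`` or
    any involved base outside ACGT).
    """
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = np.full(b.size, -1, dtype=np.int64)
    for i, base in enumerate(BASES):
        code[b == ord(base)] = i
    out = np.full(b.size, -1, dtype=np.int64)
    if b.size >= K:
        c0, c1, c2 = code[:-2], code[1:-1], code[2:]
        valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0)
        out[2:][valid] = c0[valid] * 16 + c1[valid] * 4 + c2[valid]
    return out


@dataclass
class EmpiricalDistribution:
    """A discrete distribution over numeric support values.

    When ``bin_width`` is set the support values are bin centers and
    sampling draws a bin, then a uniform offset inside it; otherwise the
    support values are returned exactly.
    """

    support: np.ndarray
    probabilities: np.ndarray
    bin_width: float | None = None

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self._cum: np.ndarray | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def point_mass(cls, value: float) -> "EmpiricalDistribution":
        return cls(np.array([value]), np.array([1.0]))

    @classmethod
    def from_values(cls, values, bin_width: float | None = None) -> "EmpiricalDistribution":
        values = np.asarray(list(values), dtype=float)
        if values.size == 0:
            raise ProfileError("cannot build a distribution from zero values")
        if bin_width:
            idx = np.floor(values / bin_width).astype(np.int64)
            uniq, counts = np.unique(idx, return_counts=True)
            support = (uniq + 0.5) * bin_width
        else:
            support, counts = np.unique(values, return_counts=True)
        return cls(support, counts / counts.sum(), bin_width)

    @classmethod
    def from_counts(cls, counts: Mapping[float, float], bin_width: float | None = None) -> "EmpiricalDistribution":
        items = sorted(counts.items())
        support = np.array([v for v, _ in items], dtype=float)
        weights = np.array([c for _, c in items], dtype=float)
        total = weights.sum()
        if total <= 0:
            raise ProfileError("cannot build a distribution from zero counts")
        return cls(support, weights / total, bin_width)

    # -- behaviour --------------------------------------------------------
    def validate(self, name: str = "distribution") -> list[str]:
        v: list[str] = []
        if self.support.ndim != 1 or self.support.shape != self.probabilities.shape:
            return [f"{name}: support and probabilities must be 1-d and equal length"]
        if self.support.size == 0:
            return [f"{name}: empty support"]
        if np.any(np.diff(self.support) <= 0):
            v.append(f"{name}: support values must be strictly increasing")
        if np.any(self.probabilities < 0):
            v.append(f"{name}: negative probabilities")
        if abs(self.probabilities.sum() - 1.0) > PROB_TOL:
            v.append(f"{name}: probabilities sum to {self.probabilities.sum()!r}, not 1")
        return v

    @property
    def cum(self) -> np.ndarray:
        if self._cum is None:
            self._cum = np.cumsum(self.probabilities)
        return self._cum

    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities))

    def sample(self, rng: np.random.Generator) -> float:
        i = int(np.searchsorted(self.cum, rng.random(), side="right"))
        i = min(i, self.support.size - 1)
        x = float(self.support[i])
        if self.bin_width:
            x = x - self.bin_width / 2.0 + rng.random() * self.bin_width
        return x

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "support": self.support.tolist(),
            "probabilities": self.probabilities.tolist(),
            "bin_width": self.bin_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmpiricalDistribution":
        try:
            return cls(np.asarray(d["support"]), np.asarray(d["probabilities"]), d.get("bin_width"))
        except (KeyError, TypeError) as exc:
            raise ProfileError(f"malformed distribution entry: {exc}") from exc

    def __eq__(self, other) -> bool:  # array fields defeat dataclass eq
        return (
            isinstance(other, EmpiricalDistribution)
            and self.bin_width == other.bin_width
            and np.array_equal(self.support, other.support)
            and np.array_equal(self.probabilities, other.probabilities)
        )


@dataclass
class ContextErrorTable:
    """Per-3-mer probabilities of (match, insertion, deletion, substitution)."""

    rows: dict[str, np.ndarray]
    k: int = K
    #: contexts that had no observations and were filled with the marginal row
    fallback_contexts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.rows = {c: np.asarray(r, dtype=float) for c, r in self.rows.items()}

    def matrix(self) -> np.ndarray:
        """Rows stacked in lexicographic k-mer order, shape (4**k, 4)."""
        return np.stack([self.rows[c] for c in KMERS])

    def marginal(self, weights: Mapping[str, float] | None = None) -> np.ndarray:
        if weights is None:
            w = np.ones(len(KMERS))
        else:
            w = np.array([float(weights.get(c, 0.0)) for c in KMERS])
            if np.any(w < 0):
                raise ProfileError("context weights must be non-negative")
        if w.sum() <= 0:
            raise ProfileError("context weights sum to zero")
        m = (self.matrix() * (w / w.sum())[:, None]).sum(axis=0)
        return m / m.sum()

    def validate(self) -> list[str]:
        v: list[str] = []
        expected = 4 ** self.k
        if len(self.rows) != expected:
            v.append(f"context_table: {len(self.rows)} rows, expected 4^{self.k} = {expected}")
        for c, row in self.rows.items():
            if row.shape != (4,):
                v.append(f"context_table[{c}]: row must have 4 entries")
                continue
            if np.any(row < 0):
                v.append(f"context_table[{c}]: negative probability")
            if abs(row.sum() - 1.0) > PROB_TOL:
                v.append(f"context_table[{c}]: row sums to {row.sum()!r}, not 1")
        return v

    def to_dict(self) -> dict:
        return {
            "rows": {c: r.tolist() for c, r in self.rows.items()},
            "fallback_contexts": list(self.fallback_contexts),
        }

    @classmethod
    def from_dict(cls, d: dict, k: int = K) -> "ContextErrorTable":
        return cls(
            {c: np.asarray(r) for c, r in d["rows"].items()},
            k=k,
            fallback_contexts=tuple(d.get("fallback_contexts", ())),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ContextErrorTable)
            and self.k == other.k
            and set(self.rows) == set(other.rows)
            and all(np.array_equal(self.rows[c], other.rows[c]) for c in self.rows)
        )


@dataclass
class SizeModel:
    """Per error type, the distribution of event sizes (bases, >= 1).

    Sizes above ``cap`` are lumped into the cap bin at estimation time.
    """

    insertion: EmpiricalDistribution
    deletion: EmpiricalDistribution
    substitution: EmpiricalDistribution
    cap: int = DEFAULT_SIZE_CAP

    def dist(self, error_type: str) -> EmpiricalDistribution:
        return getattr(self, error_type)

    def validate(self) -> list[str]:
        v: list[str] = []
        for t in ERROR_TYPES:
            d = self.dist(t)
            v.extend(d.validate(f"sizes.{t}"))
            s = d.support
            if s.size and (np.any(s < 1) or np.any(s != np.round(s))):
                v.append(f"sizes.{t}: support must be integers >= 1")
            if s.size and np.any(s > self.cap):
                v.append(f"sizes.{t}: support exceeds cap {self.cap}")
        return v

    def to_dict(self) -> dict:
        return {"cap": self.cap, **{t: self.dist(t).to_dict() for t in ERROR_TYPES}}

    @classmethod
    def from_dict(cls, d: dict) -> "SizeModel":
        return cls(
            insertion=EmpiricalDistribution.from_dict(d["insertion"]),
            deletion=EmpiricalDistribution.from_dict(d["deletion"]),
            substitution=EmpiricalDistribution.from_dict(d["substitution"]),
            cap=int(d.get("cap", DEFAULT_SIZE_CAP)),
        )


@dataclass
class InsertionBaseTable:
    """Per-context frequencies of each inserted base (A, C, G, T)."""

    rows: dict[str, np.ndarray]
    fallback_contexts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.rows = {c: np.asarray(r, dtype=float) for c, r in self.rows.items()}

    def matrix(self) -> np.ndarray:
        return np.stack([self.rows[c] for c in KMERS])

    def validate(self) -> list[str]:
        v: list[str] = []
        if len(self.rows) != len(KMERS):
            v.append(f"insertion_bases: {len(self.rows)} rows, expected {len(KMERS)}")
        for c, row in self.rows.items():
            if row.shape != (4,) or np.any(row < 0) or abs(row.sum() - 1.0) > PROB_TOL:
                v.append(f"insertion_bases[{c}]: must be a 4-vector of non-negative reals summing to 1")
        return v

    def to_dict(self) -> dict:
        return {
            "rows": {c: r.tolist() for c, r in self.rows.items()},
            "fallback_contexts": list(self.fallback_contexts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InsertionBaseTable":
        return cls(
            {c: np.asarray(r) for c, r in d["rows"].items()},
            fallback_contexts=tuple(d.get("fallback_contexts", ())),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, InsertionBaseTable)
            and set(self.rows) == set(other.rows)
            and all(np.array_equal(self.rows[c], other.rows[c]) for c in self.rows)
        )


#: Read-base alternatives for each reference base, in ACGT order minus self.
SUBSTITUTION_ALTS = {b: tuple(a for a in BASES if a != b) for b in BASES}


@dataclass
class SubstitutionMatrix:
    """The twelve substitution categories: each reference base to the three
    non-identical read bases, as a conditional probability 3-vector."""

    rows: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.rows = {b: np.asarray(r, dtype=float) for b, r in self.rows.items()}

    @classmethod
    def uniform(cls) -> "SubstitutionMatrix":
        return cls({b: np.full(3, 1.0 / 3.0) for b in BASES})

    def n_categories(self) -> int:
        return sum(r.size for r in self.rows.values())

    def validate(self) -> list[str]:
        v: list[str] = []
        if set(self.rows) != set(BASES):
            v.append("substitutions: must have one row per reference base ACGT")
            return v
        if self.n_categories() != 12:
            v.append(f"substitutions: {self.n_categories()} categories, expected 12")
        for b, row in self.rows.items():
            if row.shape != (3,) or np.any(row < 0) or abs(row.sum() - 1.0) > PROB_TOL:
                v.append(f"substitutions[{b}]: must be a 3-vector of non-negative reals summing to 1")
        return v

    def to_dict(self) -> dict:
        return {
            b: {alt: float(p) for alt, p in zip(SUBSTITUTION_ALTS[b], row)}
            for b, row in self.rows.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubstitutionMatrix":
        return cls(
            {b: np.array([float(d[b][alt]) for alt in SUBSTITUTION_ALTS[b]]) for b in d}
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SubstitutionMatrix)
            and set(self.rows) == set(other.rows)
            and all(np.array_equal(self.rows[b], other.rows[b]) for b in self.rows)
        )


@dataclass
class PassLengthModel:
    """Joint model of pass number and polymerase read length.

    ``pass_distribution`` is over integer pass numbers >= 1; for every pass
    number with nonzero probability, ``length_by_pass`` holds the (binned)
    polymerase read-length distribution conditional on that pass number.
    """

    pass_distribution: EmpiricalDistribution
    length_by_pass: dict[int, EmpiricalDistribution]

    def validate(self) -> list[str]:
        v = self.pass_distribution.validate("pass_length.pass_distribution")
        s = self.pass_distribution.support
        if s.size and (np.any(s < 1) or np.any(s != np.round(s))):
            v.append("pass_length: pass numbers must be integers >= 1")
        for n, p in zip(s, self.pass_distribution.probabilities):
            if p > 0 and int(n) not in self.length_by_pass:
                v.append(f"pass_length: pass number {int(n)} has probability {p} but no length distribution")
        for n, dist in self.length_by_pass.items():
            v.extend(dist.validate(f"pass_length.length_by_pass[{n}]"))
        return v

    def to_dict(self) -> dict:
        return {
            "pass_distribution": self.pass_distribution.to_dict(),
            "length_by_pass": {str(n): d.to_dict() for n, d in self.length_by_pass.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PassLengthModel":
        return cls(
            pass_distribution=EmpiricalDistribution.from_dict(d["pass_distribution"]),
            length_by_pass={int(n): EmpiricalDistribution.from_dict(e) for n, e in d["length_by_pass"].items()},
        )


@dataclass
class UnalignedRatioModel:
    """Distributions of the unaligned head/tail fraction of a polymerase read.

    A sampled (head, tail) pair is rejected and redrawn while
    ``head + tail >= guard`` so that every simulated read keeps an aligned
    core; the guard slightly perturbs the marginals for profiles with heavy
    upper tails, which real profiles do not have.
    """

    head: EmpiricalDistribution
    tail: EmpiricalDistribution
    guard: float = 0.9

    def validate(self) -> list[str]:
        v = self.head.validate("unaligned.head") + self.tail.validate("unaligned.tail")
        for name, d in (("head", self.head), ("tail", self.tail)):
            if d.support.size and (np.any(d.support < 0) or np.any(d.support >= 1)):
                v.append(f"unaligned.{name}: support values must lie in [0, 1)")
        return v

    def sample_pair(self, rng: np.random.Generator, max_tries: int = 10000) -> tuple[float, float]:
        for _ in range(max_tries):
            h = max(0.0, self.head.sample(rng))
            t = max(0.0, self.tail.sample(rng))
            if h + t < self.guard:
                return h, t
        raise ProfileError(
            f"unaligned-ratio model never produced head + tail < {self.guard} in {max_tries} draws"
        )

    def to_dict(self) -> dict:
        return {"head": self.head.to_dict(), "tail": self.tail.to_dict(), "guard": self.guard}

    @classmethod
    def from_dict(cls, d: dict) -> "UnalignedRatioModel":
        return cls(
            head=EmpiricalDistribution.from_dict(d["head"]),
            tail=EmpiricalDistribution.from_dict(d["tail"]),
            guard=float(d.get("guard", 0.9)),
        )


@dataclass
class SequencingProfile:
    """The full generative model; see module docstring."""

    pass_length: PassLengthModel
    unaligned: UnalignedRatioModel
    context_table: ContextErrorTable
    sizes: SizeModel
    insertion_bases: InsertionBaseTable
    substitutions: SubstitutionMatrix
    end_error_rate: float = DEFAULT_END_ERROR_RATE
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        meta = {"schema_version": SCHEMA_VERSION, "k": self.context_table.k}
        meta.update(self.metadata)
        return {
            "meta": meta,
            "pass_length": self.pass_length.to_dict(),
            "unaligned": self.unaligned.to_dict(),
            "context_table": self.context_table.to_dict(),
            "sizes": self.sizes.to_dict(),
            "insertion_bases": self.insertion_bases.to_dict(),
            "substitutions": self.substitutions.to_dict(),
            "end_error_rate": self.end_error_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequencingProfile":
        required = (
            "meta", "pass_length", "unaligned", "context_table",
            "sizes", "insertion_bases", "substitutions", "end_error_rate",
        )
        missing = [key for key in required if key not in d]
        if missing:
            raise ProfileError(f"profile file missing components: {', '.join(missing)}")
        meta = dict(d["meta"])
        version = meta.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ProfileError(f"unknown profile schema version: {version!r}")
        k = int(meta.pop("k", K))
        return cls(
            pass_length=PassLengthModel.from_dict(d["pass_length"]),
            unaligned=UnalignedRatioModel.from_dict(d["unaligned"]),
            context_table=ContextErrorTable.from_dict(d["context_table"], k=k),
            sizes=SizeModel.from_dict(d["sizes"]),
            insertion_bases=InsertionBaseTable.from_dict(d["insertion_bases"]),
            substitutions=SubstitutionMatrix.from_dict(d["substitutions"]),
            end_error_rate=float(d["end_error_rate"]),
            metadata=meta,
        )


def validate_profile(profile: SequencingProfile) -> list[str]:
    """Collect invariant violations; an empty list means the profile is valid."""
    v: list[str] = []
    v.extend(profile.pass_length.validate())
    v.extend(profile.unaligned.validate())
    v.extend(profile.context_table.validate())
    v.extend(profile.sizes.validate())
    v.extend(profile.insertion_bases.validate())
    v.extend(profile.substitutions.validate())
    if not (0.0 < profile.end_error_rate < 1.0):
        v.append(f"end_error_rate: {profile.end_error_rate!r} not in (0, 1)")
    return v


def uniform_profile(
    p_ins: float,
    p_del: float,
    p_sub: float,
    mean_length: int = 9000,
    pass_counts: Mapping[int, float] | None = None,
    *,
    head_ratio: float = 0.0,
    tail_ratio: float = 0.0,
    end_error_rate: float = DEFAULT_END_ERROR_RATE,
) -> SequencingProfile:
    """A context-free baseline profile: every 3-mer shares one event row,
    all error sizes are 1, inserted bases are uniform, substitutions uniform
    over the three alternatives, and the polymerase length is a point mass.
    """
    rates = (p_ins, p_del, p_sub)
    if any(r < 0 for r in rates):
        raise ProfileError("error rates must be non-negative")
    if sum(rates) >= 1.0:
        raise ProfileError(f"error rates sum to {sum(rates)}, must be < 1")
    row = np.array([1.0 - sum(rates), p_ins, p_del, p_sub])
    if pass_counts is None:
        pass_counts = {1: 1.0}
    pass_dist = EmpiricalDistribution.from_counts(dict(pass_counts))
    point = EmpiricalDistribution.point_mass
    return SequencingProfile(
        pass_length=PassLengthModel(
            pass_distribution=pass_dist,
            length_by_pass={int(n): point(float(mean_length)) for n in pass_counts},
        ),
        unaligned=UnalignedRatioModel(head=point(head_ratio), tail=point(tail_ratio)),
        context_table=ContextErrorTable({c: row.copy() for c in KMERS}),
        sizes=SizeModel(insertion=point(1.0), deletion=point(1.0), substitution=point(1.0)),
        insertion_bases=InsertionBaseTable({c: np.full(4, 0.25) for c in KMERS}),
        substitutions=SubstitutionMatrix.uniform(),
        end_error_rate=end_error_rate,
        metadata={"platform": "uniform-baseline"},
    )


def marginal_event_distribution(
    profile: SequencingProfile, context_weights: Mapping[str, float] | None = None
) -> np.ndarray:
    """Weighted average of context rows (uniform weights by default).

    Used wherever a full 3-mer context is unavailable, e.g. the first two
    positions of a template.
    """
    return profile.context_table.marginal(context_weights)


def save_profile(profile: SequencingProfile, path) -> None:
    problems = validate_profile(profile)
    if problems:
        raise ProfileError("refusing to save invalid profile: " + "; ".join(problems))
    Path(path).write_text(json.dumps(profile.to_dict(), indent=1) + "\n")


def load_profile(path) -> SequencingProfile:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ProfileError(f"not a valid profile file ({exc})") from exc
    if not isinstance(d, dict):
        raise ProfileError("profile file must contain a JSON object")
    profile = SequencingProfile.from_dict(d)
    expected_rows = 4 ** profile.context_table.k
    if len(profile.context_table.rows) != expected_rows:
        raise ProfileError(
            f"profile declares k={profile.context_table.k} but has "
            f"{len(profile.context_table.rows)} context rows (expected {expected_rows})"
        )
    problems = validate_profile(profile)
    if problems:
        raise ProfileError("invalid profile file: " + "; ".join(problems))
    return profile
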