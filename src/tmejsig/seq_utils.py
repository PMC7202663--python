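"""Strand-aware sequence primitives shared by all junction analyses.

Conventions
-----------
* Sequences are uppercase strings over ``{A, C, G, T, N}``.
* All public coordinates are 1-based and inclusive; BED output is converted
  to 0-based half-open at write time.
* Windows that reach past a contig end are filled with ``N``; ``N`` never
  scores as an identity match anywhere downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for sequences containing characters outside {A,C,G,T,N}."""


def validate_seq(s: str, *, allow_empty: bool = True) -> str:
    """Upper-case ``s`` and verify it is a valid DNA string."""
    if not isinstance(s, str):
        raise SequenceError(f"expected str, got {type(s).__name__}")
    s = s.upper()
    if not allow_empty and not s:
        raise SequenceError("empty sequence where non-empty required")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"non-DNA characters {sorted(bad)} in sequence")
    return s


def complement(s: str) -> str:
    """Watson-Crick complement without reversal; N maps to N."""
    return validate_seq(s).translate(_COMPLEMENT)


def revcomp(s: str) -> str:
    """Watson-Crick reverse complement; involution on valid input."""
    return validate_seq(s).translate(_COMPLEMENT)[::-1]


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def shuffle_seq(s: str, seed: Union[int, np.random.Generator]) -> str:
    """Uniform random permutation of the characters of ``s``.

    Base composition is exactly preserved and the result is deterministic for
    a given integer seed (or consumes from a supplied Generator).
    """
    s = validate_seq(s)
    rng = _as_rng(seed)
    arr = np.frombuffer(s.encode("ascii"), dtype="S1").copy()
    rng.shuffle(arr)
    return arr.tobytes().decode("ascii")


class RefGenome:
    """Uniform 1-based, N-padded access over a reference genome.

    Accepts a mapping of chromosome name to sequence string, a
    :class:`pyfaidx.Fasta`, a path to a FASTA file, or another ``RefGenome``.
    """

    def __init__(self, source):
        if isinstance(source, RefGenome):
            self._seqs = source._seqs
        elif isinstance(source, (str, Path)):
            import pyfaidx

            fa = pyfaidx.Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._seqs = {name: str(fa[name][:]) for name in fa.keys()}
        elif isinstance(source, Mapping):
            self._seqs = {str(k): validate_seq(v) for k, v in source.items()}
        else:  # pyfaidx.Fasta or similar keyed object
            self._seqs = {name: validate_seq(str(source[name][:])) for name in source.keys()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self):
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        self._check(chrom)
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        self._check(chrom)
        return self._seqs[chrom]

    def _check(self, chrom: str):
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases at 1-based inclusive [start, end]; out-of-range bases are N.

        ``end < start`` yields the empty string.
        """
        self._check(chrom)
        if end < start:
            return ""
        seq = self._seqs[chrom]
        n = len(seq)
        left_pad = max(0, 1 - start)
        right_pad = max(0, end - n)
        lo = max(start, 1) - 1
        hi = min(end, n)
        core = seq[lo:hi] if hi > lo else ""
        return "N" * left_pad + core + "N" * right_pad


def extract_window(ref, chrom: str, pos: int, upstream: int, downstream: int) -> str:
    """Bases [pos-upstream, pos+downstream] on the top strand, N-filled outside.

    Length is always ``upstream + downstream + 1``. Unknown chromosomes raise
    ``KeyError``.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    return RefGenome(ref).fetch(chrom, pos - upstream, pos + downstream)


@dataclass(frozen=True)
class MotifHit:
    """One motif match; 1-based inclusive coordinates on the top strand."""

    start: int
    end: int
    strand: str
    matched: str

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("end < start in MotifHit")
        if self.end - self.start + 1 != len(self.matched):
            raise ValueError("MotifHit span does not match sequence length")


def _g_runs(s: str, min_run: int):
    return [(m.start(), m.end()) for m in re.finditer("G{%d,}" % min_run, s)]


def _scan_strand(s: str, min_run: int, max_loop: int, n_runs: int):
    """Maximal non-overlapping chains of >= n_runs G-runs with 1..max_loop loops."""
    runs = _g_runs(s, min_run)
    hits = []
    i = 0
    while i < len(runs):
        j = i
        while j + 1 < len(runs) and 1 <= runs[j + 1][0] - runs[j][1] <= max_loop:
            j += 1
        if j - i + 1 >= n_runs:
            start0, end0 = runs[i][0], runs[j][1]
            hits.append((start0 + 1, end0))  # 1-based inclusive
            i = j + 1
        else:
            i += 1
    return hits


def scan_g4(
    s: str,
    min_run: int = 3,
    max_loop: int = 7,
    n_runs: int = 4,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan for G-quadruplex-forming motifs: (G{min_run,} N{1,max_loop}){n_runs-1} G{min_run,}.

    Matches are maximal (runs are chained as far as loop lengths permit) and
    non-overlapping per strand. Minus-strand hits are found on the reverse
    complement and mapped back to top-strand coordinates; ``matched`` carries
    the G-rich minus-strand sequence.
    """
    if min(min_run, max_loop, n_runs) < 1:
        raise ValueError("scan_g4 parameters must be >= 1")
    s = validate_seq(s)
    hits = [MotifHit(a, b, "+", s[a - 1 : b]) for a, b in _scan_strand(s, min_run, max_loop, n_runs)]
    if both_strands:
        rc = revcomp(s)
        L = len(s)
        for a, b in _scan_strand(rc, min_run, max_loop, n_runs):
            start, end = L - b + 1, L - a + 1
            hits.append(MotifHit(start, end, "-", rc[a - 1 : b]))
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def write_bed(hits: Iterable[MotifHit], chrom: str, path, name: str = "G4") -> None:
    """Write motif hits as BED6 (0-based half-open intervals)."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            fh.write(f"{chrom}\t{h.start - 1}\t{h.end}\t{name}_{i + 1}\t0\t{h.strand}\n")
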