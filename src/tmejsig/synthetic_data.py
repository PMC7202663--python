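"""Synthetic mutation-accumulation (MA) lines with TMEJ-like deletion scars.

The generator emits a random reference genome plus per-line variant tables
whose statistical structure mirrors what the junction analyses assume:

* per-class Poisson mutation counts per generation (wild-type-like defaults:
  ~0.23 SNVs, ~0.04 microsatellite indels, ~0.04 deletions per animal
  generation, lines grown 40-60 generations),
* 50-500 bp deletions (log-uniform sizes) carrying a geometric micro-homology
  length at their junctions, annotated under maximal 5' conservation,
* junctional inserts, a configurable fraction of which are copied from within
  40 bp of a breakpoint (templated; length >= 5 so they can be mapped back),
  the rest short (< 5 bp) simple inserts,
* a configurable bias for cytosine as the first deleted base, emulating a
  guanine lesion blocking the nascent strand on the template.

Every event comes with a ground-truth record so recovery can be checked end
to end. Implanting rewrites the local reference so that the *normalized*
deletion has exactly the requested micro-homology and -1 base; implant sites
are kept disjoint genome-wide (with margins) so edits never collide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .seq_utils import revcomp
from .variant_io import DeletionEvent, VariantRecord, write_variant_table

#: reserved flank around an implanted deletion: composition window (100) plus
#: templated-origin search (40) with slack
IMPLANT_MARGIN = 160


class GenerationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    genome_length: int = 1_000_000
    gc_content: float = 0.36            # C. elegans-like background
    n_lines: int = 50
    generations_range: tuple = (40, 60)  # uniform draw per line
    generations_fixed: Optional[int] = None
    class_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "SNV": 0.23,
            "microsatellite_indel": 0.04,
            "deletion_50_500": 0.04,
        }
    )
    deletion_size_range: tuple = (50, 500)  # log-uniform
    mh_geom_p: float = 0.5                  # P(mh = k) = p * (1-p)^k
    mh_max: int = 8
    insert_prob: float = 0.3
    insert_templated_prob: float = 0.5      # given an insert
    templated_insert_len_range: tuple = (5, 12)
    simple_insert_len_range: tuple = (1, 4)
    minus1_c_bias: float = 0.5              # P(first deleted base is C)
    insert_search_window: int = 40
    genotype: str = "sim"
    chrom: str = "chrI"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if any(r < 0 for r in self.class_rates.values()):
            raise ValueError("rates must be >= 0")
        for p in (self.insert_prob, self.insert_templated_prob, self.minus1_c_bias, self.mh_geom_p):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


def make_reference(length: int, gc_content: float, seed) -> str:
    """I.i.d. bases at the requested GC content; deterministic given seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    at, gc = (1 - gc_content) / 2, gc_content / 2
    arr = rng.choice(np.array(list("ACGT")), size=length, p=[at, gc, gc, at])
    return "".join(arr)


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _rand_base(rng, exclude: str = "") -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[rng.integers(len(choices))]


def implant_deletion(
    ref: list,
    chrom: str,
    d0: int,
    size: int,
    mh_len: int,
    minus1_base: str,
    insert_spec: Optional[dict],
    rng: np.random.Generator,
    search_window: int = 40,
) -> tuple[DeletionEvent, dict]:
    """Rewrite the local reference (``ref`` is a mutable list of bases, 0-based
    ``d0`` the first deleted index) so that the deletion, as annotated, is the
    maximal-5'-conservation form with exactly ``mh_len`` of junction
    micro-homology and ``minus1_base`` as the first deleted base.

    ``insert_spec`` is None (simple deletion) or
    ``{'templated': bool, 'length': int}``; templated inserts are copied from
    a recorded origin within ``search_window`` bp of a breakpoint, on either
    strand. Returns the (already normalized) event plus a truth dict.
    """
    d1 = d0 + size - 1
    if mh_len < 0 or mh_len > size - 2:
        raise ValueError("infeasible constraint: need 0 <= mh_len <= size - 2")
    if d0 - mh_len - 1 < 0 or d1 + 1 >= len(ref):
        raise ValueError("locus window too small for the requested construction")
    pure = insert_spec is None
    # junction micro-homology: copy the retained 5' suffix into the lost 3' suffix
    for i in range(1, mh_len + 1):
        ref[d1 - i + 1] = ref[d0 - i]
    # cap the homology at exactly mh_len
    if ref[d0 - mh_len - 1] == ref[d1 - mh_len]:
        ref[d1 - mh_len] = _rand_base(rng, exclude=ref[d0 - mh_len - 1])
    # lesion-anchored first deleted base
    ref[d0] = minus1_base
    if pure and ref[d1 + 1] == ref[d0]:
        # keep the annotation right-most: first deleted != first retained-after
        ref[d1 + 1] = _rand_base(rng, exclude=ref[d0])
    insert = ""
    origin = None
    if not pure:
        length = int(insert_spec["length"])
        if insert_spec.get("templated"):
            start1, end1 = d0 + 1, d1 + 1  # 1-based
            side = "5p" if rng.random() < 0.5 else "3p"
            lo = (start1 - search_window) if side == "5p" else (end1 - search_window + 1)
            hi = (start1 - 1 + search_window) if side == "5p" else (end1 + search_window)
            o = int(rng.integers(lo, hi - length + 2))  # origin start, 1-based
            seq = "".join(ref[o - 1 : o - 1 + length])
            strand = "+" if rng.random() < 0.5 else "-"
            insert = seq if strand == "+" else revcomp(seq)
            origin = dict(start=o, end=o + length - 1, strand=strand, side=side)
        else:
            insert = "".join(_rand_base(rng) for _ in range(length))
    deleted = "".join(ref[d0 : d1 + 1])
    ev = DeletionEvent(
        chrom=chrom,
        start=d0 + 1,
        end=d1 + 1,
        ref_allele=deleted,
        alt_allele=insert,
        normalized=True,
        shift_skipped=not pure,
    )
    truth = dict(
        chrom=chrom,
        start=d0 + 1,
        end=d1 + 1,
        size=size,
        true_mh_length=mh_len,
        minus1_base=minus1_base,
        insert_len=len(insert),
        templated=bool(insert_spec and insert_spec.get("templated")),
        origin_start=origin["start"] if origin else "",
        origin_strand=origin["strand"] if origin else "",
    )
    return ev, truth


@dataclass
class SimResult:
    config: SimConfig
    reference: dict
    records: list
    truth: pd.DataFrame
    lines: pd.DataFrame

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = dict(
            fasta=out / "reference.fa",
            variants=out / "variants.tsv",
            truth=out / "truth.tsv",
            lines=out / "lines.tsv",
        )
        write_fasta(self.reference, paths["fasta"])
        write_variant_table(self.records, paths["variants"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.lines.to_csv(paths["lines"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}


class _SiteAllocator:
    """Rejection-samples non-overlapping reserved intervals on the genome."""

    def __init__(self, length: int, rng: np.random.Generator, max_tries: int = 200):
        self.length = length
        self.rng = rng
        self.max_tries = max_tries
        self.taken: list[tuple[int, int]] = []

    def reserve(self, span: int, margin: int) -> int:
        lo_bound = margin + 1
        hi_bound = self.length - span - margin - 1
        if hi_bound <= lo_bound:
            raise GenerationError("genome too small for the requested event span")
        for _ in range(self.max_tries):
            s = int(self.rng.integers(lo_bound, hi_bound))
            a, b = s - margin, s + span + margin
            if all(b < ta or a > tb for ta, tb in self.taken):
                self.taken.append((a, b))
                return s
        raise GenerationError(
            "could not place event without overlap; increase genome_length or lower rates"
        )


def simulate_ma_lines(config: SimConfig) -> SimResult:
    """Simulate independent MA lines on a shared reference.

    Each line accumulates its own events (single-bottleneck inheritance, no
    sharing across lines); per-class counts are Poisson(rate x generations);
    events are placed uniformly with disjoint reserved windows; read-evidence
    flags are emitted as passing (depth 30, both strands). Deterministic and
    byte-identical in its outputs for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    ref = list(make_reference(config.genome_length, config.gc_content, rng))
    alloc = _SiteAllocator(config.genome_length, rng)
    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    line_rows: list[dict] = []
    flags = dict(has_forward_read=True, has_reverse_read=True, depth=30)
    n_digits = max(2, len(str(config.n_lines)))
    for li in range(config.n_lines):
        subpop = f"L{li + 1:0{n_digits}d}"
        if config.generations_fixed is not None:
            gens = int(config.generations_fixed)
        else:
            gens = int(rng.integers(config.generations_range[0], config.generations_range[1] + 1))
        line_rows.append(dict(genotype=config.genotype, subpop=subpop, generations=gens))
        for cls, rate in config.class_rates.items():
            n_events = rng.poisson(rate * gens)
            for _ in range(n_events):
                if cls == "SNV":
                    rec, tr = _make_snv(ref, config, alloc, rng)
                elif cls == "microsatellite_indel":
                    rec, tr = _make_ms_indel(ref, config, alloc, rng)
                elif cls == "deletion_50_500":
                    rec, tr = _make_deletion(ref, config, alloc, rng)
                else:
                    raise ValueError(f"unknown event class {cls!r}")
                rec.genotype = config.genotype
                rec.subpop = subpop
                rec.generations = gens
                rec.has_forward_read = flags["has_forward_read"]
                rec.has_reverse_read = flags["has_reverse_read"]
                rec.depth = flags["depth"]
                tr.update(subpop=subpop, genotype=config.genotype, true_class=cls)
                records.append(rec)
                truth_rows.append(tr)
    reference = {config.chrom: "".join(ref)}
    truth = pd.DataFrame(truth_rows)
    lines = pd.DataFrame(line_rows)
    return SimResult(config=config, reference=reference, records=records, truth=truth, lines=lines)


def _make_snv(ref, config, alloc, rng):
    pos0 = alloc.reserve(1, margin=3)
    old = ref[pos0]
    new = _rand_base(rng, exclude=old)
    rec = VariantRecord(
        chrom=config.chrom, start=pos0 + 1, end=pos0 + 1, ref_allele=old, alt_allele=new
    )
    truth = dict(chrom=config.chrom, start=pos0 + 1, end=pos0 + 1, size=1,
                 true_mh_length="", minus1_base="", insert_len=0, templated=False,
                 origin_start="", origin_strand="")
    return rec, truth


def _make_ms_indel(ref, config, alloc, rng):
    """Write a short tandem repeat tract and delete its last unit."""
    unit_len = int(rng.integers(1, 3))
    copies = int(rng.integers(5, 9))
    unit = "".join(_rand_base(rng) for _ in range(unit_len))
    span = unit_len * copies
    t0 = alloc.reserve(span, margin=20)
    ref[t0 : t0 + span] = list(unit * copies)
    # tract must terminate: flanks must not extend the repeat
    if ref[t0 - 1] == unit[-1]:
        ref[t0 - 1] = _rand_base(rng, exclude=unit[-1])
    if ref[t0 + span] == unit[0]:
        ref[t0 + span] = _rand_base(rng, exclude=unit[0])
    d0 = t0 + span - unit_len  # last unit (right-most annotation)
    rec = VariantRecord(
        chrom=config.chrom,
        start=d0 + 1,
        end=d0 + unit_len,
        ref_allele="".join(ref[d0 : d0 + unit_len]),
        alt_allele="",
    )
    truth = dict(chrom=config.chrom, start=d0 + 1, end=d0 + unit_len, size=unit_len,
                 true_mh_length="", minus1_base="", insert_len=0, templated=False,
                 origin_start="", origin_strand="")
    return rec, truth


def _draw_deletion_size(config, rng) -> int:
    lo, hi = config.deletion_size_range
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _make_deletion(ref, config, alloc, rng):
    size = _draw_deletion_size(config, rng)
    mh = min(int(rng.geometric(config.mh_geom_p)) - 1, config.mh_max, size - 2)
    if rng.random() < config.minus1_c_bias:
        minus1, anchored = "C", True
    else:
        minus1, anchored = _rand_base(rng, exclude="C"), False
    insert_spec = None
    if rng.random() < config.insert_prob:
        if rng.random() < config.insert_templated_prob:
            lo, hi = config.templated_insert_len_range
            insert_spec = dict(templated=True, length=int(rng.integers(lo, hi + 1)))
        else:
            lo, hi = config.simple_insert_len_range
            insert_spec = dict(templated=False, length=int(rng.integers(lo, hi + 1)))
    d0 = alloc.reserve(size, margin=IMPLANT_MARGIN)
    ev, truth = implant_deletion(
        ref, config.chrom, d0, size, mh, minus1, insert_spec, rng,
        search_window=config.insert_search_window,
    )
    truth["lesion_anchored"] = anchored
    return ev, truth


def fixture_dataset(seed: int = 42, n_lines: int = 6) -> SimResult:
    """Small deterministic dataset used by the test suite and CLI fixtures."""
    config = SimConfig(
        genome_length=200_000,
        n_lines=n_lines,
        generations_fixed=40,
        class_rates={"SNV": 0.2, "microsatellite_indel": 0.05, "deletion_50_500": 0.1},
        minus1_c_bias=0.7,
        seed=seed,
    )
    return simulate_ma_lines(config)
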