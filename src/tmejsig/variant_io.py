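"""Variant record I/O, allele normalization, classification and junction contexts.

Records use 1-based inclusive coordinates. A pure insertion is anchored with
``start`` at the first reference base *after* the inserted sequence and
``end = start - 1`` (an empty reference interval), so the invariant
``len(ref_allele) == end - start + 1`` holds for every record.

Deletions are annotated under *maximal 5' conservation*: while the first
deleted base equals the first retained base after the deletion, the deleted
interval shifts one base toward the 3' end, so shared bases are assigned to
the retained 5' flank. This is the opposite of VCF left-alignment; a
converter to the left-aligned representation is provided.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .seq_utils import RefGenome, validate_seq


class VariantFormatError(ValueError):
    """Malformed input file (missing columns, unparseable rows)."""


class VariantValidationError(ValueError):
    """Record violates coordinate or allele invariants."""


class VariantClass(enum.Enum):
    SNV = "SNV"
    MICROSATELLITE_INDEL = "microsatellite_indel"
    DELETION_50_500 = "deletion_50_500"
    DELETION_OTHER = "deletion_other"
    INSERTION = "insertion"
    STRUCTURAL = "structural"

    @property
    def label(self) -> str:
        return self.value


#: class-column tags that mark a record as a structural variant
STRUCTURAL_TAGS = frozenset({"inversion", "tandem_duplication", "gcr", "structural"})


@dataclass
class VariantRecord:
    chrom: str
    start: int
    end: int
    ref_allele: str = ""
    alt_allele: str = ""
    genotype: str = ""
    subpop: str = ""
    generations: Optional[int] = None
    class_label: Optional[str] = None
    has_forward_read: Optional[bool] = None
    has_reverse_read: Optional[bool] = None
    depth: Optional[int] = None

    def __post_init__(self):
        self.ref_allele = validate_seq(self.ref_allele)
        self.alt_allele = validate_seq(self.alt_allele)
        if not self.ref_allele and not self.alt_allele:
            raise VariantValidationError("both alleles empty")
        if self.ref_allele and self.end < self.start:
            raise VariantValidationError("end < start with non-empty ref allele")
        if len(self.ref_allele) != self.end - self.start + 1:
            raise VariantValidationError(
                f"ref allele length {len(self.ref_allele)} != span "
                f"{self.end - self.start + 1} at {self.chrom}:{self.start}"
            )
        if self.generations is not None and self.generations <= 0:
            raise VariantValidationError("generations must be positive")

    # -- derived geometry ------------------------------------------------
    @property
    def deletion_size(self) -> int:
        return len(self.ref_allele)

    @property
    def insert_size(self) -> int:
        return len(self.alt_allele)

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele != self.alt_allele
        )

    @property
    def is_pure_deletion(self) -> bool:
        return self.deletion_size >= 1 and self.insert_size == 0

    @property
    def is_pure_insertion(self) -> bool:
        return self.deletion_size == 0 and self.insert_size >= 1

    @property
    def is_structural(self) -> bool:
        return (self.class_label or "").lower() in STRUCTURAL_TAGS

    def key(self):
        """Identity of the variant irrespective of sample labels."""
        return (self.chrom, self.start, self.end, self.ref_allele, self.alt_allele)


@dataclass
class DeletionEvent(VariantRecord):
    """A deletion (optionally with an inserted sequence at the junction)."""

    normalized: bool = False
    shift_applied: int = 0
    shift_skipped: bool = False  # insert-carrying events are never shifted

    def __post_init__(self):
        super().__post_init__()
        if self.deletion_size < 1:
            raise VariantValidationError("DeletionEvent requires >= 1 deleted base")

    @classmethod
    def from_record(cls, rec: VariantRecord, **kw) -> "DeletionEvent":
        data = {f.name: getattr(rec, f.name) for f in fields(VariantRecord)}
        data.update(kw)
        return cls(**data)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "chrom", "start", "end", "ref_allele", "alt_allele", "class",
    "genotype", "subpop", "generations", "fwd", "rev", "depth",
]
_REQUIRED = ["chrom", "start", "end", "ref_allele", "alt_allele", "genotype", "subpop"]

_BOOL = {"1": True, "true": True, "yes": True, "0": False, "false": False, "no": False}


def _parse_bool(v: str):
    if v == "" or v is None:
        return None
    try:
        return _BOOL[str(v).strip().lower()]
    except KeyError:
        raise ValueError(f"cannot parse boolean {v!r}")


def _parse_int(v):
    if v == "" or v is None:
        return None
    return int(v)


def read_variant_table(path, dialect: str = "tsv", ref=None, strict: bool = True):
    """Read variant records from ``path``.

    dialect ``tsv``
        The canonical tab-separated interchange table (columns of
        :data:`TSV_COLUMNS`; ``class``/``generations``/``fwd``/``rev``/``depth``
        optional).
    dialect ``vcf_subset``
        A minimal VCF 4.x reader: single-ALT records; REF/ALT length
        differences are mapped onto deleted/inserted bases after stripping the
        shared anchor base; symbolic ``<DEL>`` with END (and optional INSSEQ)
        supported. Sample labels are taken from INFO keys GENOTYPE, SUBPOP,
        GENERATIONS, FWD, REV, DP when present.

    Returns a list of :class:`VariantRecord`. Malformed rows are reported with
    their line numbers (raised when ``strict``, else skipped). When ``ref`` is
    supplied, coordinates are checked against it.
    """
    if dialect == "tsv":
        records, problems = _read_tsv(path)
    elif dialect == "vcf_subset":
        records, problems = _read_vcf(path, ref)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if ref is not None:
        genome = RefGenome(ref)
        for i, rec in enumerate(records):
            if rec.chrom not in genome:
                problems.append((None, f"{rec.chrom}: unknown chromosome"))
            elif rec.end > genome.length(rec.chrom) or rec.start < 1 - (rec.deletion_size == 0):
                problems.append((None, f"{rec.chrom}:{rec.start}-{rec.end} outside reference"))
    if problems and strict:
        msgs = "; ".join(
            (f"line {ln}: {msg}" if ln else msg) for ln, msg in problems[:20]
        )
        raise VariantFormatError(f"{len(problems)} malformed/invalid rows: {msgs}")
    return records


def _read_tsv(path):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise VariantFormatError(f"missing mandatory column(s): {missing}")
    records, problems = [], []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            records.append(
                VariantRecord(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    ref_allele=row["ref_allele"].replace("-", ""),
                    alt_allele=row["alt_allele"].replace("-", ""),
                    genotype=row["genotype"],
                    subpop=row["subpop"],
                    generations=_parse_int(row.get("generations", "")),
                    class_label=(row.get("class", "") or None),
                    has_forward_read=_parse_bool(row.get("fwd", "")),
                    has_reverse_read=_parse_bool(row.get("rev", "")),
                    depth=_parse_int(row.get("depth", "")),
                )
            )
        except (ValueError, VariantValidationError) as exc:
            problems.append((line_no, str(exc)))
    return records, problems


def _read_vcf(path, ref=None):
    import pysam

    genome = RefGenome(ref) if ref is not None else None
    records, problems = [], []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            try:
                records.append(_vcf_to_record(rec, genome))
            except (ValueError, VariantValidationError) as exc:
                problems.append((None, f"{rec.chrom}:{rec.pos}: {exc}"))
    return records, problems


def _vcf_to_record(rec, genome):
    if rec.alts is None or len(rec.alts) != 1:
        raise ValueError("multi-allelic or ALT-less records unsupported")
    alt = rec.alts[0]
    info = dict(rec.info)
    common = dict(
        chrom=rec.chrom,
        genotype=str(info.get("GENOTYPE", "")),
        subpop=str(info.get("SUBPOP", "")),
        generations=int(info["GENERATIONS"]) if "GENERATIONS" in info else None,
        has_forward_read=bool(info["FWD"]) if "FWD" in info else None,
        has_reverse_read=bool(info["REV"]) if "REV" in info else None,
        depth=int(info["DP"]) if "DP" in info else None,
    )
    if alt.startswith("<"):
        if alt != "<DEL>":
            raise ValueError(f"symbolic allele {alt} unsupported")
        start, end = rec.pos + 1, rec.stop
        if genome is not None:
            ref_allele = genome.fetch(rec.chrom, start, end)
        else:
            ref_allele = "N" * (end - start + 1)
        return VariantRecord(
            start=start, end=end, ref_allele=ref_allele,
            alt_allele=str(info.get("INSSEQ", "")), **common,
        )
    ref = rec.ref
    if len(ref) == 1 and len(alt) == 1:
        return VariantRecord(start=rec.pos, end=rec.pos, ref_allele=ref, alt_allele=alt, **common)
    if ref[0] != alt[0]:
        # unanchored complex substitution: take alleles literally
        return VariantRecord(
            start=rec.pos, end=rec.pos + len(ref) - 1, ref_allele=ref, alt_allele=alt, **common
        )
    return VariantRecord(
        start=rec.pos + 1,
        end=rec.pos + len(ref) - 1,
        ref_allele=ref[1:],
        alt_allele=alt[1:],
        **common,
    )


def write_variant_table(records: Iterable[VariantRecord], path) -> None:
    """Write records as the canonical TSV dialect (round-trips with the reader)."""
    rows = []
    for r in records:
        rows.append(
            dict(
                chrom=r.chrom, start=r.start, end=r.end,
                ref_allele=r.ref_allele, alt_allele=r.alt_allele,
                **{"class": r.class_label or ""},
                genotype=r.genotype, subpop=r.subpop,
                generations="" if r.generations is None else r.generations,
                fwd="" if r.has_forward_read is None else int(r.has_forward_read),
                rev="" if r.has_reverse_read is None else int(r.has_reverse_read),
                depth="" if r.depth is None else r.depth,
            )
        )
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_bed_deletions(records: Iterable[VariantRecord], path) -> None:
    """Deletion intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in records:
            if r.deletion_size >= 1:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.genotype or '.'}\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_deletion(ref, ev: VariantRecord) -> DeletionEvent:
    """Annotate a deletion under maximal 5' conservation (right-most shift).

    While the first deleted base equals the first retained base after the
    deletion, the deleted interval moves one base 3'-ward; the result is the
    unique right-most annotation and the operation is idempotent. Deletions
    carrying an insert are returned unchanged and flagged (shifting past an
    insert would change junction semantics).
    """
    genome = RefGenome(ref)
    if ev.deletion_size < 1:
        raise VariantValidationError("normalize_deletion requires a deletion")
    if ev.start < 1 or ev.end > genome.length(ev.chrom):
        raise VariantValidationError(
            f"{ev.chrom}:{ev.start}-{ev.end} exceeds chromosome bounds"
        )
    ev = ev if isinstance(ev, DeletionEvent) else DeletionEvent.from_record(ev)
    if ev.insert_size > 0:
        return replace(ev, normalized=True, shift_skipped=True, shift_applied=0)
    seq = genome.sequence(ev.chrom)
    s0, e0 = ev.start - 1, ev.end - 1  # 0-based inclusive
    shift = 0
    n = len(seq)
    while e0 + 1 < n and seq[s0] == seq[e0 + 1] and seq[s0] != "N":
        s0 += 1
        e0 += 1
        shift += 1
    return replace(
        ev,
        start=s0 + 1,
        end=e0 + 1,
        ref_allele=seq[s0 : e0 + 1],
        normalized=True,
        shift_applied=shift,
        shift_skipped=False,
    )


def left_align_deletion(ref, ev: VariantRecord) -> DeletionEvent:
    """Convert to the left-aligned (VCF-style) representation of the same allele."""
    genome = RefGenome(ref)
    ev = ev if isinstance(ev, DeletionEvent) else DeletionEvent.from_record(ev)
    if ev.insert_size > 0:
        return replace(ev, normalized=False, shift_skipped=True)
    seq = genome.sequence(ev.chrom)
    s0, e0 = ev.start - 1, ev.end - 1
    while s0 - 1 >= 0 and seq[s0 - 1] == seq[e0] and seq[e0] != "N":
        s0 -= 1
        e0 -= 1
    return replace(
        ev, start=s0 + 1, end=e0 + 1, ref_allele=seq[s0 : e0 + 1], normalized=False
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassThresholds:
    deletion_min: int = 50
    deletion_max: int = 500
    ms_unit_max: int = 4       # microsatellite repeat unit length <= this
    ms_min_copies: int = 3     # tandem copies (variant + adjacent reference)


def _tandem_copies(seq: str, pos0: int, unit: str, direction: int) -> int:
    """Count adjacent tandem copies of ``unit`` in ``seq`` starting at 0-based
    ``pos0`` going right (direction=+1) or copies ending at pos0 going left."""
    u = len(unit)
    count = 0
    if direction > 0:
        i = pos0
        while seq[i : i + u] == unit:
            count += 1
            i += u
    else:
        i = pos0
        while i - u >= -1 and seq[i - u + 1 : i + 1] == unit:
            count += 1
            i -= u
    return count


def _is_microsatellite(rec: VariantRecord, genome: Optional[RefGenome], th: ClassThresholds) -> bool:
    if not (rec.is_pure_deletion or rec.is_pure_insertion):
        return False
    s = rec.ref_allele or rec.alt_allele
    if genome is None or rec.chrom not in genome:
        return False
    seq = genome.sequence(rec.chrom)
    for u in range(1, min(th.ms_unit_max, len(s)) + 1):
        if len(s) % u:
            continue
        unit = s[:u]
        if unit * (len(s) // u) != s:
            continue
        own = len(s) // u if rec.is_pure_deletion else 0
        # reference copies adjacent to the variant site
        right_anchor = rec.end if rec.is_pure_deletion else rec.start - 1
        left = _tandem_copies(seq, rec.start - 2, unit, -1)
        right = _tandem_copies(seq, right_anchor, unit, +1)
        if own + left + right >= th.ms_min_copies:
            return True
    return False


def _in_tracts(rec: VariantRecord, tracts) -> bool:
    for chrom, a, b in tracts:
        if chrom == rec.chrom and rec.start >= a and max(rec.end, rec.start) <= b:
            return True
    return False


def classify_variant(
    rec: VariantRecord,
    ref=None,
    thresholds: ClassThresholds = ClassThresholds(),
    repeat_tracts: Optional[Sequence] = None,
) -> VariantClass:
    """Total classification of a (normalized) record into the five mutation
    classes used throughout: SNV, microsatellite indel, 50-500 bp deletion,
    other deletion / insertion, and structural (inversion, tandem duplication,
    gross chromosomal rearrangement, consumed as tags).

    ``repeat_tracts`` — optional iterable of (chrom, start, end) microsatellite
    tracts (1-based inclusive); any indel inside one is a microsatellite indel.
    Without tracts, an indel is microsatellite when its sequence is a whole
    multiple of a unit <= ``ms_unit_max`` bp present in >= ``ms_min_copies``
    adjacent tandem copies (variant plus flanking reference).
    """
    if rec.is_structural:
        return VariantClass.STRUCTURAL
    if rec.is_snv:
        return VariantClass.SNV
    genome = RefGenome(ref) if ref is not None else None
    is_indel = rec.is_pure_deletion or rec.is_pure_insertion
    if is_indel and repeat_tracts is not None and _in_tracts(rec, repeat_tracts):
        return VariantClass.MICROSATELLITE_INDEL
    if is_indel and repeat_tracts is None and _is_microsatellite(rec, genome, thresholds):
        return VariantClass.MICROSATELLITE_INDEL
    if thresholds.deletion_min <= rec.deletion_size <= thresholds.deletion_max:
        return VariantClass.DELETION_50_500
    if rec.deletion_size >= 1:
        return VariantClass.DELETION_OTHER
    return VariantClass.INSERTION


# ---------------------------------------------------------------------------
# Junction contexts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionContext:
    """The four sequence windows around one deletion junction pair.

    Position convention (matching the breakpoint axes of the heatmap):
    ``+k`` = k-th retained base counting away from the junction, ``-k`` = k-th
    lost base counting into the deletion.

    Storage order:

    * ``up_retained``  — genome order; index 0 is position +w, index w-1 is +1
      (last retained base before the deletion).
    * ``up_lost``      — genome order; index 0 is -1 (first deleted base).
    * ``down_lost``    — *reversed* genome order; index 0 is -1 (last deleted
      base), read away from the junction into the deletion.
    * ``down_retained``— genome order; index 0 is +1 (first retained base
      after the deletion).

    Windows are N-padded: beyond contig ends and, for the lost windows, beyond
    the deletion itself.
    """

    window: int
    up_retained: str
    up_lost: str
    down_lost: str
    down_retained: str
    deletion_size: int

    def __post_init__(self):
        for name in ("up_retained", "up_lost", "down_lost", "down_retained"):
            if len(getattr(self, name)) != self.window:
                raise ValueError(f"{name} must have length window={self.window}")

    def base_5p(self, pos: int) -> str:
        """Base at 5'-breakpoint position ``pos`` (+k retained, -k lost)."""
        if pos > 0:
            return self.up_retained[self.window - pos]
        return self.up_lost[-pos - 1]

    def base_3p(self, pos: int) -> str:
        """Base at 3'-breakpoint position ``pos`` (-k lost, +k retained)."""
        if pos > 0:
            return self.down_retained[pos - 1]
        return self.down_lost[-pos - 1]


def build_junction_context(ref, ev: VariantRecord, w: int) -> JunctionContext:
    """Extract the four junction windows of width ``w`` for a deletion event."""
    if w <= 0:
        raise ValueError("window must be positive")
    genome = RefGenome(ref)
    if ev.deletion_size < 1:
        raise VariantValidationError("junction context requires a deletion")
    size = ev.deletion_size
    take = min(w, size)
    up_retained = genome.fetch(ev.chrom, ev.start - w, ev.start - 1)
    up_lost = genome.fetch(ev.chrom, ev.start, ev.start + take - 1) + "N" * (w - take)
    down_lost = genome.fetch(ev.chrom, ev.end - take + 1, ev.end)[::-1] + "N" * (w - take)
    down_retained = genome.fetch(ev.chrom, ev.end + 1, ev.end + w)
    return JunctionContext(
        window=w,
        up_retained=up_retained,
        up_lost=up_lost,
        down_lost=down_lost,
        down_retained=down_retained,
        deletion_size=size,
    )
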