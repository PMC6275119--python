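"""Variant, TSS and annotation-track I/O plus dataset-construction filters.

Conventions
-----------
Variant positions are 1-based (VCF convention); annotation intervals are
0-based half-open (BED convention).  :func:`pos_to_bed` / :func:`bed_to_pos`
centralize the conversion.  Sequence windows are always taken from the
forward reference strand; promoter membership respects gene strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from ._seq import BASES
from .errors import (
    BoundaryError,
    ConfigurationError,
    ContractError,
    GenomeLookupError,
    ParseError,
    ReferenceMismatchError,
)

logger = logging.getLogger(__name__)

LABELS = ("functional", "neutral")


def pos_to_bed(pos: int) -> int:
    """1-based position -> 0-based BED coordinate."""
    return pos - 1


def bed_to_pos(start: int) -> int:
    """0-based BED coordinate -> 1-based position."""
    return start + 1


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant with optional class label and MAF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    label: str | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ContractError(
                f"alleles must be single bases in ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ContractError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ContractError(f"pos must be >= 1, got {self.pos}")
        if self.label is not None and self.label not in LABELS:
            raise ContractError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ContractError(f"maf must lie in [0,1], got {self.maf}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_functional(self) -> bool:
        return self.label == "functional"


@dataclass(frozen=True)
class TssEntry:
    """A transcription start site."""

    chrom: str
    tss_pos: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.tss_pos < 1:
            raise ContractError(f"tss_pos must be >= 1, got {self.tss_pos}")
        if self.strand not in ("+", "-"):
            raise ContractError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class SequenceWindow:
    """A reference window of length ``2*flank+1`` centered on ``center_pos``."""

    chrom: str
    center_pos: int
    flank: int
    seq: str

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ContractError("flank must be >= 0")
        if len(self.seq) != 2 * self.flank + 1:
            raise ContractError(
                f"window at {self.chrom}:{self.center_pos}: sequence length "
                f"{len(self.seq)} != 2*{self.flank}+1"
            )

    @property
    def center(self) -> str:
        return self.seq[self.flank]

    def subwindow(self, flank: int) -> str:
        """Centered sub-sequence with the given (smaller) flank."""
        if flank > self.flank:
            raise ContractError(f"subwindow flank {flank} exceeds window flank {self.flank}")
        return self.seq[self.flank - flank : self.flank + flank + 1]


class AnnotationTrack:
    """A genomic interval track (binary overlap or per-position scores).

    Intervals are (chrom, start, end, value) with 0-based half-open
    coordinates.  Lookup is by 1-based position.
    """

    def __init__(
        self,
        track_id: str,
        intervals: Iterable[tuple[str, int, int, float]],
        kind: str = "binary",
    ) -> None:
        if kind not in ("binary", "scored"):
            raise ContractError(f"track kind must be binary|scored, got {kind!r}")
        self.track_id = track_id
        self.kind = kind
        self.intervals: list[tuple[str, int, int, float]] = []
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, value in intervals:
            if start < 0 or start >= end:
                raise ContractError(
                    f"track {track_id}: bad interval {chrom}:{start}-{end}"
                )
            self.intervals.append((chrom, int(start), int(end), float(value)))
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, float(value))

    def overlaps(self, chrom: str, pos: int) -> bool:
        """True iff the 1-based position falls inside any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos_to_bed(pos)))

    def value_at(self, chrom: str, pos: int, default: float = 0.0) -> float:
        """Score at a 1-based position (0 where the track is absent)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return default
        hits = tree.at(pos_to_bed(pos))
        if not hits:
            return default
        # overlapping scored intervals: average their values
        return sum(h.data for h in hits) / len(hits)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TSV_FIELDS = ("chrom", "pos", "ref", "alt", "label", "maf")


def _parse_tsv_row(fields: Mapping[str, str], lineno: int) -> VariantRecord | None:
    """Return a record, or None when the row is a (skippable) non-SNV."""
    try:
        pos = int(fields["pos"])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer pos {fields['pos']!r}") from exc
    ref, alt = fields["ref"].upper(), fields["alt"].upper()
    for allele in (ref, alt):
        if not all(c in BASES + "*" for c in allele):
            raise ParseError(f"line {lineno}: bad allele {allele!r}")
    if len(ref) != 1 or len(alt) != 1 or ref == alt or "*" in (ref, alt):
        return None
    label = fields.get("label") or None
    maf_str = fields.get("maf") or None
    maf = float(maf_str) if maf_str not in (None, "", ".") else None
    try:
        return VariantRecord(fields["chrom"], pos, ref, alt, label=label, maf=maf)
    except ContractError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def _read_variants_tsv(path: Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    skipped = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = {"chrom", "pos", "ref", "alt"} - set(header)
        if missing:
            raise ParseError(f"{path}: header lacks columns {sorted(missing)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = dict(zip(header, line.split("\t")))
            rec = _parse_tsv_row(fields, lineno)
            if rec is None:
                skipped += 1
            else:
                records.append(rec)
    if skipped:
        logger.info("read_variants(%s): skipped %d non-SNV rows", path, skipped)
    return records


def _read_variants_vcf(path: Path) -> list[VariantRecord]:
    import pysam

    records: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in BASES
                or alts[0].upper() not in BASES
                or rec.ref.upper() == alts[0].upper()
            ):
                skipped += 1
                continue
            info = rec.info
            maf = info.get("MAF") if "MAF" in info else None
            if isinstance(maf, tuple):
                maf = maf[0]
            label = info.get("LABEL") if "LABEL" in info else None
            if isinstance(label, tuple):
                label = label[0]
            try:
                records.append(
                    VariantRecord(
                        rec.chrom,
                        rec.pos,
                        rec.ref.upper(),
                        alts[0].upper(),
                        label=label,
                        maf=float(maf) if maf is not None else None,
                    )
                )
            except ContractError as exc:
                raise ParseError(f"{path} record {rec.chrom}:{rec.pos}: {exc}") from exc
    if skipped:
        logger.info("read_variants(%s): skipped %d non-SNV records", path, skipped)
    return records


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read SNVs from a tab-delimited table or a VCF subset.

    Multi-allelic and non-SNV rows are skipped (count logged); malformed
    rows raise :class:`ParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise ContractError(f"unknown dialect {dialect!r} (expected tsv|vcf)")


def write_variants(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write variants as a tab-delimited table (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_FIELDS) + "\n")
        for r in records:
            maf = "" if r.maf is None else repr(r.maf)
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.label or ''}\t{maf}\n"
            )


def read_tss_table(path: str | Path) -> list[TssEntry]:
    """Read a tab-delimited TSS table (chrom, tss_pos, strand, gene_id)."""
    entries: list[TssEntry] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"chrom", "tss_pos", "strand", "gene_id"}
        if not required <= set(header):
            raise ParseError(f"{path}: header lacks {sorted(required - set(header))}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = dict(zip(header, line.rstrip("\n").split("\t")))
            try:
                entries.append(
                    TssEntry(
                        fields["chrom"],
                        int(fields["tss_pos"]),
                        fields["strand"],
                        fields["gene_id"],
                    )
                )
            except (ValueError, ContractError) as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    return entries


def write_tss_table(entries: Sequence[TssEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\ttss_pos\tstrand\tgene_id\n")
        for e in entries:
            fh.write(f"{e.chrom}\t{e.tss_pos}\t{e.strand}\t{e.gene_id}\n")


def read_bed_track(
    path: str | Path, track_id: str, kind: str = "binary"
) -> AnnotationTrack:
    """Read a BED3(+score) file into an :class:`AnnotationTrack`."""
    intervals: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path} line {lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3]) if len(parts) > 3 else 1.0
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            intervals.append((parts[0], start, end, value))
    return AnnotationTrack(track_id, intervals, kind=kind)


def write_bed_track(track: AnnotationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{float(value)!r}\n")


# ---------------------------------------------------------------------------
# sequence windows
# ---------------------------------------------------------------------------


def _contig(genome, chrom: str):
    try:
        return genome[chrom]
    except KeyError as exc:
        raise GenomeLookupError(f"chromosome {chrom!r} absent from reference") from exc


def fetch_window(genome, chrom: str, pos: int, flank: int) -> SequenceWindow:
    """Extract the forward-strand window of length ``2*flank+1`` around ``pos``.

    ``genome`` may be a plain mapping of chromosome -> sequence string or a
    ``pyfaidx.Fasta``.  Windows overrunning a contig boundary raise
    :class:`BoundaryError` (no padding).
    """
    if pos < 1:
        raise ContractError(f"pos must be >= 1, got {pos}")
    contig = _contig(genome, chrom)
    length = len(contig)
    if pos - flank < 1 or pos + flank > length:
        raise BoundaryError(
            f"window {chrom}:{pos}±{flank} overruns contig of length {length}"
        )
    seq = str(contig[pos - 1 - flank : pos + flank]).upper()
    return SequenceWindow(chrom, pos, flank, seq)


def substitute_center(
    window: SequenceWindow, alt: str, ref: str | None = None
) -> SequenceWindow:
    """Return the window with its center base replaced by ``alt``.

    When ``ref`` is given the window center must match it, otherwise a
    :class:`ReferenceMismatchError` is raised (reported with chrom:pos).
    """
    if alt not in BASES:
        raise ContractError(f"alt must be a single base in ACGT, got {alt!r}")
    if ref is not None and window.center != ref:
        raise ReferenceMismatchError(
            f"{window.chrom}:{window.center_pos}: reference base "
            f"{window.center!r} != declared ref {ref!r}"
        )
    if window.center == alt:
        raise ContractError(
            f"{window.chrom}:{window.center_pos}: alt equals the center base {alt!r}"
        )
    seq = window.seq[: window.flank] + alt + window.seq[window.flank + 1 :]
    return replace(window, seq=seq)


# ---------------------------------------------------------------------------
# dataset-construction filters
# ---------------------------------------------------------------------------


def filter_promoter(
    variants: Sequence[VariantRecord],
    tss_table: Sequence[TssEntry],
    span: int = 5000,
) -> list[VariantRecord]:
    """Keep variants lying within ``span`` bp immediately upstream of any TSS.

    Upstream respects gene strand: for "+" the window is
    [tss-span, tss-1]; for "-" it is [tss+1, tss+span].
    """
    if span <= 0:
        raise ContractError(f"span must be > 0, got {span}")
    if not tss_table:
        raise ConfigurationError("empty TSS table")
    by_chrom: dict[str, list[TssEntry]] = {}
    for entry in tss_table:
        by_chrom.setdefault(entry.chrom, []).append(entry)

    def upstream(v: VariantRecord) -> bool:
        for t in by_chrom.get(v.chrom, ()):
            if t.strand == "+":
                if t.tss_pos - span <= v.pos <= t.tss_pos - 1:
                    return True
            else:
                if t.tss_pos + 1 <= v.pos <= t.tss_pos + span:
                    return True
        return False

    return [v for v in variants if upstream(v)]


def filter_maf(
    variants: Sequence[VariantRecord], min_maf: float = 0.01
) -> list[VariantRecord]:
    """Keep variants with MAF >= ``min_maf`` (inclusive); drop records lacking MAF."""
    kept = [v for v in variants if v.maf is not None and v.maf >= min_maf]
    missing = sum(1 for v in variants if v.maf is None)
    if missing:
        logger.info("filter_maf: dropped %d records lacking MAF", missing)
    return kept


def remove_overlap(
    set_a: Sequence[VariantRecord], set_b: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Return ``set_a`` minus records matching ``set_b`` on (chrom,pos,ref,alt)."""
    b_keys = {(v.chrom, v.pos, v.ref, v.alt) for v in set_b}
    return [v for v in set_a if (v.chrom, v.pos, v.ref, v.alt) not in b_keys]
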