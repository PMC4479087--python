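"""Strand-aware transcript models parsed from GTF.

All internal coordinates are 0-based half-open; GTF I/O converts from/to the
1-based inclusive convention of the format. Exons are stored in genomic
(ascending) order regardless of strand; transcript (5'->3') orientation is
applied only when projecting genomic positions onto the spliced mRNA.

The spliced coordinate system defined here is the substrate for every
nonsense-mediated-decay (NMD) geometry rule downstream: 3'UTR lengths,
3'UTR introns and stop-to-junction distances are all measured in exonic
bases along the mature transcript.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from gffutils.feature import feature_from_line

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "SplicedPosition",
    "GTFParseError",
    "AnnotationError",
    "OutOfTranscriptError",
    "parse_gtf",
    "write_gtf",
    "genomic_to_spliced",
]


class GTFParseError(ValueError):
    """A GTF line could not be parsed (names the offending line number)."""


class AnnotationError(ValueError):
    """A transcript violates a structural invariant (names the transcript)."""


class OutOfTranscriptError(ValueError):
    """A genomic position does not fall inside any exon of the transcript."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval: ``start`` inclusive, ``end`` exclusive."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise AnnotationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SplicedPosition:
    """0-based offset along the mature (spliced) mRNA, 5'->3'."""

    transcript_id: str
    offset: int


def _as_sorted_tuple(intervals: Iterable[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    return tuple(sorted(intervals, key=lambda iv: iv.start))


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon/CDS structure plus gene identity and biotype.

    ``exons`` and ``cds`` are genomic-ascending and non-overlapping; ``cds``
    may be empty (non-coding transcript). ``stop_codon`` holds the explicit
    stop-codon pieces when the annotation provides them (1-3 intervals,
    possibly split across exons), else ``None``.
    """

    transcript_id: str
    gene_id: str
    gene_biotype: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    stop_codon: tuple[GenomicInterval, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", _as_sorted_tuple(self.exons))
        object.__setattr__(self, "cds", _as_sorted_tuple(self.cds))
        if self.stop_codon is not None:
            object.__setattr__(self, "stop_codon", _as_sorted_tuple(self.stop_codon))
        self._validate()

    def _validate(self) -> None:
        tid = self.transcript_id
        if not self.exons:
            raise AnnotationError(f"transcript {tid}: no exons")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"transcript {tid}: invalid strand {self.strand!r}")
        chrom = self.exons[0].chrom
        for iv in self.exons + self.cds + (self.stop_codon or ()):
            if iv.chrom != chrom:
                raise AnnotationError(
                    f"transcript {tid}: features on multiple chromosomes "
                    f"({chrom} vs {iv.chrom})"
                )
            if iv.strand != self.strand:
                raise AnnotationError(
                    f"transcript {tid}: features on multiple strands"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {tid}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        for iv in self.cds + (self.stop_codon or ()):
            if not any(e.start <= iv.start and iv.end <= e.end for e in self.exons):
                raise AnnotationError(
                    f"transcript {tid}: CDS/stop interval {iv.start}-{iv.end} "
                    "not contained in any exon"
                )

    # -- basic geometry -----------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons, genomic order; ``n_exons - 1`` items."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    def exons_in_transcript_order(self) -> tuple[GenomicInterval, ...]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def spliced_offset(self, pos: int) -> int:
        """Project a genomic position onto the spliced mRNA (0-based, 5'->3').

        Raises :class:`OutOfTranscriptError` for intronic or flanking
        positions.
        """
        upstream = 0  # exonic bases 5' of pos, plus-strand reading
        hit = None
        for e in self.exons:
            if e.contains(pos):
                hit = upstream + (pos - e.start)
                break
            upstream += len(e)
        if hit is None:
            raise OutOfTranscriptError(
                f"position {self.chrom}:{pos} is not exonic in {self.transcript_id}"
            )
        if self.strand == "+":
            return hit
        return self.spliced_length - 1 - hit

    def junction_spliced_offsets(self) -> tuple[int, ...]:
        """Spliced offset of the last exonic base 5' of each junction.

        Transcript orientation; strictly increasing; ``n_exons - 1`` values.
        """
        offsets = []
        running = 0
        for e in self.exons_in_transcript_order()[:-1]:
            running += len(e)
            offsets.append(running - 1)
        return tuple(offsets)

    def spliced_range_to_genomic(self, start: int, end: int) -> tuple[GenomicInterval, ...]:
        """Map a half-open spliced range back to genomic intervals.

        Returned in genomic order; used to lay CDS pieces onto exons.
        """
        if not (0 <= start < end <= self.spliced_length):
            raise OutOfTranscriptError(
                f"spliced range [{start},{end}) outside {self.transcript_id}"
            )
        pieces = []
        running = 0
        for e in self.exons_in_transcript_order():
            elen = len(e)
            lo = max(start, running)
            hi = min(end, running + elen)
            if lo < hi:
                if self.strand == "+":
                    g0 = e.start + (lo - running)
                    g1 = e.start + (hi - running)
                else:
                    g1 = e.end - (lo - running)
                    g0 = e.end - (hi - running)
                pieces.append(GenomicInterval(self.chrom, g0, g1, self.strand))
            running += elen
        return _as_sorted_tuple(pieces)


def genomic_to_spliced(t: TranscriptModel, pos: int) -> SplicedPosition:
    """Functional wrapper around :meth:`TranscriptModel.spliced_offset`."""
    return SplicedPosition(t.transcript_id, t.spliced_offset(pos))


# -- GTF I/O ----------------------------------------------------------------

_HANDLED_FEATURES = {"exon", "CDS", "stop_codon"}


def _attr_first(attrs, *keys: str, default: str | None = None) -> str | None:
    for k in keys:
        if k in attrs and attrs[k]:
            return attrs[k][0]
    return default


def parse_gtf(source: str | TextIO) -> list[TranscriptModel]:
    """Parse GTF text into validated :class:`TranscriptModel` objects.

    Accepts a string or a readable text stream. Only ``exon``, ``CDS`` and
    ``stop_codon`` feature lines are consumed; other feature types (gene,
    transcript, UTR, start_codon, ...) are skipped silently. Coordinates are
    converted from the 1-based inclusive GTF convention to 0-based half-open.
    The gene biotype is read from the ``gene_biotype`` attribute, falling back
    to ``gene_type`` (GENCODE dialect) and then to ``"unknown"``.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GTFParseError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        if fields[2] not in _HANDLED_FEATURES:
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises bare ValueError on bad coords
            raise GTFParseError(f"line {lineno}: {exc}") from exc
        tid = _attr_first(feat.attributes, "transcript_id")
        gid = _attr_first(feat.attributes, "gene_id", default="unknown")
        if tid is None:
            raise GTFParseError(f"line {lineno}: missing transcript_id attribute")
        rec = per_tx.get(tid)
        if rec is None:
            rec = per_tx[tid] = {
                "gene_id": gid,
                "biotype": None,
                "strand": feat.strand,
                "exons": [],
                "cds": [],
                "stop": [],
            }
            order.append(tid)
        biotype = _attr_first(feat.attributes, "gene_biotype", "gene_type")
        if biotype is not None and rec["biotype"] is None:
            rec["biotype"] = biotype
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        {"exon": rec["exons"], "CDS": rec["cds"], "stop_codon": rec["stop"]}[
            feat.featuretype
        ].append(iv)

    models = []
    for tid in order:
        rec = per_tx[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                gene_biotype=rec["biotype"] or "unknown",
                strand=rec["strand"],
                exons=tuple(rec["exons"]),
                cds=tuple(rec["cds"]),
                stop_codon=tuple(rec["stop"]) or None,
            )
        )
    return models


def _gtf_line(t: TranscriptModel, feature: str, iv: GenomicInterval) -> str:
    attrs = (
        f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
        f'gene_biotype "{t.gene_biotype}";'
    )
    return "\t".join(
        (
            iv.chrom,
            "nmdscope",
            feature,
            str(iv.start + 1),
            str(iv.end),
            ".",
            iv.strand,
            ".",
            attrs,
        )
    )


def write_gtf(models: Iterable[TranscriptModel], stream: TextIO | None = None) -> str:
    """Serialize models to GTF text (1-based inclusive). Returns the text."""
    lines = []
    for t in models:
        for e in t.exons:
            lines.append(_gtf_line(t, "exon", e))
        for c in t.cds:
            lines.append(_gtf_line(t, "CDS", c))
        for s in t.stop_codon or ():
            lines.append(_gtf_line(t, "stop_codon", s))
    text = "\n".join(lines) + ("\n" if lines else "")
    if stream is not None:
        stream.write(text)
    return text
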