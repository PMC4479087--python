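"""NMD-susceptibility classification of transcripts.

A transcript is called NMD-prone when any of three annotation-derived
features holds:

* ``LONG_UTR3`` — the spliced 3'UTR is at least 1250 bp;
* ``UTR3_INTRON`` — an intron lies within the 3'UTR, i.e. both of its
  flanking exons are made up entirely of 3'UTR sequence;
* ``DOWNSTREAM_JUNCTION`` — an exon-exon junction sits more than 50 nt
  downstream of the stop codon in spliced coordinates.

All distances are exonic (spliced) base counts. The reference point is the
spliced offset of the stop codon's 3'-most base; a junction's distance is
``junction_offset - stop_offset`` where ``junction_offset`` is the offset of
the last exonic base 5' of the junction. A junction therefore counts as
downstream of the stop when at least one 3'UTR base precedes it (distance
>= 1); a junction falling exactly at the stop/UTR boundary has distance 0
and is not downstream. The two junction-based features are deliberately
disjoint in attribution: an intron whose upstream exon still contains coding
sequence is captured by the junction-distance criterion, not the 3'UTR-intron
criterion, so each triggered rule names an independent structural cause.

Transcripts without an annotated CDS or stop codon (non-coding biotypes)
are not evaluable: they are reported with zeroed features and are never
called prone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .annotation import TranscriptModel

__all__ = [
    "NMDFeatureSet",
    "NMDCall",
    "GeneNMD",
    "ConfigurationError",
    "RULE_LONG_UTR3",
    "RULE_UTR3_INTRON",
    "RULE_DOWNSTREAM_JUNCTION",
    "stop_codon_spliced_offset",
    "extract_nmd_features",
    "classify_nmd",
    "classify_transcript",
    "gene_level_nmd",
]

RULE_LONG_UTR3 = "LONG_UTR3"
RULE_UTR3_INTRON = "UTR3_INTRON"
RULE_DOWNSTREAM_JUNCTION = "DOWNSTREAM_JUNCTION"

DEFAULT_UTR3_MIN_BP = 1250
DEFAULT_JUNCTION_MIN_NT = 50


class ConfigurationError(ValueError):
    """Invalid threshold or policy configuration."""


@dataclass(frozen=True)
class NMDFeatureSet:
    """The three rule features of one transcript, in spliced coordinates.

    ``max_junction_distance`` is ``None`` when no junction lies downstream
    of the stop codon (or the transcript is not evaluable).
    """

    transcript_id: str
    evaluable: bool
    utr3_length: int = 0
    utr3_intron_count: int = 0
    max_junction_distance: int | None = None


@dataclass(frozen=True)
class NMDCall:
    transcript_id: str
    prone: bool
    triggered_rules: frozenset[str]
    utr3_min_bp: int = DEFAULT_UTR3_MIN_BP
    junction_min_nt: int = DEFAULT_JUNCTION_MIN_NT


@dataclass(frozen=True)
class GeneNMD:
    gene_id: str
    prone: bool
    n_transcripts: int
    n_prone: int


def stop_codon_spliced_offset(
    t: TranscriptModel, cds_includes_stop: bool = True
) -> int | None:
    """Spliced offset of the stop codon's 3'-most base, or None.

    Resolution order: explicit ``stop_codon`` features win; otherwise the
    stop is inferred from the CDS — its 3'-most 3 spliced bases when
    ``cds_includes_stop`` (Ensembl GTFs exclude the stop from CDS, many
    other dialects include it), else the 3 spliced bases immediately after
    the CDS (clamped at the transcript end). Returns None for transcripts
    with neither feature (not evaluable).
    """
    if t.stop_codon:
        return max(
            t.spliced_offset(pos)
            for iv in t.stop_codon
            for pos in range(iv.start, iv.end)
        )
    if not t.cds:
        return None
    cds_end = max(t.spliced_offset(pos) for iv in t.cds for pos in (iv.start, iv.end - 1))
    if cds_includes_stop:
        return cds_end
    return min(cds_end + 3, t.spliced_length - 1)


def extract_nmd_features(
    t: TranscriptModel, cds_includes_stop: bool = True
) -> NMDFeatureSet:
    """Measure 3'UTR length, 3'UTR introns and stop-to-junction distances."""
    stop = stop_codon_spliced_offset(t, cds_includes_stop=cds_includes_stop)
    if stop is None:
        return NMDFeatureSet(t.transcript_id, evaluable=False)

    utr3_length = t.spliced_length - (stop + 1)

    junctions = t.junction_spliced_offsets()
    downstream = [j - stop for j in junctions if j > stop]
    max_dist = max(downstream) if downstream else None

    # An intron is "in the 3'UTR" when the exon 5' of it (transcript order)
    # starts after the stop codon, i.e. contains no coding sequence.
    utr3_introns = 0
    running = 0
    tx_exons = t.exons_in_transcript_order()
    for e in tx_exons[:-1]:
        if running > stop:
            utr3_introns += 1
        running += len(e)

    return NMDFeatureSet(
        transcript_id=t.transcript_id,
        evaluable=True,
        utr3_length=utr3_length,
        utr3_intron_count=utr3_introns,
        max_junction_distance=max_dist,
    )


def classify_nmd(
    f: NMDFeatureSet,
    utr3_min_bp: int = DEFAULT_UTR3_MIN_BP,
    junction_min_nt: int = DEFAULT_JUNCTION_MIN_NT,
) -> NMDCall:
    """Apply the three-rule test: 3'UTR >= ``utr3_min_bp`` (inclusive), any
    3'UTR intron, or a junction strictly more than ``junction_min_nt``
    downstream of the stop."""
    if utr3_min_bp <= 0 or junction_min_nt <= 0:
        raise ConfigurationError(
            f"thresholds must be positive (utr3_min_bp={utr3_min_bp}, "
            f"junction_min_nt={junction_min_nt})"
        )
    rules: set[str] = set()
    if f.evaluable:
        if f.utr3_length >= utr3_min_bp:
            rules.add(RULE_LONG_UTR3)
        if f.utr3_intron_count >= 1:
            rules.add(RULE_UTR3_INTRON)
        if f.max_junction_distance is not None and f.max_junction_distance > junction_min_nt:
            rules.add(RULE_DOWNSTREAM_JUNCTION)
    return NMDCall(
        transcript_id=f.transcript_id,
        prone=bool(rules),
        triggered_rules=frozenset(rules),
        utr3_min_bp=utr3_min_bp,
        junction_min_nt=junction_min_nt,
    )


def classify_transcript(
    t: TranscriptModel,
    utr3_min_bp: int = DEFAULT_UTR3_MIN_BP,
    junction_min_nt: int = DEFAULT_JUNCTION_MIN_NT,
    cds_includes_stop: bool = True,
) -> tuple[NMDFeatureSet, NMDCall]:
    f = extract_nmd_features(t, cds_includes_stop=cds_includes_stop)
    return f, classify_nmd(f, utr3_min_bp=utr3_min_bp, junction_min_nt=junction_min_nt)


def gene_level_nmd(
    calls: Iterable[NMDCall],
    transcript_to_gene: Mapping[str, str],
    policy: str = "any",
) -> dict[str, GeneNMD]:
    """Aggregate transcript calls to genes.

    ``policy='any'`` (default): a gene is prone when at least one transcript
    is prone. ``policy='all'``: every evaluable transcript must be prone
    (genes with no prone transcript are not prone).
    """
    if policy not in ("any", "all"):
        raise ConfigurationError(f"unknown aggregation policy {policy!r}")
    per_gene: dict[str, list[NMDCall]] = {}
    for c in calls:
        gene = transcript_to_gene.get(c.transcript_id)
        if gene is None:
            raise ConfigurationError(
                f"transcript {c.transcript_id} has no gene mapping"
            )
        per_gene.setdefault(gene, []).append(c)
    out: dict[str, GeneNMD] = {}
    for gene, cs in per_gene.items():
        n_prone = sum(c.prone for c in cs)
        if policy == "any":
            prone = n_prone >= 1
        else:
            prone = n_prone >= 1 and all(c.prone for c in cs)
        out[gene] = GeneNMD(gene, prone, n_transcripts=len(cs), n_prone=n_prone)
    return out
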