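"""Synthetic inputs with planted ground truth.

Four generators emulate, at desk scale, the inputs the pipeline consumes:

* :func:`generate_annotation` — GTF transcript structures with controlled
  3'UTR geometry. Each planted NMD-prone transcript carries exactly one
  triggering feature (a >=1250 bp 3'UTR, one 3'UTR intron with all
  junctions <=50 nt downstream of the stop, or a junction 51-500 nt
  downstream of the stop), so rule attribution is testable; non-prone
  coding transcripts stay below every threshold, and a configurable
  fraction of genes are non-coding (no CDS, hence not evaluable).
* :func:`generate_expression` — a two-condition FPKM table with a planted
  fraction of DE genes at fixed fold changes and q <= 0.05; null genes sit
  near fold change 1 with q > 0.05.
* :func:`generate_genesets` — a GMT collection in which one set has an
  exact planted overlap with a designated query; the others are uniform
  draws from the universe.
* :func:`generate_events` — a MISO-style event table with a planted set of
  significant events (BF > 10, |Δψ| > 0.2, reads above the floor); every
  null event violates at least one criterion.

All outputs are plain text and byte-reproducible: a single integer seed
drives one assignment stream, and per-entity geometry uses a child stream
keyed by (seed, entity index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation import GenomicInterval, TranscriptModel, write_gtf
from .nmd import RULE_DOWNSTREAM_JUNCTION, RULE_LONG_UTR3, RULE_UTR3_INTRON
from .splicing import EVENT_TYPES

__all__ = [
    "GenerationError",
    "SyntheticTruth",
    "generate_annotation",
    "generate_expression",
    "generate_genesets",
    "generate_events",
    "DEFAULT_EVENT_COMPOSITION",
]


class GenerationError(ValueError):
    """Requested synthetic geometry or parameters are infeasible."""


@dataclass
class SyntheticTruth:
    """Planted ground truth; each generator fills the fields it owns."""

    seed: int
    nmd_labels: dict[str, str] = field(default_factory=dict)  # tid -> prone|not_prone|not_evaluable
    planted_rules: dict[str, str] = field(default_factory=dict)  # tid -> rule name
    transcript_to_gene: dict[str, str] = field(default_factory=dict)
    gene_biotypes: dict[str, str] = field(default_factory=dict)
    gene_prone: dict[str, bool] = field(default_factory=dict)
    de_genes: dict[str, str] = field(default_factory=dict)  # gid -> up|down|null
    enriched_sets: dict[str, int] = field(default_factory=dict)  # set -> planted k
    significant_events: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "nmd_labels": dict(sorted(self.nmd_labels.items())),
            "planted_rules": dict(sorted(self.planted_rules.items())),
            "transcript_to_gene": dict(sorted(self.transcript_to_gene.items())),
            "gene_biotypes": dict(sorted(self.gene_biotypes.items())),
            "gene_prone": dict(sorted(self.gene_prone.items())),
            "de_genes": dict(sorted(self.de_genes.items())),
            "enriched_sets": dict(sorted(self.enriched_sets.items())),
            "significant_events": sorted(self.significant_events),
        }
        return json.dumps(payload, indent=2, sort_keys=False) + "\n"


# ---------------------------------------------------------------------------
# annotation generator

_NONCODING_BIOTYPES = ("lincRNA", "antisense", "processed_pseudogene")
_PLANTED_FEATURES = (RULE_LONG_UTR3, RULE_UTR3_INTRON, RULE_DOWNSTREAM_JUNCTION)


@dataclass(frozen=True)
class _SplicedDesign:
    """One transcript in spliced coordinates, before genomic layout."""

    junctions: tuple[int, ...]  # offsets of exon-final bases, transcript order
    total: int  # spliced length
    cds_start: int | None  # spliced start of CDS (None for non-coding)
    cds_end: int | None  # spliced offset one past the stop codon


def _coding_design(rng: np.random.Generator, planted: str | None) -> _SplicedDesign:
    """Spliced design of one coding transcript; the planted feature (if any)
    fixes the 3' structure, upstream junctions fall within 5'UTR+CDS."""
    utr5 = int(rng.integers(20, 301))
    cds_len = 3 * int(rng.integers(100, 501))  # includes the stop codon
    stop = utr5 + cds_len - 1  # spliced offset of the stop's 3'-most base

    junctions: list[int] = []
    n_up = int(rng.integers(0, 4))
    if n_up:
        pool = rng.choice(np.arange(10, stop - 10), size=n_up, replace=False)
        junctions.extend(int(j) for j in sorted(pool))

    if planted is None:
        utr3 = int(rng.integers(60, 1200))
        if rng.random() < 0.3:  # benign junction <=50 nt downstream of stop
            d = int(rng.integers(1, min(50, utr3 - 1) + 1))
            junctions.append(stop + d)
    elif planted == RULE_LONG_UTR3:
        utr3 = int(rng.integers(1250, 5001))
    elif planted == RULE_UTR3_INTRON:
        # stop exon ends at the stop; a short pure-UTR exon (junction <=50 nt
        # downstream) is followed by the final exon, so only the 3'UTR-intron
        # rule fires.
        utr3 = int(rng.integers(120, 1200))
        first_utr_exon = int(rng.integers(1, 51))
        junctions.append(stop)
        junctions.append(stop + first_utr_exon)
    elif planted == RULE_DOWNSTREAM_JUNCTION:
        d = int(rng.integers(51, 501))
        utr3 = int(rng.integers(d + 1, 1250))
        junctions.append(stop + d)
    else:  # pragma: no cover - internal misuse
        raise GenerationError(f"unknown planted feature {planted!r}")

    total = utr5 + cds_len + utr3
    if junctions and junctions[-1] >= total - 1:
        raise GenerationError("junction beyond transcript end")
    return _SplicedDesign(tuple(junctions), total, utr5, utr5 + cds_len)


def _noncoding_design(rng: np.random.Generator) -> _SplicedDesign:
    n_ex = int(rng.integers(1, 5))
    lens = [int(x) for x in rng.integers(100, 801, size=n_ex)]
    bounds = np.cumsum(lens)
    junctions = tuple(int(b) - 1 for b in bounds[:-1])
    return _SplicedDesign(junctions, int(bounds[-1]), None, None)


def _lay_out(
    rng: np.random.Generator,
    chrom: str,
    cursor: int,
    strand: str,
    design: _SplicedDesign,
) -> tuple[tuple[GenomicInterval, ...], int]:
    """Place spliced exon spans on the genome; returns exons + new cursor."""
    bounds = [0, *[j + 1 for j in design.junctions], design.total]
    exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]
    n_introns = len(exon_lens) - 1
    intron_lens = [int(x) for x in rng.integers(80, 2001, size=n_introns)]
    spans = []  # plus-layout in transcript order
    g = 0
    for i, elen in enumerate(exon_lens):
        spans.append((g, g + elen))
        g += elen + (intron_lens[i] if i < n_introns else 0)
    span_total = g
    exons = []
    for a, b in spans:
        if strand == "+":
            exons.append(GenomicInterval(chrom, cursor + a, cursor + b, strand))
        else:
            exons.append(
                GenomicInterval(
                    chrom, cursor + span_total - b, cursor + span_total - a, strand
                )
            )
    exons.sort(key=lambda iv: iv.start)
    return tuple(exons), cursor + span_total + 5000


def generate_annotation(
    n_genes: int = 50,
    transcripts_per_gene: int = 1,
    prone_fraction: float = 0.4,
    noneval_fraction: float = 0.15,
    seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """Synthetic GTF with planted NMD labels.

    ``noneval_fraction`` of genes are non-coding (their transcripts lack a
    CDS and are not evaluable); among the transcripts of the remaining
    coding genes, ``prone_fraction`` are planted NMD-prone, each with
    exactly one triggering feature chosen uniformly. Returns GTF text plus
    the truth record (labels, planted rules, gene mapping and biotypes,
    gene-level prone flags under any-transcript aggregation).
    """
    if not 0.0 <= prone_fraction <= 1.0 or not 0.0 <= noneval_fraction <= 1.0:
        raise GenerationError("fractions must lie in [0, 1]")
    if n_genes < 1 or transcripts_per_gene < 1:
        raise GenerationError("need at least one gene and one transcript per gene")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)

    n_noneval_genes = round(n_genes * noneval_fraction)
    noneval_genes = {int(g) for g in rng.permutation(n_genes)[:n_noneval_genes]}

    coding_tx = [
        (g, k)
        for g in range(n_genes)
        if g not in noneval_genes
        for k in range(transcripts_per_gene)
    ]
    n_prone = round(len(coding_tx) * prone_fraction)
    prone_pick = rng.permutation(len(coding_tx))[:n_prone]
    prone_set = {coding_tx[int(i)] for i in prone_pick}
    feature_for = {
        key: _PLANTED_FEATURES[int(rng.integers(0, len(_PLANTED_FEATURES)))]
        for key in sorted(prone_set)
    }

    models: list[TranscriptModel] = []
    cursors: dict[str, int] = {}
    tx_index = 0
    for g in range(n_genes):
        gid = f"SYNG{g:04d}"
        chrom = f"chr{g % 5 + 1}"
        cursor = cursors.get(chrom, 1000)
        noncoding = g in noneval_genes
        biotype = (
            _NONCODING_BIOTYPES[g % len(_NONCODING_BIOTYPES)]
            if noncoding
            else "protein_coding"
        )
        truth.gene_biotypes[gid] = biotype
        any_prone = False
        for k in range(transcripts_per_gene):
            tid = f"SYNT{g:04d}.{k}"
            trng = np.random.default_rng([seed, tx_index])
            tx_index += 1
            strand = "+" if trng.random() < 0.5 else "-"
            if noncoding:
                design = _noncoding_design(trng)
                label = "not_evaluable"
            else:
                planted = feature_for.get((g, k))
                design = _coding_design(trng, planted)
                label = "prone" if planted else "not_prone"
                if planted:
                    truth.planted_rules[tid] = planted
                    any_prone = True
            exons, cursor = _lay_out(trng, chrom, cursor, strand, design)
            skeleton = TranscriptModel(tid, gid, biotype, strand, exons)
            cds = ()
            if design.cds_start is not None:
                cds = skeleton.spliced_range_to_genomic(design.cds_start, design.cds_end)
            models.append(
                TranscriptModel(tid, gid, biotype, strand, exons, cds=cds)
            )
            truth.nmd_labels[tid] = label
            truth.transcript_to_gene[tid] = gid
        truth.gene_prone[gid] = any_prone
        cursors[chrom] = cursor

    return write_gtf(models), truth


# ---------------------------------------------------------------------------
# expression generator


def generate_expression(
    genes: Sequence[str] | SyntheticTruth,
    de_fraction: float = 0.1,
    up_down_ratio: float = 1.0,
    fc_up: float = 3.0,
    fc_down: float = 1.0 / 3.0,
    seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """Two-condition FPKM table (TSV) with planted DE genes.

    ``genes`` is a gene-id list or an annotation truth (its genes are
    reused so expression joins the annotation). DE genes receive the fixed
    fold change and q uniform in (0, 0.05]; null genes receive fold change
    uniform in [0.9, 1.1] and q uniform in (0.05, 1]. Control FPKM is
    log-uniform over [1, 100].
    """
    if isinstance(genes, SyntheticTruth):
        gene_ids = sorted(genes.gene_biotypes) or sorted(
            set(genes.transcript_to_gene.values())
        )
    else:
        gene_ids = list(genes)
    n = len(gene_ids)
    if n == 0:
        raise GenerationError("no genes to simulate expression for")
    if not 0.0 <= de_fraction <= 1.0:
        raise GenerationError("de_fraction must lie in [0, 1]")
    if up_down_ratio < 0:
        raise GenerationError("up_down_ratio must be non-negative")
    if not (fc_up > 1.5 and 0 <= fc_down < 0.67):
        raise GenerationError(
            "planted fold changes must be detectable: fc_up > 1.5 and "
            f"fc_down < 0.67 (got fc_up={fc_up}, fc_down={fc_down})"
        )

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    n_de = round(n * de_fraction)
    n_up = round(n_de * up_down_ratio / (1.0 + up_down_ratio)) if n_de else 0
    order = rng.permutation(n)
    de_idx = [int(i) for i in order[:n_de]]
    up_idx = set(de_idx[:n_up])

    lines = ["gene_id\tfpkm_control\tfpkm_case\tq_value"]
    status = {}
    for i, gid in enumerate(gene_ids):
        ctrl = float(10.0 ** rng.uniform(0.0, 2.0))
        if i in up_idx:
            fc = fc_up
            q = float(rng.uniform(1e-4, 0.05))
            status[gid] = "up"
        elif i in de_idx:
            fc = fc_down
            q = float(rng.uniform(1e-4, 0.05))
            status[gid] = "down"
        else:
            fc = float(rng.uniform(0.9, 1.1))
            q = float(rng.uniform(0.051, 1.0))
            status[gid] = "null"
        case = ctrl * fc
        lines.append(f"{gid}\t{ctrl:.6g}\t{case:.6g}\t{q:.6g}")
    truth.de_genes = status
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# gene-set generator


def generate_genesets(
    universe: Sequence[str],
    query: Sequence[str],
    n_sets: int = 5,
    set_size: int = 50,
    planted_overlap: int = 20,
    seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """GMT collection with one set of exact planted overlap with ``query``.

    The first set ("planted_set") shares exactly ``planted_overlap`` genes
    with the query (the rest of its members are drawn outside the query);
    the remaining sets are uniform draws from the universe, independent of
    the query.
    """
    uni = sorted(set(universe))
    qry = sorted(set(query))
    if not set(qry) <= set(uni):
        raise GenerationError("query must be a subset of the universe")
    if set_size > len(uni):
        raise GenerationError("set_size exceeds universe size")
    if planted_overlap > min(set_size, len(qry)):
        raise GenerationError(
            f"planted overlap {planted_overlap} infeasible for set_size="
            f"{set_size}, query={len(qry)}"
        )
    non_query = sorted(set(uni) - set(qry))
    if set_size - planted_overlap > len(non_query):
        raise GenerationError("not enough non-query genes to fill the planted set")
    if n_sets < 1:
        raise GenerationError("need at least one set")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    lines = []

    hit = [str(x) for x in rng.choice(qry, size=planted_overlap, replace=False)]
    pad = [
        str(x)
        for x in rng.choice(non_query, size=set_size - planted_overlap, replace=False)
    ]
    lines.append("\t".join(["planted_set", "synthetic", *sorted(hit + pad)]))
    truth.enriched_sets["planted_set"] = planted_overlap

    for s in range(1, n_sets):
        members = [str(x) for x in rng.choice(uni, size=set_size, replace=False)]
        lines.append("\t".join([f"random_set_{s:02d}", "synthetic", *sorted(members)]))

    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# splicing-event generator

# The printed event-type composition of the study this emulates covers four
# of the five categories (SE, ALE, A3SS, A5SS); AFE is part of the
# vocabulary but has no printed share, so its default weight is 0.
DEFAULT_EVENT_COMPOSITION: Mapping[str, float] = {
    "SE": 0.614,
    "ALE": 0.185,
    "A3SS": 0.1115,
    "A5SS": 0.0924,
    "AFE": 0.0,
}


def _integer_counts(weights: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items over EVENT_TYPES."""
    w = {t: float(weights.get(t, 0.0)) for t in EVENT_TYPES}
    if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
        raise GenerationError("composition weights must be non-negative, sum > 0")
    total = sum(w.values())
    exact = {t: n * v / total for t, v in w.items()}
    counts = {t: int(np.floor(x)) for t, x in exact.items()}
    short = n - sum(counts.values())
    remainders = sorted(
        EVENT_TYPES, key=lambda t: (-(exact[t] - counts[t]), EVENT_TYPES.index(t))
    )
    for t in remainders[:short]:
        counts[t] += 1
    return counts


def generate_events(
    n_events: int = 500,
    sig_fraction: float = 0.2,
    composition: Mapping[str, float] | None = None,
    min_reads: int = 20,
    seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """MISO-style event table (TSV) with planted significant events.

    Significant events have BF in (10, 1e6], |Δψ| in (0.2, 0.8] and reads
    at or above ``min_reads``; each null event violates exactly one
    criterion (low BF, small |Δψ| or shallow coverage). Event types follow
    ``composition`` (largest-remainder integer counts within the
    significant and null groups separately).
    """
    if not 0.0 <= sig_fraction <= 1.0:
        raise GenerationError("sig_fraction must lie in [0, 1]")
    if n_events < 1:
        raise GenerationError("need at least one event")
    comp = composition or DEFAULT_EVENT_COMPOSITION

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    n_sig = round(n_events * sig_fraction)

    sig_types = [t for t, c in _integer_counts(comp, n_sig).items() for _ in range(c)]
    null_types = [
        t for t, c in _integer_counts(comp, n_events - n_sig).items() for _ in range(c)
    ]

    n_genes = max(1, n_events // 4)
    rows = []
    for i in range(n_events):
        eid = f"EV{i:05d}"
        gid = f"EVG{int(rng.integers(0, n_genes)):04d}"
        significant = i < n_sig
        etype = sig_types[i] if significant else null_types[i - n_sig]
        if significant:
            bf = float(10.0 ** rng.uniform(1.05, 6.0))
            dpsi = float(rng.uniform(0.21, 0.8))
            reads = int(rng.integers(min_reads, min_reads + 200))
            truth.significant_events.add(eid)
        else:
            mode = int(rng.integers(0, 3))
            if mode == 0:  # weak evidence
                bf = float(rng.uniform(0.0, 9.9))
                dpsi = float(rng.uniform(0.0, 0.8))
                reads = int(rng.integers(min_reads, min_reads + 200))
            elif mode == 1:  # small effect
                bf = float(10.0 ** rng.uniform(1.05, 6.0))
                dpsi = float(rng.uniform(0.0, 0.19))
                reads = int(rng.integers(min_reads, min_reads + 200))
            else:  # shallow coverage
                bf = float(10.0 ** rng.uniform(1.05, 6.0))
                dpsi = float(rng.uniform(0.21, 0.8))
                reads = int(rng.integers(0, min_reads))
        lo = float(rng.uniform(0.0, 1.0 - dpsi))
        if rng.random() < 0.5:
            psi_c, psi_t = lo, lo + dpsi
        else:
            psi_c, psi_t = lo + dpsi, lo
        rows.append((eid, gid, etype, psi_c, psi_t, bf, reads))

    # shuffle row order so significance is not positional in the file
    order = rng.permutation(n_events)
    lines = [
        "event_id\tgene_id\tevent_type\tpsi_control\tpsi_case\tbayes_factor\tinformative_reads"
    ]
    for i in order:
        eid, gid, etype, psi_c, psi_t, bf, reads = rows[int(i)]
        lines.append(
            f"{eid}\t{gid}\t{etype}\t{psi_c:.6g}\t{psi_t:.6g}\t{bf:.6g}\t{reads}"
        )
    return "\n".join(lines) + "\n", truth
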