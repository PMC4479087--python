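"""Shared fixtures and independent brute-force oracles.

The oracles here never touch the package's coordinate arithmetic: they
enumerate every exonic base of a transcript in 5'->3' order and compute
spliced offsets, junction positions, stop location and the three NMD rule
features by direct counting over that list.
"""

from __future__ import annotations

import numpy as np
import pytest

from nmdscope.annotation import GenomicInterval, TranscriptModel

# ---------------------------------------------------------------------------
# per-base enumeration oracle


def enumerate_bases(t: TranscriptModel) -> list[int]:
    """Genomic position of every spliced base, transcript orientation."""
    positions = [p for e in sorted(t.exons, key=lambda e: e.start) for p in range(e.start, e.end)]
    return positions[::-1] if t.strand == "-" else positions


def base_exon_index(t: TranscriptModel) -> list[int]:
    """Transcript-order exon index of every spliced base."""
    exons_tx = t.exons if t.strand == "+" else t.exons[::-1]
    idx: list[int] = []
    for i, e in enumerate(exons_tx):
        idx.extend([i] * (e.end - e.start))
    return idx


def oracle_spliced_offset(t: TranscriptModel, pos: int) -> int:
    return enumerate_bases(t).index(pos)


def oracle_junction_offsets(t: TranscriptModel) -> list[int]:
    idx = base_exon_index(t)
    return [i for i in range(len(idx) - 1) if idx[i] != idx[i + 1]]


def oracle_stop_offset(t: TranscriptModel, cds_includes_stop: bool = True) -> int | None:
    bases = enumerate_bases(t)
    if t.stop_codon:
        hits = [
            i for i, p in enumerate(bases) if any(s.contains(p) for s in t.stop_codon)
        ]
        return max(hits) if hits else None
    if not t.cds:
        return None
    hits = [i for i, p in enumerate(bases) if any(c.contains(p) for c in t.cds)]
    last = max(hits)
    return last if cds_includes_stop else min(last + 3, len(bases) - 1)


def oracle_nmd_features(t: TranscriptModel, cds_includes_stop: bool = True) -> dict:
    """Direct-count NMD features; mirrors the documented conventions only
    through base bookkeeping, never through the package's arithmetic."""
    stop = oracle_stop_offset(t, cds_includes_stop)
    if stop is None:
        return {"evaluable": False, "utr3": 0, "n_utr3_introns": 0, "max_dist": None}
    idx = base_exon_index(t)
    L = len(idx)
    utr3 = sum(1 for i in range(L) if i > stop)
    junctions = oracle_junction_offsets(t)
    down = [j - stop for j in junctions if j > stop]
    exon_min_offset: dict[int, int] = {}
    for i, k in enumerate(idx):
        exon_min_offset.setdefault(k, i)
    n_introns = sum(1 for j in junctions if exon_min_offset[idx[j]] > stop)
    return {
        "evaluable": True,
        "utr3": utr3,
        "n_utr3_introns": n_introns,
        "max_dist": max(down) if down else None,
    }


def oracle_prone(t: TranscriptModel, utr3_min=1250, junction_min=50, cds_includes_stop=True) -> bool:
    f = oracle_nmd_features(t, cds_includes_stop)
    if not f["evaluable"]:
        return False
    return (
        f["utr3"] >= utr3_min
        or f["n_utr3_introns"] >= 1
        or (f["max_dist"] is not None and f["max_dist"] > junction_min)
    )


# ---------------------------------------------------------------------------
# transcript construction helpers (independent of the simulate module)


def _spliced_span_to_intervals(
    exons: list[GenomicInterval], strand: str, a: int, b: int
) -> tuple[GenomicInterval, ...]:
    """Map spliced [a, b) to genomic intervals by flat enumeration."""
    positions = [p for e in sorted(exons, key=lambda e: e.start) for p in range(e.start, e.end)]
    if strand == "-":
        positions = positions[::-1]
    chosen = sorted(positions[a:b])
    ivs = []
    chrom = exons[0].chrom
    run_start = prev = chosen[0]
    for p in chosen[1:]:
        if p != prev + 1:
            ivs.append(GenomicInterval(chrom, run_start, prev + 1, strand))
            run_start = p
        prev = p
    ivs.append(GenomicInterval(chrom, run_start, prev + 1, strand))
    return tuple(ivs)


def build_tx(
    exon_lens: list[int],
    cds: tuple[int, int] | None = None,
    stop_codon: tuple[int, int] | None = None,
    strand: str = "+",
    intron_len: int = 100,
    origin: int = 0,
    tid: str = "T1",
    gid: str = "G1",
    biotype: str = "protein_coding",
    chrom: str = "chrT",
) -> TranscriptModel:
    """Build a transcript from transcript-order exon lengths.

    ``cds`` / ``stop_codon`` are half-open spliced ranges; they are laid
    onto the genome by per-base enumeration.
    """
    spans = []
    g = 0
    for elen in exon_lens:
        spans.append((g, g + elen))
        g += elen + intron_len
    total_span = g - intron_len
    if strand == "+":
        exons = [GenomicInterval(chrom, origin + a, origin + b, strand) for a, b in spans]
    else:
        exons = [
            GenomicInterval(chrom, origin + total_span - b, origin + total_span - a, strand)
            for a, b in spans
        ]
    cds_ivs = _spliced_span_to_intervals(exons, strand, *cds) if cds else ()
    stop_ivs = (
        _spliced_span_to_intervals(exons, strand, *stop_codon) if stop_codon else None
    )
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        gene_biotype=biotype,
        strand=strand,
        exons=tuple(sorted(exons, key=lambda e: e.start)),
        cds=cds_ivs,
        stop_codon=stop_ivs,
    )


def random_transcript(
    rng: np.random.Generator,
    coding: bool = True,
    tid: str = "T1",
    gid: str = "G1",
) -> TranscriptModel:
    """Random structure: 1-8 exons, random lengths, strand, CDS placement."""
    n_exons = int(rng.integers(1, 9))
    exon_lens = [int(x) for x in rng.integers(3, 800, size=n_exons)]
    strand = "+" if rng.random() < 0.5 else "-"
    total = sum(exon_lens)
    cds = None
    if coding and total >= 9:
        a = int(rng.integers(0, total - 6))
        b = int(rng.integers(a + 3, min(total, a + 2000) + 1))
        cds = (a, b)
    return build_tx(
        exon_lens,
        cds=cds,
        strand=strand,
        intron_len=int(rng.integers(60, 500)),
        origin=int(rng.integers(0, 10_000)),
        biotype="protein_coding" if cds else "lincRNA",
        tid=tid,
        gid=gid,
    )


# ---------------------------------------------------------------------------
# fixtures

TOY_GTF = (
    'chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_biotype "protein_coding";\n'
    'chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_biotype "protein_coding";\n'
    'chr1\ttest\tCDS\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_biotype "protein_coding";\n'
    'chr1\ttest\tgene\t101\t400\t.\t+\t.\tgene_id "G1";\n'
)


@pytest.fixture
def toy_gtf() -> str:
    return TOY_GTF


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
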