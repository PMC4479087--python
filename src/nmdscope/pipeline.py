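"""End-to-end orchestration: annotate -> NMD classify -> DE filter ->
intersect -> enrich -> splicing summary.

Every stage's table is written to the output directory as TSV and the run
is summarized in a single JSON report whose fractions always carry their
explicit numerator and denominator. Reports contain no timestamps, so a
rerun with identical inputs and configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .annotation import parse_gtf
from .de import (
    DEFAULT_DOWN_MAX,
    DEFAULT_Q_MAX,
    DEFAULT_UP_MIN,
    DEResult,
    biotype_breakdown,
    filter_de,
    read_expression_table,
)
from .enrichment import DEFAULT_ALPHA, cross_reference, read_gmt
from .nmd import (
    DEFAULT_JUNCTION_MIN_NT,
    DEFAULT_UTR3_MIN_BP,
    classify_transcript,
    gene_level_nmd,
)
from .splicing import (
    DEFAULT_BF_MIN,
    DEFAULT_DPSI_MIN,
    DEFAULT_MIN_READS,
    filter_events,
    read_events_table,
    summarize_events,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "intersect_de_nmd"]

log = logging.getLogger("nmdscope")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Thresholds (defaults are the published cutoffs), paths and policies."""

    gtf: str = ""
    expression: str = ""
    gmt: str = ""
    events: str = ""
    out_dir: str = "nmdscope_out"

    utr3_min_bp: int = DEFAULT_UTR3_MIN_BP
    junction_min_nt: int = DEFAULT_JUNCTION_MIN_NT
    q_max: float = DEFAULT_Q_MAX
    up_min: float = DEFAULT_UP_MIN
    down_max: float = DEFAULT_DOWN_MAX
    bf_min: float = DEFAULT_BF_MIN
    dpsi_min: float = DEFAULT_DPSI_MIN
    min_reads: int = DEFAULT_MIN_READS
    alpha: float = DEFAULT_ALPHA

    pseudocount: float = 0.0
    cds_includes_stop: bool = True
    universe_policy: str = "expressed"  # or "annotated"
    aggregation: str = "any"  # gene-level NMD policy
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError("config", f"unknown keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def intersect_de_nmd(
    de: list[DEResult], gene_prone: Mapping[str, bool]
) -> tuple[int, int, float]:
    """Count DE genes whose gene-level NMD flag is set.

    Returns (n_prone, n_de, fraction). Genes absent from the NMD table
    count as not prone.
    """
    if not de:
        raise ValueError("empty DE set: NMD intersection undefined")
    n_de = len(de)
    n_prone = sum(1 for r in de if gene_prone.get(r.gene_id, False))
    return n_prone, n_de, n_prone / n_de


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path_str: str, stage: str) -> Path:
    if not path_str:
        raise PipelineError(stage, "no input file configured")
    p = Path(path_str)
    if not p.is_file():
        raise PipelineError(stage, f"input file not found: {p}")
    return p


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the report dict.

    Intermediates land in ``config.out_dir`` as TSV, the report as
    ``report.json``. Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}

    # -- annotation -------------------------------------------------------
    gtf_path = _require(config.gtf, "annotation")
    checksums["gtf"] = _sha256(gtf_path)
    try:
        models = parse_gtf(gtf_path.read_text())
    except Exception as exc:
        raise PipelineError("annotation", str(exc)) from exc
    log.info("annotation: %d transcripts", len(models))

    # -- NMD classification ----------------------------------------------
    try:
        feats_calls = [
            classify_transcript(
                t,
                utr3_min_bp=config.utr3_min_bp,
                junction_min_nt=config.junction_min_nt,
                cds_includes_stop=config.cds_includes_stop,
            )
            for t in models
        ]
        tx2gene = {t.transcript_id: t.gene_id for t in models}
        calls = [c for _, c in feats_calls]
        genes_nmd = gene_level_nmd(calls, tx2gene, policy=config.aggregation)
    except Exception as exc:
        raise PipelineError("nmd_classify", str(exc)) from exc

    _write_tsv(
        out / "nmd_transcripts.tsv",
        [
            "transcript_id",
            "gene_id",
            "evaluable",
            "utr3_length",
            "utr3_intron_count",
            "max_junction_distance",
            "prone",
            "triggered_rules",
        ],
        [
            [
                f.transcript_id,
                tx2gene[f.transcript_id],
                f.evaluable,
                f.utr3_length,
                f.utr3_intron_count,
                "" if f.max_junction_distance is None else f.max_junction_distance,
                c.prone,
                ",".join(sorted(c.triggered_rules)),
            ]
            for f, c in feats_calls
        ],
    )
    _write_tsv(
        out / "nmd_genes.tsv",
        ["gene_id", "prone", "n_transcripts", "n_prone"],
        [
            [g.gene_id, g.prone, g.n_transcripts, g.n_prone]
            for g in sorted(genes_nmd.values(), key=lambda g: g.gene_id)
        ],
    )
    log.info("nmd_classify: %d/%d genes prone", sum(g.prone for g in genes_nmd.values()), len(genes_nmd))

    # -- DE filter --------------------------------------------------------
    expr_path = _require(config.expression, "de_filter")
    checksums["expression"] = _sha256(expr_path)
    try:
        records = read_expression_table(expr_path)
        de = filter_de(
            records,
            q_max=config.q_max,
            up_min=config.up_min,
            down_max=config.down_max,
            pseudocount=config.pseudocount,
        )
    except Exception as exc:
        raise PipelineError("de_filter", str(exc)) from exc
    de = sorted(de, key=lambda r: r.gene_id)
    _write_tsv(
        out / "de_genes.tsv",
        ["gene_id", "fold_change", "direction", "q_value"],
        [[r.gene_id, f"{r.fold_change:.6g}", r.direction, f"{r.q_value:.6g}"] for r in de],
    )
    n_annotated = len({t.gene_id for t in models})
    detected = [r for r in records if r.fpkm_control > 0 or r.fpkm_case > 0]
    log.info("de_filter: %d/%d records retained", len(de), len(records))

    # -- biotype breakdown ------------------------------------------------
    breakdown_rows = []
    if de:
        try:
            bd = biotype_breakdown(de, models)
        except Exception as exc:
            raise PipelineError("biotype_breakdown", str(exc)) from exc
        breakdown_rows = [
            [r.biotype, r.count, f"{r.percent:.6g}"] for r in bd.itertuples()
        ]
    _write_tsv(out / "biotype_breakdown.tsv", ["biotype", "count", "percent"], breakdown_rows)

    # -- DE x NMD intersection -------------------------------------------
    nmd_section = None
    if de:
        prone_flags = {g.gene_id: g.prone for g in genes_nmd.values()}
        n_prone, n_de, frac = intersect_de_nmd(de, prone_flags)
        nmd_section = {
            "n_nmd_prone_de": n_prone,
            "n_de": n_de,
            "fraction_nmd_prone": frac,
        }
        log.info("intersect: %d/%d DE genes NMD-prone", n_prone, n_de)

    # -- enrichment -------------------------------------------------------
    gmt_path = _require(config.gmt, "enrichment")
    checksums["gmt"] = _sha256(gmt_path)
    query = [r.gene_id for r in de]
    if not query:
        raise PipelineError("enrichment", "empty query: no DE genes to cross-reference")
    if config.universe_policy == "expressed":
        universe = [r.gene_id for r in detected]
    elif config.universe_policy == "annotated":
        universe = sorted({t.gene_id for t in models})
    else:
        raise PipelineError(
            "enrichment", f"unknown universe policy {config.universe_policy!r}"
        )
    try:
        sets = read_gmt(gmt_path)
        enr = cross_reference(query, sets, universe, alpha=config.alpha)
    except Exception as exc:
        raise PipelineError("enrichment", str(exc)) from exc
    _write_tsv(
        out / "enrichment.tsv",
        ["set_name", "N", "K", "n", "k", "p_value", "significant", "degenerate"],
        [
            [
                r.set_name,
                r.universe_size,
                r.set_size_in_universe,
                r.query_size_in_universe,
                r.overlap,
                f"{r.p_value:.6g}",
                r.significant,
                r.degenerate,
            ]
            for r in enr
        ],
    )
    log.info("enrichment: %d/%d sets significant", sum(r.significant for r in enr), len(enr))

    # -- splicing ---------------------------------------------------------
    events_path = _require(config.events, "splicing")
    checksums["events"] = _sha256(events_path)
    try:
        events = read_events_table(events_path)
        sig = filter_events(
            events,
            bf_min=config.bf_min,
            dpsi_min=config.dpsi_min,
            min_reads=config.min_reads,
        )
        summary = summarize_events(sig) if sig else None
    except Exception as exc:
        raise PipelineError("splicing", str(exc)) from exc
    _write_tsv(
        out / "splicing_significant.tsv",
        ["event_id", "gene_id", "event_type", "psi_control", "psi_case", "bayes_factor", "informative_reads"],
        [
            [
                e.event_id,
                e.gene_id,
                e.event_type,
                f"{e.psi_control:.6g}",
                f"{e.psi_case:.6g}",
                f"{e.bayes_factor:.6g}",
                e.informative_reads,
            ]
            for e in sorted(sig, key=lambda e: e.event_id)
        ],
    )
    log.info("splicing: %d/%d events significant", len(sig), len(events))

    # -- report -----------------------------------------------------------
    report = {
        "tool": {"name": "nmdscope", "version": __version__},
        "config": asdict(config),
        "input_checksums": checksums,
        "annotation": {
            "n_transcripts": len(models),
            "n_genes": n_annotated,
        },
        "nmd": {
            "n_transcripts_evaluable": sum(f.evaluable for f, _ in feats_calls),
            "n_transcripts_prone": sum(c.prone for _, c in feats_calls),
            "n_genes_prone": sum(g.prone for g in genes_nmd.values()),
            "n_genes": len(genes_nmd),
        },
        "de": {
            "n_de_genes": len(de),
            "n_up": sum(r.direction == "up" for r in de),
            "n_down": sum(r.direction == "down" for r in de),
            "n_annotated_genes": n_annotated,
            "n_detected_genes": len(detected),
            "de_fraction_of_annotated": (len(de) / n_annotated) if n_annotated else None,
            "de_fraction_of_detected": (len(de) / len(detected)) if detected else None,
        },
        "biotype_breakdown": [
            {"biotype": b, "count": int(c), "percent": float(p)}
            for b, c, p in breakdown_rows
        ],
        "de_nmd_intersection": nmd_section,
        "enrichment": [
            {
                "set_name": r.set_name,
                "N": r.universe_size,
                "K": r.set_size_in_universe,
                "n": r.query_size_in_universe,
                "k": r.overlap,
                "p_value": r.p_value,
                "significant": r.significant,
                "degenerate": r.degenerate,
            }
            for r in enr
        ],
        "splicing": {
            "n_events_total": len(events),
            "n_events_significant": len(sig),
            "n_genes": summary.n_genes if summary else 0,
            "event_type_counts": summary.counts if summary else {},
            "event_type_percent": summary.proportions if summary else {},
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
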