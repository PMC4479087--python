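"""Alternative-splicing event filtering and composition summary.

Events come from a MISO-style summary table: per event a ψ (fraction
spliced in) for each condition and a Bayes factor for the hypothesis of a
nonzero between-condition Δψ. An event is significant when BF > 10 and
|Δψ| > 0.2 (both strict) and it carries at least the minimum number of
informative reads (a single coverage floor standing in for MISO's default
per-event read-class thresholds). MISO emits BF = +inf for overwhelming
evidence; such events pass the BF criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .nmd import ConfigurationError

__all__ = [
    "EVENT_TYPES",
    "SplicingEvent",
    "SplicingSummary",
    "delta_psi",
    "filter_events",
    "summarize_events",
    "read_events_table",
]

EVENT_TYPES = ("SE", "A3SS", "A5SS", "ALE", "AFE")

DEFAULT_BF_MIN = 10.0
DEFAULT_DPSI_MIN = 0.2
DEFAULT_MIN_READS = 20


@dataclass(frozen=True)
class SplicingEvent:
    event_id: str
    gene_id: str
    event_type: str
    psi_control: float
    psi_case: float
    bayes_factor: float
    informative_reads: int

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"{self.event_id}: unknown event type {self.event_type!r} "
                f"(expected one of {EVENT_TYPES})"
            )
        for name, v in (("psi_control", self.psi_control), ("psi_case", self.psi_case)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.event_id}: {name}={v} outside [0,1]")
        if self.bayes_factor < 0 and not math.isnan(self.bayes_factor):
            raise ValueError(f"{self.event_id}: negative Bayes factor")
        if self.informative_reads < 0:
            raise ValueError(f"{self.event_id}: negative read count")


@dataclass(frozen=True)
class SplicingSummary:
    n_events_significant: int
    n_genes: int
    counts: dict[str, int]
    proportions: dict[str, float]  # percentages over represented types


def delta_psi(e: SplicingEvent, signed: bool = False) -> float:
    """Between-condition inclusion change; absolute by default."""
    d = e.psi_case - e.psi_control
    return d if signed else abs(d)


def filter_events(
    events: Iterable[SplicingEvent],
    bf_min: float = DEFAULT_BF_MIN,
    dpsi_min: float = DEFAULT_DPSI_MIN,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[SplicingEvent]:
    """Keep events with BF > bf_min, |Δψ| > dpsi_min, reads >= min_reads."""
    if bf_min < 0 or dpsi_min < 0 or min_reads < 0:
        raise ConfigurationError(
            f"negative threshold (bf_min={bf_min}, dpsi_min={dpsi_min}, "
            f"min_reads={min_reads})"
        )
    return [
        e
        for e in events
        if e.bayes_factor > bf_min
        and delta_psi(e) > dpsi_min
        and e.informative_reads >= min_reads
    ]


def summarize_events(significant: Sequence[SplicingEvent]) -> SplicingSummary:
    """Event-type counts/percentages and distinct-gene count."""
    if not significant:
        raise ValueError("empty significant event set: nothing to summarize")
    counts = {t: 0 for t in EVENT_TYPES}
    genes = set()
    for e in significant:
        counts[e.event_type] += 1
        genes.add(e.gene_id)
    counts = {t: c for t, c in counts.items() if c > 0}
    total = sum(counts.values())
    proportions = {t: 100.0 * c / total for t, c in counts.items()}
    return SplicingSummary(
        n_events_significant=total,
        n_genes=len(genes),
        counts=counts,
        proportions=proportions,
    )


_COLUMN_ALIASES = {
    "event_id": ("event_id", "event_name", "event"),
    "gene_id": ("gene_id", "gene", "gene_symbol"),
    "event_type": ("event_type", "type"),
    "psi_control": ("psi_control", "psi_1", "sample1_posterior_mean"),
    "psi_case": ("psi_case", "psi_2", "sample2_posterior_mean"),
    "bayes_factor": ("bayes_factor", "bf"),
    "informative_reads": ("informative_reads", "reads", "counts"),
}


def read_events_table(path: str | Path) -> list[SplicingEvent]:
    """Read a MISO-summary-compatible TSV of splicing events."""
    df = pd.read_csv(path, sep="\t")
    cols = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in df.columns:
                cols[canonical] = a
                break
        else:
            raise ValueError(
                f"{path}: no column for {canonical!r} (accepted: {aliases})"
            )
    return [
        SplicingEvent(
            event_id=str(row[cols["event_id"]]),
            gene_id=str(row[cols["gene_id"]]),
            event_type=str(row[cols["event_type"]]),
            psi_control=float(row[cols["psi_control"]]),
            psi_case=float(row[cols["psi_case"]]),
            bayes_factor=float(row[cols["bayes_factor"]]),
            informative_reads=int(row[cols["informative_reads"]]),
        )
        for row in df.to_dict("records")
    ]
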