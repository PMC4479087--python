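"""Differential-expression filtering and biotype breakdown.

The filter keeps a gene when its FDR-adjusted q-value is at most 0.05 and
its case/control FPKM fold change is either above 1.5 (up) or below 0.67
(down). The q boundary is inclusive; the fold-change boundaries are strict.
Fold change is the plain ratio case/control, optionally stabilized with a
pseudocount; with pseudocount 0 a gene expressed only in the case condition
has fold change +inf (counted as up) and a 0/0 gene is undefined and
excluded from the DE set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotation import TranscriptModel
from .nmd import ConfigurationError

__all__ = [
    "ExpressionRecord",
    "DEResult",
    "fold_change",
    "filter_de",
    "bh_fdr",
    "biotype_breakdown",
    "read_expression_table",
    "DEFAULT_BIOTYPE_COLLAPSE",
]

DEFAULT_Q_MAX = 0.05
DEFAULT_UP_MIN = 1.5
DEFAULT_DOWN_MAX = 0.67


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fpkm_control: float
    fpkm_case: float
    q_value: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.fpkm_control < 0 or self.fpkm_case < 0:
            raise ValueError(f"{self.gene_id}: negative FPKM")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"{self.gene_id}: q-value {self.q_value} outside [0,1]")


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    fold_change: float
    direction: str  # "up" | "down"
    q_value: float


def fold_change(r: ExpressionRecord, pseudocount: float = 0.0) -> float:
    """Case/control FPKM ratio; nan for 0/0, +inf for x/0 with x > 0."""
    if pseudocount < 0:
        raise ConfigurationError(f"negative pseudocount {pseudocount}")
    num = r.fpkm_case + pseudocount
    den = r.fpkm_control + pseudocount
    if den == 0.0:
        return math.inf if num > 0.0 else math.nan
    return num / den


def filter_de(
    records: Iterable[ExpressionRecord],
    q_max: float = DEFAULT_Q_MAX,
    up_min: float = DEFAULT_UP_MIN,
    down_max: float = DEFAULT_DOWN_MAX,
    pseudocount: float = 0.0,
) -> list[DEResult]:
    """Keep genes with q <= q_max and fold change > up_min or < down_max."""
    if up_min <= down_max:
        raise ConfigurationError(
            f"up_min ({up_min}) must exceed down_max ({down_max})"
        )
    out: list[DEResult] = []
    for r in records:
        fc = fold_change(r, pseudocount=pseudocount)
        if math.isnan(fc) or r.q_value > q_max:
            continue
        if fc > up_min:
            out.append(DEResult(r.gene_id, fc, "up", r.q_value))
        elif fc < down_max:
            out.append(DEResult(r.gene_id, fc, "down", r.q_value))
    return out


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# Fig-7a-style coarse categories: pseudogene sub-biotypes collapse together.
DEFAULT_BIOTYPE_COLLAPSE: dict[str, str] = {
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "transcribed_processed_pseudogene": "pseudogene",
    "transcribed_unprocessed_pseudogene": "pseudogene",
    "unitary_pseudogene": "pseudogene",
    "polymorphic_pseudogene": "pseudogene",
    "IG_pseudogene": "pseudogene",
    "TR_pseudogene": "pseudogene",
    "lincRNA": "lincRNA",
    "antisense": "antisense",
    "protein_coding": "protein_coding",
}


def biotype_breakdown(
    de: Sequence[DEResult],
    annotation: Iterable[TranscriptModel] | Mapping[str, str],
    collapse: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-biotype counts and percentages over the DE gene set.

    ``annotation`` is either parsed transcript models or a direct
    gene_id -> biotype mapping. DE genes absent from the annotation fall in
    an ``unknown`` bucket (with a warning). Percentages sum to 100.
    """
    if not de:
        raise ValueError("empty DE set: no biotype breakdown to compute")
    if collapse is None:
        collapse = DEFAULT_BIOTYPE_COLLAPSE
    if isinstance(annotation, Mapping):
        gene_biotype = dict(annotation)
    else:
        gene_biotype = {t.gene_id: t.gene_biotype for t in annotation}

    counts: dict[str, int] = {}
    missing = []
    for r in de:
        bt = gene_biotype.get(r.gene_id)
        if bt is None:
            missing.append(r.gene_id)
            bt = "unknown"
        bt = collapse.get(bt, bt)
        counts[bt] = counts.get(bt, 0) + 1
    if missing:
        warnings.warn(
            f"{len(missing)} DE gene(s) absent from annotation, counted as "
            f"'unknown' (e.g. {missing[:5]})"
        )
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "biotype": list(counts),
            "count": list(counts.values()),
        }
    ).sort_values(["count", "biotype"], ascending=[False, True], ignore_index=True)
    df["percent"] = 100.0 * df["count"] / total
    return df


_CUFFDIFF_COLS = {"value_1", "value_2", "q_value"}
_MINIMAL_COLS = {"gene_id", "fpkm_control", "fpkm_case", "q_value"}


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a two-condition expression TSV.

    Two schemas are auto-detected from the header: Cuffdiff ``gene_exp.diff``
    (``gene``/``gene_id``, ``value_1`` control FPKM, ``value_2`` case FPKM,
    optional ``p_value``, ``q_value``) and the minimal 4-column schema
    (``gene_id``, ``fpkm_control``, ``fpkm_case``, ``q_value``).
    """
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if _CUFFDIFF_COLS <= cols:
        gene_col = "gene_id" if "gene_id" in cols else "gene"
        if gene_col not in cols:
            raise ValueError(f"{path}: Cuffdiff-style table lacks a gene column")
        ctrl, case = "value_1", "value_2"
    elif _MINIMAL_COLS <= cols:
        gene_col, ctrl, case = "gene_id", "fpkm_control", "fpkm_case"
    else:
        raise ValueError(
            f"{path}: unrecognized expression schema (columns: {sorted(cols)})"
        )
    has_p = "p_value" in cols
    return [
        ExpressionRecord(
            gene_id=str(row[gene_col]),
            fpkm_control=float(row[ctrl]),
            fpkm_case=float(row[case]),
            q_value=float(row["q_value"]),
            p_value=float(row["p_value"]) if has_p else None,
        )
        for row in df.to_dict("records")
    ]
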