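"""Gene-set over-representation via the hypergeometric upper tail.

For a query list of n genes drawn from a universe of N genes, a set with K
members in the universe, and an observed overlap of k genes, the
over-representation p-value is P(X >= k) for X ~ Hypergeometric(N, K, n) —
the chance of seeing at least k shared genes if the query were a uniform
random draw. Sets and queries are intersected with the universe before
counting, so genes outside the background never inflate the overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from scipy.stats import hypergeom

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeom_overrep",
    "cross_reference",
    "harmonize",
    "read_gmt",
    "write_gmt",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    universe_size: int  # N
    set_size_in_universe: int  # K
    query_size_in_universe: int  # n
    overlap: int  # k
    p_value: float
    overlapping_genes: frozenset[str]
    significant: bool
    degenerate: bool = False  # set had no members in the universe


def hypergeom_overrep(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    Delegates to scipy's survival function, which evaluates the tail in
    log space rather than via naive factorials. ``k = 0`` returns exactly 1.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int,)) or isinstance(v, bool):
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if N < 1 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"invalid population: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(p, 1.0)


def harmonize(
    ids: Iterable[str],
    synonym_map: Mapping[str, str] | None = None,
    case_insensitive: bool = True,
) -> list[str]:
    """Normalize gene identifiers: optional synonym replacement, then
    case-folding. Order-preserving, duplicates retained."""
    out = []
    for g in ids:
        g = str(g).strip()
        if synonym_map:
            g = synonym_map.get(g, g)
        if case_insensitive:
            g = g.casefold()
        out.append(g)
    return out


def cross_reference(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    synonym_map: Mapping[str, str] | None = None,
    case_insensitive: bool = True,
    unmapped_warn_fraction: float = 0.05,
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation in the query list.

    All identifier collections are harmonized, then intersected with the
    universe: K = |set ∩ universe|, n = |query ∩ universe|,
    k = |set ∩ query ∩ universe|. A loud warning is raised when more than
    ``unmapped_warn_fraction`` of the query is absent from the universe.
    """
    uni = set(harmonize(universe, synonym_map, case_insensitive))
    if not uni:
        raise ValueError("empty universe")
    q_raw = harmonize(query, synonym_map, case_insensitive)
    q_all = set(q_raw)
    q = q_all & uni
    unmapped = q_all - uni
    if q_all and len(unmapped) / len(q_all) > unmapped_warn_fraction:
        warnings.warn(
            f"{len(unmapped)}/{len(q_all)} query genes absent from the "
            f"universe (e.g. {sorted(unmapped)[:5]})"
        )
    N, n = len(uni), len(q)
    results = []
    for gs in sets:
        members = set(harmonize(gs.members, synonym_map, case_insensitive)) & uni
        K = len(members)
        hits = members & q
        k = len(hits)
        p = hypergeom_overrep(k, K, n, N)
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                universe_size=N,
                set_size_in_universe=K,
                query_size_in_universe=n,
                overlap=k,
                p_value=p,
                overlapping_genes=frozenset(hits),
                significant=p < alpha,
                degenerate=(K == 0),
            )
        )
    return results


def read_gmt(source: str | Path | TextIO) -> list[GeneSet]:
    """Read GMT: one set per line — name, description, then members (tabs)."""
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        # GMT content always contains tabs; a bare string without them is a path
        text = source if ("\t" in source or "\n" in source) else Path(source).read_text()
    else:
        text = source.read()
    sets = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: need name, description, >=1 member")
        name, desc, members = fields[0], fields[1], fields[2:]
        sets.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    return sets


def write_gmt(sets: Sequence[GeneSet], stream: TextIO | None = None) -> str:
    lines = [
        "\t".join([gs.name, gs.description, *sorted(gs.members)]) for gs in sets
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if stream is not None:
        stream.write(text)
    return text
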