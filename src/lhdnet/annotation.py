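"""Functional-term catalogs (GO / KEGG in GMT format) and enrichment scores.

The function test compares genes through their enrichment-score profiles:
for gene ``g`` with network neighborhood ``G`` (``g`` plus its interactors at
medium-or-better confidence) and a term with member set ``F``, the score is
the -log10 upper-tail hypergeometric probability of observing at least
``|G & F|`` members of ``F`` in a draw of ``|G|`` genes from a universe of
``N`` genes.  One score per term, concatenated over all catalogs, gives the
profile vector ``ES(g)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .network import PPINetwork

__all__ = [
    "AnnotationCatalog",
    "EnrichmentContext",
    "GmtParseError",
    "read_gmt",
    "neighbor_set",
    "enrichment_score",
    "enrichment_profile",
]


class GmtParseError(ValueError):
    """Raised when a GMT line cannot be interpreted."""


@dataclass(frozen=True)
class AnnotationCatalog:
    """Ordered functional terms with their (deduplicated) member gene sets."""

    source: str
    terms: tuple[str, ...]
    members: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.members):
            raise ValueError("terms and members length mismatch")
        for term, genes in zip(self.terms, self.members):
            if len(genes) < 2:
                raise ValueError(f"term {term!r} has fewer than 2 members")

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentContext:
    """Parameters shared by all enrichment computations.

    ``universe_size`` is the hypergeometric ``N`` ("total number of genes");
    when ``None`` it defaults to the network's node count at call time.
    ``neighbor_confidence_cutoff`` restricts the neighborhood ``G`` to
    medium-or-better interactions (STRING convention: >= 400).  Scores are
    capped at ``score_cap`` to keep cosine similarities finite under
    floating-point underflow of the tail probability.
    """

    universe_size: int | None = None
    neighbor_confidence_cutoff: int = 400
    score_cap: float = 300.0

    def __post_init__(self) -> None:
        if not (1 <= self.neighbor_confidence_cutoff <= 999):
            raise ValueError("neighbor_confidence_cutoff must be in [1, 999]")
        if self.score_cap <= 0:
            raise ValueError("score_cap must be positive")

    def resolve_universe(self, net: PPINetwork) -> int:
        return self.universe_size if self.universe_size is not None else net.n_nodes


def read_gmt(path: str | Path, source: str | None = None) -> AnnotationCatalog:
    """Load a Broad-dialect GMT file: ``term<TAB>description<TAB>gene...``.

    Member lists are deduplicated preserving no particular order (sets);
    terms with fewer than two distinct members are dropped with a warning.
    """
    path = Path(path)
    terms: list[str] = []
    members: list[frozenset[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if len(genes) < 2:
                warnings.warn(
                    f"{path.name}:{lineno}: term {term!r} has {len(genes)} "
                    "member(s) (< 2), dropped",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            terms.append(term)
            members.append(genes)
    return AnnotationCatalog(
        source=source or path.stem, terms=tuple(terms), members=tuple(members)
    )


def neighbor_set(
    net: PPINetwork, gene: str, ctx: EnrichmentContext
) -> frozenset[str]:
    """``{g} | {neighbors of g at confidence >= cutoff}`` — the set ``G``."""
    if not net.has_node(gene):
        raise KeyError(f"gene {gene!r} not in network")
    cut = ctx.neighbor_confidence_cutoff
    out = {gene}
    for nb, conf in net.neighbors(gene).items():
        if conf >= cut:
            out.add(nb)
    return frozenset(out)


def enrichment_score(
    G: Iterable[str],
    F: Iterable[str],
    ctx: EnrichmentContext,
    universe_size: int | None = None,
) -> float:
    """-log10 upper-tail hypergeometric probability of the overlap of G and F.

    With ``N = universe_size`` (falling back to ``ctx.universe_size``),
    ``M = |F|``, ``n = |G|``, ``m = |G & F|``, the tail is ``P(X >= m)`` for
    ``X ~ Hypergeom(N, M, n)``, computed in log space and capped at
    ``ctx.score_cap``.  ``m = 0`` gives score 0 (the tail is the whole
    support).
    """
    G = frozenset(G)
    F = frozenset(F)
    if universe_size is None:
        universe_size = ctx.universe_size
    if universe_size is None:
        raise ValueError("universe size unset: pass universe_size or set it on ctx")
    N = int(universe_size)
    M, n = len(F), len(G)
    if M > N or n > N:
        raise ValueError(f"term size M={M} or draw size n={n} exceeds universe N={N}")
    m = len(G & F)
    if m == 0:
        return 0.0
    log_p = hypergeom.logsf(m - 1, N, M, n)
    score = -log_p / math.log(10.0)
    if not np.isfinite(score):
        return float(ctx.score_cap)
    return float(min(max(score, 0.0), ctx.score_cap))


def enrichment_profile(
    net: PPINetwork,
    gene: str,
    catalogs: Sequence[AnnotationCatalog],
    ctx: EnrichmentContext,
) -> np.ndarray:
    """Enrichment-score vector ``ES(g)`` over the concatenated term list.

    Term order follows the catalogs in the order given, each catalog's own
    deterministic term order inside, so profiles from the same catalogs are
    always comparable component-wise.
    """
    if not catalogs:
        raise ValueError("at least one annotation catalog is required")
    G = neighbor_set(net, gene, ctx)
    N = ctx.resolve_universe(net)
    scores = [
        enrichment_score(G, F, ctx, N)
        for catalog in catalogs
        for F in catalog.members
    ]
    return np.asarray(scores, dtype=float)
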