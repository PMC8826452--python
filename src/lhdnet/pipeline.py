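"""Per-level runs, pairwise intersections, and interaction-confidence summaries.

A *level* is one omics layer (epigenomics, genomics, transcriptomics,
post-transcriptomics) with its own validated driver-gene seed list.  Each
level is processed identically — diffusion from its seeds, heat-threshold
candidate selection, three-stage screen — under one shared configuration,
and the surviving "latent" driver genes of every unordered level pair are
intersected to nominate genes involved at two omics levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotation import AnnotationCatalog, EnrichmentContext
from .diffusion import (
    DiffusionConfig,
    SeedSet,
    initial_heat,
    propagate_until_stable,
    select_candidates,
)
from .network import LaplacianOperator, PPINetwork, build_laplacian
from .screening import ScreenConfig, ScreenTable, run_screen

__all__ = [
    "LevelResult",
    "IntersectionResult",
    "run_level",
    "run_all",
    "intersect_levels",
    "interaction_confidence_summary",
    "CONFIDENCE_BINS",
]

#: STRING convention: medium (>=400), high (>=700), highest (>=900) confidence.
CONFIDENCE_BINS = (400, 700, 900)


@dataclass(frozen=True)
class LevelResult:
    """Outcome of one omics level: latent genes plus full provenance."""

    level: str
    latent_genes: tuple[str, ...]
    screen: ScreenTable
    chosen_t: float
    converged: bool
    n_seeds_used: int
    diffusion_config: DiffusionConfig
    screen_config: ScreenConfig

    def stage_counts(self) -> dict[str, int]:
        return dict(self.screen.stage_counts)


@dataclass(frozen=True)
class IntersectionResult:
    """Shared latent genes for every unordered pair of levels."""

    pairs: Mapping[tuple[str, str], tuple[str, ...]]

    def counts(self) -> dict[tuple[str, str], int]:
        return {pair: len(genes) for pair, genes in self.pairs.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level_a": a, "level_b": b, "gene": g}
            for (a, b) in sorted(self.pairs)
            for g in self.pairs[(a, b)]
        ]
        return pd.DataFrame(rows, columns=["level_a", "level_b", "gene"])


def run_level(
    net: PPINetwork,
    seeds: SeedSet,
    catalogs: Sequence[AnnotationCatalog],
    ctx: EnrichmentContext,
    dcfg: DiffusionConfig,
    scfg: ScreenConfig,
    lap: LaplacianOperator | None = None,
) -> LevelResult:
    """Diffuse, select candidates, screen; return the level's latent genes.

    ``lap`` may be passed to reuse one Laplacian (and its spectral cache)
    across levels; it must match ``net`` and the default weight mode is used
    otherwise.
    """
    if lap is None:
        lap = build_laplacian(net)
    present = seeds.restrict_to(net)
    h0 = initial_heat(net, present)
    heat, chosen_t, converged = propagate_until_stable(lap, h0, dcfg, net=net)
    candidates = select_candidates(net, heat, present, dcfg)
    screen = run_screen(
        candidates, lap, net, present, catalogs, ctx, scfg, t=chosen_t
    )
    return LevelResult(
        level=seeds.level,
        latent_genes=tuple(screen.survivors()),
        screen=screen,
        chosen_t=chosen_t,
        converged=converged,
        n_seeds_used=len(present.genes),
        diffusion_config=dcfg,
        screen_config=scfg,
    )


def run_all(
    net: PPINetwork,
    level_seeds: Sequence[SeedSet],
    catalogs: Sequence[AnnotationCatalog],
    ctx: EnrichmentContext,
    dcfg: DiffusionConfig,
    scfg: ScreenConfig,
) -> list[LevelResult]:
    """Run every level under the shared configuration, reusing one Laplacian."""
    lap = build_laplacian(net)
    return [
        run_level(net, seeds, catalogs, ctx, dcfg, scfg, lap=lap)
        for seeds in level_seeds
    ]


def intersect_levels(results: Sequence[LevelResult]) -> IntersectionResult:
    """Shared latent genes for every unordered pair of levels (C(k, 2) pairs)."""
    if len(results) < 2:
        raise ValueError("need at least two levels to intersect")
    labels = [r.level for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate level labels: {labels}")
    latent = {r.level: frozenset(r.latent_genes) for r in results}
    pairs: dict[tuple[str, str], tuple[str, ...]] = {}
    for a, b in itertools.combinations(sorted(labels), 2):
        pairs[(a, b)] = tuple(sorted(latent[a] & latent[b]))
    return IntersectionResult(pairs=pairs)


def interaction_confidence_summary(
    net: PPINetwork,
    latent: Sequence[str],
    seeds: SeedSet,
    bins: Sequence[int] = CONFIDENCE_BINS,
) -> pd.DataFrame:
    """Per latent gene: number of seed genes adjacent at each confidence bin.

    Mirrors the medium/high/highest-confidence summary used to check that
    nominated genes interact with validated drivers.  Counts are
    non-increasing as bins get stricter.
    """
    rows = []
    for gene in latent:
        confs = [
            conf
            for nb, conf in net.neighbors(gene).items()
            if nb in seeds.genes and nb != gene
        ]
        row: dict[str, object] = {"gene": gene}
        for b in bins:
            row[f"ge_{b}"] = sum(1 for c in confs if c >= b)
        rows.append(row)
    columns = ["gene"] + [f"ge_{b}" for b in bins]
    return pd.DataFrame(rows, columns=columns)
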