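"""Three-stage statistical screen for raw diffusion candidates.

Candidates that cleared the heat threshold are filtered in order by

1. a **permutation test** — 500 random seed sets of the same size are
   diffused at the same time ``t``; the empirical p-value of a candidate is
   the fraction of replicates on which its heat strictly exceeds its actual
   heat (hub nodes collect heat from any seed set and are discarded here);
2. an **association test** — the maximum association score MAS(g) is the
   highest edge confidence between ``g`` and any validated driver gene;
3. a **function test** — the maximum function score MFS(g) is the highest
   cosine similarity between the enrichment profile of ``g`` and that of any
   validated driver gene.

Later stages are only evaluated on survivors of earlier ones, mirroring how
the staged survivor counts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationCatalog, EnrichmentContext, enrichment_profile
from .diffusion import SeedSet
from .network import LaplacianOperator, PPINetwork

__all__ = [
    "ScreenConfig",
    "ScreenTable",
    "permutation_pvalues",
    "max_association_score",
    "linkage",
    "max_function_score",
    "run_screen",
]

STAGES = ("candidate", "permutation", "association", "function")


@dataclass(frozen=True)
class ScreenConfig:
    """Cutoffs and permutation settings for one screen run.

    The permutation cutoff is strict (``p < p_cutoff``); the association and
    function cutoffs are inclusive (``MAS >= mas_cutoff``,
    ``MFS >= mfs_cutoff``).  ``plus_one_pvalues`` switches the estimator to
    ``(Heat_> + 1)/(n + 1)``, which avoids exact zeros; it is off by default
    so that p-values are exact multiples of ``1/n_permutations``.
    """

    n_permutations: int = 500
    p_cutoff: float = 0.05
    mas_cutoff: int = 400
    mfs_cutoff: float = 0.3
    rng_seed: int = 0
    plus_one_pvalues: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 <= self.p_cutoff <= 1.1):
            raise ValueError("p_cutoff outside [0, 1.1]")
        if not (0 <= self.mas_cutoff <= 999):
            raise ValueError("mas_cutoff outside [0, 999]")
        if not (0 <= self.mfs_cutoff <= 1):
            raise ValueError("mfs_cutoff outside [0, 1]")


@dataclass(frozen=True)
class ScreenTable:
    """Per-candidate screen measurements and staged survivor counts.

    ``table`` has one row per candidate with columns ``gene``, ``heat``,
    ``p_value``, ``mas``, ``mfs`` and ``stage_reached`` (the last stage the
    gene passed; ``function`` means it survived the whole screen).  MAS/MFS
    are NaN for genes eliminated before the corresponding stage was run.
    """

    table: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)

    def survivors(self) -> list[str]:
        """Genes that passed all three tests, in table (heat-ranked) order."""
        mask = self.table["stage_reached"] == "function"
        return list(self.table.loc[mask, "gene"])

    def __post_init__(self) -> None:
        counts = [self.stage_counts.get(s, 0) for s in STAGES]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"survivor counts increase across stages: {counts}")


def permutation_pvalues(
    lap: LaplacianOperator,
    net: PPINetwork,
    candidates: Sequence[tuple[str, float]],
    seed_size: int,
    t: float,
    cfg: ScreenConfig,
) -> dict[str, float]:
    """Empirical p-value per candidate against random same-size seed sets.

    Each replicate draws ``seed_size`` nodes uniformly without replacement
    from all network nodes, initializes heat 1/seed_size on them, and
    diffuses for the same time ``t`` as the actual run.  ``p(g)`` is the
    fraction of replicates whose heat at ``g`` strictly exceeds the actual
    heat (ties do not count).  Fully determined by ``cfg.rng_seed``.
    """
    n = net.n_nodes
    if seed_size > n:
        raise ValueError(f"seed_size {seed_size} exceeds node count {n}")
    names = [g for g, _ in candidates]
    actual = np.array([h for _, h in candidates], dtype=float)
    idx = np.array([net.index[g] for g in names], dtype=int)
    exceed = np.zeros(len(names), dtype=int)
    rng = np.random.default_rng(cfg.rng_seed)
    share = 1.0 / seed_size
    for _ in range(cfg.n_permutations):
        picked = rng.choice(n, size=seed_size, replace=False)
        h0 = np.zeros(n)
        h0[picked] = share
        h_t = lap.apply_exp_neg(h0, t)
        exceed += h_t[idx] > actual
    if cfg.plus_one_pvalues:
        pvals = (exceed + 1) / (cfg.n_permutations + 1)
    else:
        pvals = exceed / cfg.n_permutations
    return dict(zip(names, pvals.astype(float)))


def max_association_score(net: PPINetwork, gene: str, reference: SeedSet) -> int:
    """MAS(g): max edge confidence between ``g`` and any reference gene.

    ``g`` itself is excluded from the reference; 0 when no reference edge
    exists.
    """
    if not net.has_node(gene):
        raise KeyError(f"gene {gene!r} not in network")
    best = 0
    for nb, conf in net.neighbors(gene).items():
        if nb != gene and nb in reference.genes and conf > best:
            best = conf
    return best


def linkage(es1: np.ndarray, es2: np.ndarray) -> float:
    """Cosine similarity of two enrichment profiles; 0 if either is all-zero."""
    es1 = np.asarray(es1, dtype=float)
    es2 = np.asarray(es2, dtype=float)
    if es1.shape != es2.shape:
        raise ValueError(f"profile length mismatch: {es1.shape} vs {es2.shape}")
    n1 = float(np.linalg.norm(es1))
    n2 = float(np.linalg.norm(es2))
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return float(np.dot(es1, es2) / (n1 * n2))


def max_function_score(
    gene: str,
    reference: SeedSet,
    profiles: Mapping[str, np.ndarray],
) -> float:
    """MFS(g): max cosine similarity to any reference gene's profile."""
    usable = [g for g in reference.genes if g != gene and g in profiles]
    if not usable:
        raise ValueError(f"no usable reference profile for gene {gene!r}")
    own = profiles[gene]
    return max(linkage(own, profiles[g]) for g in sorted(usable))


def run_screen(
    candidates: Sequence[tuple[str, float]],
    lap: LaplacianOperator,
    net: PPINetwork,
    seeds: SeedSet,
    catalogs: Sequence[AnnotationCatalog],
    ctx: EnrichmentContext,
    cfg: ScreenConfig,
    t: float,
) -> ScreenTable:
    """Apply the three tests in order and assemble the :class:`ScreenTable`.

    ``t`` must be the diffusion time of the actual run so that permuted and
    actual heat values are comparable.  MAS is computed only for permutation
    survivors and MFS only for association survivors; reference profiles are
    computed once per call.
    """
    present = seeds.restrict_to(net, warn=False)
    names = [g for g, _ in candidates]
    heat = {g: h for g, h in candidates}

    pvals = permutation_pvalues(
        lap, net, candidates, seed_size=len(present.genes), t=t, cfg=cfg
    )
    s1 = [g for g in names if pvals[g] < cfg.p_cutoff]

    mas = {g: max_association_score(net, g, present) for g in s1}
    s2 = [g for g in s1 if mas[g] >= cfg.mas_cutoff]

    mfs: dict[str, float] = {}
    if s2:
        needed = sorted(set(s2) | present.genes)
        profiles = {
            g: enrichment_profile(net, g, catalogs, ctx)
            for g in needed
            if net.has_node(g)
        }
        mfs = {g: max_function_score(g, present, profiles) for g in s2}
    s3 = [g for g in s2 if mfs[g] >= cfg.mfs_cutoff]

    s1_set, s2_set, s3_set = set(s1), set(s2), set(s3)
    rows = []
    for g in names:
        if g in s3_set:
            stage = "function"
        elif g in s2_set:
            stage = "association"
        elif g in s1_set:
            stage = "permutation"
        else:
            stage = "candidate"
        rows.append(
            {
                "gene": g,
                "heat": heat[g],
                "p_value": pvals[g],
                "mas": mas.get(g, np.nan),
                "mfs": mfs.get(g, np.nan),
                "stage_reached": stage,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "heat", "p_value", "mas", "mfs", "stage_reached"]
    )
    counts = {
        "candidate": len(names),
        "permutation": len(s1),
        "association": len(s2),
        "function": len(s3),
    }
    return ScreenTable(table=table, stage_counts=counts)
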