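"""Plain-text writers and readers for pipeline artifacts.

Every writer is deterministic: identical inputs produce byte-identical
files, which is what makes whole runs reproducible and diffable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

from .diffusion import HeatVector, SeedSet
from .network import PPINetwork
from .pipeline import IntersectionResult, LevelResult

__all__ = [
    "read_seed_list",
    "write_heat_tsv",
    "write_screen_tsv",
    "write_counts_tsv",
    "write_intersection_tsv",
    "write_manifest",
]


def read_seed_list(path: str | Path, level: str | None = None) -> SeedSet:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    path = Path(path)
    genes = []
    for line in path.read_text(encoding="utf-8").splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            genes.append(s)
    return SeedSet(level=level or path.stem, genes=genes)


def _seed_hash(seeds: SeedSet) -> str:
    payload = "\n".join(sorted(seeds.genes)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_heat_tsv(
    path: str | Path,
    net: PPINetwork,
    heat: HeatVector,
    seeds: SeedSet,
    weight_mode: str = "scaled",
) -> None:
    """Two-column TSV (identifier, heat) with a provenance header comment."""
    lines = [
        f"# t={heat.t!r}\tweight_mode={weight_mode}\tseed_hash={_seed_hash(seeds)}",
        "gene\theat",
    ]
    for i, name in enumerate(net.nodes):
        lines.append(f"{name}\t{heat.values[i]:.12e}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_screen_tsv(path: str | Path, result: LevelResult) -> None:
    """Per-candidate screen table: gene, heat, p_value, mas, mfs, stage."""
    df = result.screen.table
    lines = ["gene\theat\tp_value\tmas\tmfs\tstage_reached"]
    for row in df.itertuples(index=False):
        mas = "" if row.mas != row.mas else f"{int(row.mas)}"
        mfs = "" if row.mfs != row.mfs else f"{row.mfs:.6f}"
        lines.append(
            f"{row.gene}\t{row.heat:.12e}\t{row.p_value:.6f}\t{mas}\t{mfs}\t"
            f"{row.stage_reached}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_counts_tsv(path: str | Path, results: Sequence[LevelResult]) -> None:
    """Staged survivor counts per level (candidates -> p -> MAS -> MFS)."""
    lines = ["level\tcandidates\tafter_permutation\tafter_association\tafter_function"]
    for r in results:
        c = r.stage_counts()
        lines.append(
            f"{r.level}\t{c['candidate']}\t{c['permutation']}\t"
            f"{c['association']}\t{c['function']}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_intersection_tsv(path: str | Path, inter: IntersectionResult) -> None:
    """One row per shared gene: level_a, level_b, gene."""
    lines = ["level_a\tlevel_b\tgene"]
    for (a, b) in sorted(inter.pairs):
        for g in inter.pairs[(a, b)]:
            lines.append(f"{a}\t{b}\t{g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_manifest(
    path: str | Path,
    results: Sequence[LevelResult],
    input_hashes: dict[str, str] | None = None,
) -> None:
    """JSON run manifest: all cutoffs, seeds, chosen t, and input hashes."""
    payload = {
        "levels": [
            {
                "level": r.level,
                "chosen_t": r.chosen_t,
                "converged": r.converged,
                "n_seeds_used": r.n_seeds_used,
                "stage_counts": r.stage_counts(),
                "diffusion_config": asdict(r.diffusion_config),
                "screen_config": asdict(r.screen_config),
            }
            for r in results
        ],
        "input_hashes": input_hashes or {},
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
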