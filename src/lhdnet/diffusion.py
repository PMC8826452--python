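"""Heat diffusion on the PPI network and raw-candidate selection.

Heat starts uniformly distributed over the seed nodes (validated driver
genes at one omics level) and evolves as ``H(t) = H(0) exp(-L t)``.  Total
heat is conserved and never crosses connected components; as ``t`` grows the
distribution within each component approaches uniform, at which point seed
information is washed out — the stopping rule walks a geometric time
schedule and stops as soon as two consecutive snapshots agree in L1 norm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import LaplacianOperator, PPINetwork, component_labels

__all__ = [
    "SeedSet",
    "HeatVector",
    "DiffusionConfig",
    "NearUniformWarning",
    "MissingSeedWarning",
    "initial_heat",
    "propagate",
    "propagate_until_stable",
    "select_candidates",
]


class NearUniformWarning(UserWarning):
    """Diffusion has (nearly) reached the per-component uniform limit."""


class MissingSeedWarning(UserWarning):
    """Some seed identifiers were not found among network nodes."""


@dataclass(frozen=True)
class SeedSet:
    """A named set of seed genes for one omics level."""

    level: str
    genes: frozenset[str]

    def __init__(self, level: str, genes) -> None:
        object.__setattr__(self, "level", level)
        object.__setattr__(self, "genes", frozenset(genes))
        if not self.genes:
            raise ValueError(f"seed set for level {level!r} is empty")

    def restrict_to(self, net: PPINetwork, warn: bool = True) -> "SeedSet":
        """Drop seeds absent from the network, warning about each dropout."""
        present = frozenset(g for g in self.genes if net.has_node(g))
        missing = sorted(self.genes - present)
        if not present:
            raise ValueError(
                f"no seed of level {self.level!r} is present in the network; "
                f"missing: {missing}"
            )
        if missing and warn:
            warnings.warn(
                f"level {self.level!r}: {len(missing)} seed(s) not in network, "
                f"renormalizing over the {len(present)} present: {missing}",
                MissingSeedWarning,
                stacklevel=2,
            )
        return SeedSet(self.level, present)


@dataclass(frozen=True)
class HeatVector:
    """Node-aligned heat distribution at diffusion time ``t``."""

    values: np.ndarray
    t: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("heat vector must be one-dimensional")
        total = v.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"heat not conserved: sum={total!r}")
        if v.min(initial=0.0) < -1e-12:
            raise ValueError(f"negative heat entry: min={v.min()!r}")


@dataclass(frozen=True)
class DiffusionConfig:
    """Schedule and thresholds controlling one diffusion run.

    ``t_schedule`` defaults to the geometric grid ``0.1 * 2**k`` for
    ``k = 0..29``; diffusion time is dimensionless (weights under the default
    ``scaled`` mode are O(1), so O(1)-to-O(10) times already mix local
    neighborhoods).

    ``washout_floor`` guards against diffusing all the way to the uniform
    limit, where heat carries no seed information and the downstream
    permutation test degenerates (only the slowest eigenmode survives, so
    all nodes' p-values become perfectly correlated).  The walk stops at the
    last snapshot whose L1 distance to the per-component uniform
    distribution is still at least this floor.  Set it to 0 to disable the
    guard and study the pure stability rule / the uniform limit.
    """

    t_schedule: tuple[float, ...] = tuple(0.1 * 2.0**k for k in range(30))
    stability_tol: float = 1e-6
    heat_threshold: float = 1e-5
    exclude_seeds: bool = True
    washout_floor: float = 0.25

    def __post_init__(self) -> None:
        sched = tuple(float(t) for t in self.t_schedule)
        object.__setattr__(self, "t_schedule", sched)
        if not sched:
            raise ValueError("t_schedule must be non-empty")
        if any(t <= 0 for t in sched) or any(
            b <= a for a, b in zip(sched, sched[1:])
        ):
            raise ValueError("t_schedule must be positive and strictly increasing")
        if self.stability_tol < 0 or self.heat_threshold < 0:
            raise ValueError("tolerances must be nonnegative")
        if self.washout_floor < 0:
            raise ValueError("washout_floor must be nonnegative")


def initial_heat(net: PPINetwork, seeds: SeedSet) -> HeatVector:
    """Heat 1/|S| on each seed present in the network, 0 elsewhere, at t=0."""
    present = seeds.restrict_to(net)
    v = np.zeros(net.n_nodes)
    share = 1.0 / len(present.genes)
    for g in present.genes:
        v[net.index[g]] = share
    return HeatVector(values=v, t=0.0)


def propagate(lap: LaplacianOperator, h0: HeatVector, t: float) -> HeatVector:
    """Evolve ``h0`` for an additional time ``t``: returns ``h0 exp(-L t)``."""
    if t < 0:
        raise ValueError(f"diffusion time must be nonnegative, got {t}")
    out = lap.apply_exp_neg(h0.values, t)
    # exp(-Lt) is a stochastic semigroup; clip round-off noise only.
    np.clip(out, 0.0, None, out=out)
    out /= out.sum()
    return HeatVector(values=out, t=h0.t + t)


def _component_uniform(labels: np.ndarray, h: np.ndarray) -> np.ndarray:
    """The t -> infinity limit: per-component mass spread uniformly."""
    limit = np.empty_like(h)
    for c in np.unique(labels):
        mask = labels == c
        limit[mask] = h[mask].sum() / mask.sum()
    return limit


def propagate_until_stable(
    lap: LaplacianOperator,
    h0: HeatVector,
    cfg: DiffusionConfig,
    net: PPINetwork | None = None,
) -> tuple[HeatVector, float, bool]:
    """Walk ``cfg.t_schedule`` until two consecutive snapshots agree.

    Returns ``(heat, chosen_t, converged)``.  The first schedule point is
    compared against ``h0`` itself.  Two stopping conditions compete:

    * stability — the L1 difference between consecutive snapshots drops
      below ``cfg.stability_tol``;
    * washout guard — the next snapshot would be closer than
      ``cfg.washout_floor`` (L1) to the per-component uniform limit, in
      which case the previous, still-informative snapshot is returned.

    If the schedule is exhausted without either condition firing, the last
    snapshot is returned with ``converged = False``.  A
    :class:`NearUniformWarning` is emitted whenever the returned vector is
    within ``stability_tol`` (L1) of the per-component uniform distribution:
    that limit carries no seed information, so candidate ranking then rests
    on residual structure only.
    """
    if net is not None:
        labels = component_labels(net)
    else:
        labels = np.zeros(lap.dimension, dtype=int)
    prev = h0
    chosen_t = h0.t
    converged = False
    for t_k in cfg.t_schedule:
        cur = propagate(lap, h0, t_k)
        dist_uniform = float(
            np.abs(cur.values - _component_uniform(labels, cur.values)).sum()
        )
        if dist_uniform < cfg.washout_floor:
            if prev is not h0:
                warnings.warn(
                    f"stopping at t={chosen_t:g}: continuing to t={t_k:g} would "
                    f"bring heat within {cfg.washout_floor:g} (L1) of the "
                    "per-component uniform limit, washing out seed information",
                    NearUniformWarning,
                    stacklevel=2,
                )
                converged = True
                break
            # even the first snapshot is past the floor (tiny or dense graph):
            # keep it and let the near-uniform warning below fire
            prev = cur
            chosen_t = t_k
            converged = True
            break
        diff = float(np.abs(cur.values - prev.values).sum())
        prev = cur
        chosen_t = t_k
        if diff < cfg.stability_tol:
            converged = True
            break
    limit = _component_uniform(labels, prev.values)
    if float(np.abs(prev.values - limit).sum()) < cfg.stability_tol:
        warnings.warn(
            f"heat at t={chosen_t:g} is within {cfg.stability_tol:g} (L1) of the "
            "per-component uniform limit; seed information is washed out",
            NearUniformWarning,
            stacklevel=2,
        )
    return prev, chosen_t, converged


def select_candidates(
    net: PPINetwork,
    heat: HeatVector,
    seeds: SeedSet | None,
    cfg: DiffusionConfig,
) -> list[tuple[str, float]]:
    """Nodes with heat >= ``cfg.heat_threshold`` as (gene, heat) pairs.

    Sorted by heat descending, then identifier ascending for determinism.
    Seeds are removed when ``cfg.exclude_seeds`` is set.
    """
    exclude: frozenset[str] = frozenset()
    if cfg.exclude_seeds and seeds is not None:
        exclude = seeds.genes
    picked = [
        (name, float(heat.values[i]))
        for i, name in enumerate(net.nodes)
        if heat.values[i] >= cfg.heat_threshold and name not in exclude
    ]
    picked.sort(key=lambda pair: (-pair[1], pair[0]))
    if not picked:
        warnings.warn(
            f"no candidate reaches heat threshold {cfg.heat_threshold:g}",
            UserWarning,
            stacklevel=2,
        )
    return picked
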