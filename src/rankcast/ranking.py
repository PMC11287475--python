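"""Rule engine turning monoculture growth + supernatant edges into a rank order.

Three tentative rules predict the competitive rank order of a community from
culture-free assays:

* Rule 1 — rank species (weakest to strongest) by a monoculture growth
  parameter (1/T_mid, AUC or mu_max); values within a relative tie tolerance
  share a group.
* Rule 2 — species whose supernatant strongly inhibits others (growth reduced
  by >= 20%) are moved further up the ranking: each such producer is
  re-inserted immediately above the highest-ranked species it strongly
  inhibits.  Producers whose insertion points collide are ordered by how many
  species they inhibit; equal counts tie.
* Rule 3 — strong-inhibition edges exerted by slow-growing species (the
  weakest monoculture group; for larger communities the bottom quartile of
  groups) are ignored, since slow growth limits the build-up of inhibitory
  compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RankOrder",
    "RankingError",
    "rank_from_monoculture",
    "slow_growers",
    "predict_rank",
]


class RankingError(ValueError):
    pass


@dataclass(frozen=True)
class RankOrder:
    """Ordered groups of species labels, weakest first; within-group = tied."""

    groups: tuple[tuple[str, ...], ...]

    @staticmethod
    def of(groups) -> "RankOrder":
        return RankOrder(tuple(tuple(g) for g in groups))

    @property
    def species(self) -> list[str]:
        return [s for g in self.groups for s in g]

    def position(self, species: str) -> int:
        """Index of the group holding ``species`` (0 = weakest)."""
        for i, g in enumerate(self.groups):
            if species in g:
                return i
        raise RankingError(f"species {species!r} not in rank order")

    def validate(self) -> None:
        seen = self.species
        if len(seen) != len(set(seen)):
            raise RankingError("species appear more than once in rank order")
        if any(len(g) == 0 for g in self.groups):
            raise RankingError("empty group in rank order")

    def __str__(self) -> str:
        return " < ".join(
            " ≈ ".join(sorted(g)) for g in self.groups
        )


def rank_from_monoculture(
    values: dict[str, float], metric: str = "inv_tmid", tie_tol: float = 0.05
) -> RankOrder:
    """Rule 1: ascending rank order from per-species growth-parameter values.

    Adjacent species whose values differ by less than ``tie_tol`` relative to
    the larger value are merged into one tied group (transitively along the
    sorted chain).
    """
    if not values:
        raise RankingError("no species values given")
    for s, v in values.items():
        if not np.isfinite(v):
            raise RankingError(f"non-finite {metric} value for species {s!r}")
    ordered = sorted(values, key=lambda s: (values[s], s))
    groups: list[list[str]] = [[ordered[0]]]
    for s in ordered[1:]:
        prev = groups[-1][-1]
        a, b = values[prev], values[s]
        scale = max(abs(a), abs(b))
        if scale == 0 or abs(b - a) / scale < tie_tol:
            groups[-1].append(s)
        else:
            groups.append([s])
    return RankOrder.of(groups)


def slow_growers(rank: RankOrder, bottom_fraction: float = 0.25) -> set[str]:
    """Rule 3 targets: the weakest monoculture group.

    For communities whose rank has more than four groups, the bottom
    ``bottom_fraction`` of groups (at least one) is used instead, so the rule
    generalizes beyond four species.
    """
    rank.validate()
    if len(rank.species) <= 1:
        return set()
    n_groups = len(rank.groups)
    k = 1 if n_groups <= 4 else max(1, int(np.floor(n_groups * bottom_fraction)))
    return {s for g in rank.groups[:k] for s in g}


def predict_rank(
    mono_rank: RankOrder,
    edges: list[tuple[str, str]],
    slow: set[str] | None = None,
) -> RankOrder:
    """Rules 2+3: adjust the monoculture order with strong-inhibition edges.

    Edges produced by ``slow`` species are discarded (Rule 3).  Every
    remaining producer is removed from the base order and re-inserted
    immediately above the highest-ranked species it strongly inhibits, never
    below its Rule-1 position.  Producers that land at the same insertion
    point are stacked by the number of species they inhibit (more inhibited =
    higher); equal counts merge into a tied group.  Cyclic promotion
    constraints among producers collapse the cycle into one tied group, with
    a warning.
    """
    mono_rank.validate()
    community = set(mono_rank.species)
    for p, r in edges:
        if p not in community or r not in community:
            raise RankingError(f"edge {p}->{r} references species outside the community")
    if slow is None:
        slow = slow_growers(mono_rank)

    retained = [(p, r) for p, r in edges if p not in slow and p != r]
    producers = sorted({p for p, _ in retained})
    if not producers:
        return mono_rank

    targets: dict[str, set[str]] = {p: set() for p in producers}
    for p, r in retained:
        targets[p].add(r)

    # base order: mono groups with producers taken out
    base_groups = [
        [s for s in g if s not in producers] for g in mono_rank.groups
    ]
    # base level of each remaining species; producers get a Rule-1 floor on
    # the half-integer slot just below the base level their mono group holds
    # (a promoted producer is never re-inserted below that slot)
    levels: dict[str, int] = {}
    floor: dict[str, float] = {}
    lvl = 0
    for g_base, g_full in zip(base_groups, mono_rank.groups):
        for s in g_full:
            if s in producers:
                floor[s] = lvl - 0.5
        if g_base:
            for s in g_base:
                levels[s] = lvl
            lvl += 1

    # insertion slot per producer: the half-integer slot immediately above its
    # highest-ranked non-producer target; targets that are themselves promoted
    # producers anchor into the *same* slot as that producer (collisions are
    # then resolved by inhibited-species counts).  Cycles collapse into one
    # tied group, with a warning.
    insert: dict[str, float] = {}

    def resolve(p: str, stack: tuple[str, ...]) -> float:
        if p in insert:
            return insert[p]
        if p in stack:
            cycle = stack[stack.index(p):]
            warnings.warn(
                f"cyclic promotion constraints among {sorted(set(cycle))}; "
                "returning a tied group",
                stacklevel=2,
            )
            slot = max(
                [floor[q] for q in cycle]
                + [levels[t] + 0.5 for q in cycle for t in targets[q] if t not in producers]
            )
            for q in cycle:
                insert[q] = slot
            return slot
        slot = floor[p]
        for t in sorted(targets[p]):
            if t in producers:
                slot = max(slot, resolve(t, stack + (p,)))
            else:
                slot = max(slot, levels[t] + 0.5)
        return insert.setdefault(p, slot)

    for p in producers:
        resolve(p, ())

    # assemble: before each base level, emit the producers whose slot sits
    # there, stacked by inhibited-species count (more targets = higher);
    # equal counts within a slot merge into one tied group
    def producer_groups_at(slot: float) -> list[list[str]]:
        here = sorted(
            (p for p in producers if insert[p] == slot),
            key=lambda q: (len(targets[q]), q),
        )
        out: list[list[str]] = []
        for p in here:
            if out and len(targets[out[-1][0]]) == len(targets[p]):
                out[-1].append(p)
            else:
                out.append([p])
        return out

    result: list[list[str]] = []
    base_nonempty = [g for g in base_groups if g]
    for i, g in enumerate(base_nonempty):
        result.extend(producer_groups_at(i - 0.5))
        result.append(list(g))
    result.extend(producer_groups_at(len(base_nonempty) - 0.5))

    out = RankOrder.of(result)
    out.validate()
    return out
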