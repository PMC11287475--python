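"""Co-culture competition analysis: Wrightian relative fitness and scores.

Pairwise competitions are scored with Wrightian relative fitness

    w(1 vs 2) = (end CFU_1 * start CFU_2) / (end CFU_2 * start CFU_1)

log10-transformed so that positive values mean the focal species wins.  An
integrative per-species competitiveness score is built stepwise from the
weakest species upward: each unordered pair's mean log10 fitness is estimated
once and reused with opposite sign for the partner species, avoiding double
counting of the reciprocal value.  Scores therefore sum to zero whenever the
two perspectives of every pair are exact reciprocals.

For three- and four-species communities the pairwise formula does not apply;
end-point CFUs are compared directly across species (median log10 CFU, rank
order, and Wilcoxon signed-rank groupings with FDR correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoCultureError",
    "CompetitivenessScore",
    "relative_fitness",
    "fitness_table",
    "stepwise_competitiveness",
    "community_counts_summary",
]

PAIRWISE_COLUMNS = [
    "species1",
    "species2",
    "start_cfu1",
    "start_cfu2",
    "end_cfu1",
    "end_cfu2",
    "replicate",
    "medium",
]


class CoCultureError(ValueError):
    pass


@dataclass
class CompetitivenessScore:
    species: str
    score: float  # summed log10 relative fitness contributions


def relative_fitness(
    start1: float, start2: float, end1: float, end2: float
) -> tuple[float, float]:
    """Wrightian relative fitness of species 1 vs species 2 and its log10.

    All counts must be positive; detection-limit replicates must be imputed
    (at the plating detection limit) before calling.
    """
    for name, v in (("start1", start1), ("start2", start2), ("end1", end1), ("end2", end2)):
        if not (np.isfinite(v) and v > 0):
            raise CoCultureError(f"CFU count {name}={v} must be positive and finite")
    w = (end1 * start2) / (end2 * start1)
    return w, math.log10(w)


def fitness_table(records: pd.DataFrame, detection_limit: float | None = None) -> pd.DataFrame:
    """Derive relative fitness per pairwise record.

    ``records`` needs the columns species1, species2, start_cfu1, start_cfu2,
    end_cfu1, end_cfu2, replicate, medium.  End counts of zero are imputed at
    ``detection_limit`` when given, otherwise they raise.
    """
    missing = [c for c in PAIRWISE_COLUMNS if c not in records.columns]
    if missing:
        raise CoCultureError(f"pairwise CFU table missing columns {missing}")
    out = records.copy()
    for col in ("end_cfu1", "end_cfu2"):
        if detection_limit is not None:
            below = out[col] < detection_limit
            out.loc[below, col] = detection_limit
            out[f"{col}_censored"] = below
    rel, logrel = [], []
    for idx, row in out.iterrows():
        try:
            w, lw = relative_fitness(
                row["start_cfu1"], row["start_cfu2"], row["end_cfu1"], row["end_cfu2"]
            )
        except CoCultureError as exc:
            raise CoCultureError(f"record {idx} ({row['species1']} vs {row['species2']}, "
                                 f"replicate {row['replicate']}): {exc}") from exc
        rel.append(w)
        logrel.append(lw)
    out["rel_fitness"] = rel
    out["log10_rel_fitness"] = logrel
    return out


def _pair_means(fitness: pd.DataFrame) -> tuple[list[str], dict[tuple[str, str], float]]:
    """Mean log10 relative fitness per unordered pair, from species1's view."""
    species = sorted(set(fitness["species1"]) | set(fitness["species2"]))
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    for (s1, s2), grp in fitness.groupby(["species1", "species2"]):
        key = (s1, s2) if s1 < s2 else (s2, s1)
        vals = grp["log10_rel_fitness"].to_numpy()
        if s1 > s2:
            vals = -vals  # normalize to the alphabetically-first perspective
        pooled.setdefault(key, []).append(vals)
    means = {k: float(np.mean(np.concatenate(v))) for k, v in pooled.items()}
    for a in species:
        for b in species:
            if a < b and (a, b) not in means:
                raise CoCultureError(f"missing pairwise fitness for ({a}, {b})")
    return species, means


def stepwise_competitiveness(fitness: pd.DataFrame) -> list[CompetitivenessScore]:
    """Integrative competitiveness score per species, weakest first.

    Species are ordered weakest to strongest by the mean of their pairwise
    log10 relative fitness values (ties broken lexicographically).  Walking up
    that order, each species sums its log10 fitness against all partners; for
    pairs already visited the previously estimated value is reused with
    opposite sign rather than re-estimated, so every unordered pair enters the
    bookkeeping exactly once.
    """
    species, means = _pair_means(fitness)

    def signed(a: str, b: str) -> float:
        return means[(a, b)] if a < b else -means[(b, a)]

    provisional = {
        s: np.mean([signed(s, o) for o in species if o != s]) for s in species
    }
    order = sorted(species, key=lambda s: (provisional[s], s))

    scores: dict[str, float] = {s: 0.0 for s in species}
    accounted: set[tuple[str, str]] = set()
    for s in order:
        total = 0.0
        for o in species:
            if o == s:
                continue
            key = (s, o) if s < o else (o, s)
            total += signed(s, o)
            accounted.add(key)
        scores[s] = total
    return [CompetitivenessScore(s, scores[s]) for s in order]


# ---------------------------------------------------------------------------
# 3-/4-species community summaries


def _compact_letters(species: list[str], differs: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: species sharing a letter are not significantly
    different.  Insert-and-absorb construction over greedily grown cliques of
    the 'not different' relation."""
    groups: list[set[str]] = []
    for s in species:
        placed = False
        for g in groups:
            if all((min(s, o), max(s, o)) not in differs for o in g):
                g.add(s)
                placed = True
        if not placed:
            groups.append({s})
    # absorb subsets
    groups = [g for g in groups if not any(g < h for h in groups if h is not g)]
    letters = {s: "" for s in species}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for s in sorted(g):
            letters[s] += letter
    return letters


def community_counts_summary(
    counts: pd.DataFrame, alpha: float = 0.05, min_replicates: int = 5
) -> pd.DataFrame:
    """Rank species in a 3-/4-species community by end-point CFU.

    ``counts`` needs columns species, end_cfu, replicate (and optionally
    ``censored``).  Returns per-species median log10 CFU, rank (1 = weakest),
    and significance letters from replicate-paired Wilcoxon signed-rank tests
    with FDR (Benjamini-Hochberg) correction.
    """
    for col in ("species", "end_cfu", "replicate"):
        if col not in counts.columns:
            raise CoCultureError(f"community counts table missing column {col!r}")
    species = sorted(counts["species"].unique())
    wide = counts.pivot_table(index="replicate", columns="species", values="end_cfu")
    if wide.isna().any().any():
        raise CoCultureError(
            "unequal replicate pairing: every species needs a count in every replicate"
        )
    n = len(wide)
    if n < min_replicates:
        raise CoCultureError(f"need >= {min_replicates} replicates, got {n}")
    log_wide = np.log10(wide)

    pairs = [(a, b) for i, a in enumerate(species) for b in species[i + 1 :]]
    pvals = []
    for a, b in pairs:
        diff = log_wide[a] - log_wide[b]
        if np.allclose(diff, 0):
            pvals.append(1.0)
        else:
            pvals.append(float(wilcoxon(log_wide[a], log_wide[b]).pvalue))
    if pairs:
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    else:
        reject = []
    differs = {
        (min(a, b), max(a, b)) for (a, b), r in zip(pairs, reject) if r
    }
    letters = _compact_letters(species, differs)

    medians = log_wide.median()
    order = medians.sort_values().index.tolist()
    flagged = {}
    if "censored" in counts.columns:
        flagged = counts.groupby("species")["censored"].any().to_dict()
    return pd.DataFrame(
        {
            "species": order,
            "median_log10_cfu": [float(medians[s]) for s in order],
            "rank": np.arange(1, len(order) + 1),
            "group": [letters[s] for s in order],
            "censored": [bool(flagged.get(s, False)) for s in order],
        }
    )
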