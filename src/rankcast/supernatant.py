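"""Supernatant-assay analysis: relative growth, integrative score, edges.

Each receiver species is grown in conditioned medium (30% producer
supernatant + 70% fresh medium) and in a salt control (30% NaCl + 70% fresh
medium).  Growth in supernatant relative to control, (a)/(b), is computed on
one of the three growth parameters (mu_max, 1/T_mid or AUC); ratios below 1
mean inhibition, above 1 stimulation.

The integrative supernatant score sums, per producer, the relative-growth
ratios its supernatant imposes on the other community members.  Sums are
centered around 0 and scaled to [-1, +1] (positive residuals by the largest
positive residual, negative by the largest negative one, so both endpoints
are attained), then negated so that positive scores mark inhibitory
producers.

Strong-inhibition edges (growth reduced by at least 20% by default) feed the
rank-prediction rules and parameterize the agent-based simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import GrowthParams

__all__ = [
    "InteractionMatrix",
    "SupernatantScore",
    "SupernatantError",
    "relative_growth",
    "matrix_from_params",
    "integrative_supernatant_score",
    "strong_inhibition_edges",
]

SUPERNATANT_PREFIX = "supernatant:"


class SupernatantError(ValueError):
    pass


@dataclass
class InteractionMatrix:
    """Producer x receiver table of relative-growth ratios.

    ``values`` is a DataFrame indexed by producer with receiver columns; the
    diagonal is undefined and kept as NaN.
    """

    species: list[str]
    values: pd.DataFrame
    parameter: str = "inv_tmid"
    medium: str = "GIM"

    def validate(self) -> None:
        missing = []
        for p in self.species:
            for r in self.species:
                if p == r:
                    continue
                v = self.values.at[p, r]
                if not np.isfinite(v):
                    missing.append((p, r))
                elif v <= 0:
                    raise SupernatantError(f"non-positive ratio for {p}->{r}: {v}")
        if missing:
            raise SupernatantError(f"missing interaction cells: {missing}")

    def ratio(self, producer: str, receiver: str) -> float:
        return float(self.values.at[producer, receiver])


@dataclass
class SupernatantScore:
    species: str
    score: float


def relative_growth(treated: GrowthParams, control: GrowthParams, parameter: str) -> float:
    """Supernatant-relative growth (a)/(b) on the chosen growth parameter."""
    if parameter not in ("mu_max", "inv_tmid", "auc"):
        raise SupernatantError(f"unknown growth parameter {parameter!r}")
    a = getattr(treated, parameter)
    b = getattr(control, parameter)
    if not np.isfinite(b) or b <= 0:
        raise SupernatantError(f"control {parameter} must be positive, got {b}")
    return float(a) / float(b)


def classify(ratio: float) -> str:
    if ratio < 1.0:
        return "inhibition"
    if ratio > 1.0:
        return "stimulation"
    return "neutral"


def matrix_from_params(
    params: pd.DataFrame, parameter: str = "inv_tmid", medium: str | None = None
) -> InteractionMatrix:
    """Build the producer x receiver ratio matrix from a fitted-plate table.

    Per-replicate supernatant values are divided by the receiver's mean
    control value, then averaged per producer->receiver cell.
    """
    if parameter not in ("mu_max", "inv_tmid", "auc"):
        raise SupernatantError(f"unknown growth parameter {parameter!r}")
    df = params[params["converged"]].copy()
    if medium is not None:
        df = df[df["medium"] == medium]
    else:
        media = sorted(df["medium"].unique())
        if len(media) != 1:
            raise SupernatantError(f"multiple media present {media}; pass medium=")
        medium = media[0]

    controls = df[df["treatment"] == "control"]
    if controls.empty:
        raise SupernatantError("no control-treatment wells in params table")
    control_mean = controls.groupby("species")[parameter].mean()

    sup = df[df["treatment"].str.startswith(SUPERNATANT_PREFIX)].copy()
    if sup.empty:
        raise SupernatantError("no supernatant-treatment wells in params table")
    sup["producer"] = sup["treatment"].str.removeprefix(SUPERNATANT_PREFIX)
    species = sorted(set(sup["species"]) | set(sup["producer"]))
    values = pd.DataFrame(np.nan, index=species, columns=species, dtype=float)
    for (producer, receiver), grp in sup.groupby(["producer", "species"]):
        if receiver not in control_mean.index:
            raise SupernatantError(f"no control wells for receiver {receiver}")
        ratios = grp[parameter] / control_mean[receiver]
        values.at[producer, receiver] = float(ratios.mean())
    m = InteractionMatrix(species=species, values=values, parameter=parameter, medium=medium)
    m.validate()
    return m


def integrative_supernatant_score(m: InteractionMatrix) -> list[SupernatantScore]:
    """Per-producer integrative score in [-1, +1]; positive = inhibitory.

    The producer sums s_i = sum_j ratio(i->j) are centered; centered values
    are negated (a low sum means strong inhibition) and scaled two-sidedly so
    that the most inhibitory producer scores +1 and the most stimulatory -1.
    All-equal sums yield all-zero scores.
    """
    m.validate()
    sums = np.array(
        [sum(m.ratio(p, r) for r in m.species if r != p) for p in m.species]
    )
    centered = -(sums - sums.mean())
    pos_max = centered.max()
    neg_min = centered.min()
    scores = np.zeros_like(centered)
    if pos_max > 0:
        pos = centered > 0
        scores[pos] = centered[pos] / pos_max
    if neg_min < 0:
        neg = centered < 0
        scores[neg] = centered[neg] / (-neg_min)
    return [SupernatantScore(sp, float(s)) for sp, s in zip(m.species, scores)]


def strong_inhibition_edges(
    m: InteractionMatrix, threshold: float = 0.20
) -> list[tuple[str, str]]:
    """Producer->receiver pairs whose growth reduction is at least ``threshold``.

    The boundary is inclusive: ratio <= 1 - threshold qualifies.
    """
    if not 0.0 < threshold < 1.0:
        raise SupernatantError(f"threshold must be in (0, 1), got {threshold}")
    m.validate()
    cut = 1.0 - threshold
    return [
        (p, r)
        for p in m.species
        for r in m.species
        if p != r and m.ratio(p, r) <= cut
    ]


def scores_to_frame(scores: list[SupernatantScore]) -> pd.DataFrame:
    return pd.DataFrame({"species": [s.species for s in scores], "score": [s.score for s in scores]})
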