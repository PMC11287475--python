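"""Synthetic plate-reader and CFU data with known ground truth.

The generator emulates the data shapes of a four-species community study:

* monoculture / supernatant OD600 curves on a 15-min grid over 36 h, built
  from per-species Gompertz truths plus i.i.d. Gaussian measurement noise,
  with 3 experimental blocks x 3 replicates per condition;
* supernatant treatments that multiply the receiver's effective mu_max by a
  producer-specific factor (which propagates into 1/T_mid and AUC), the
  simplest mechanism consistent with suppressed growth curves — an
  alternative lag-extension mode is available behind a flag;
* pairwise and higher-order co-culture CFU outcomes drawn log-normally around
  expectations consistent with a ground-truth competitive rank order
  (adjacent ranks separated ~10-fold), with detection-limit censoring.

The default ("GIM-like") community has 1/T_mid order B < K < P < C, K
inhibiting everyone (factor 0.5 on mu_max), B inhibiting P (factor 0.6), and
true competitive order B < P < C < K — the configuration the rank-prediction
rules should recover end to end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import gompertz

__all__ = ["CommunitySpec", "gim_like_spec", "generate_plate", "generate_coculture_counts"]


@dataclass
class CommunitySpec:
    species: list[str]
    gompertz_truth: dict[str, tuple[float, float, float]]  # label -> (A, mu_max, lam)
    supernatant_factors: dict[tuple[str, str], float]  # (producer, receiver) -> factor
    true_rank: list[str]  # weakest -> strongest
    medium: str = "GIM"
    noise_sd: float = 0.01  # OD units
    blocks: int = 3
    replicates_per_block: int = 3
    start_cfu: float = 5e4  # per species per well
    end_log10_base: float = 7.0  # weakest species' expected end log10 CFU
    end_log10_step: float = 1.0  # ~10-fold separation per rank
    end_log10_sd: float = 0.15
    detection_limit: float = 1e3  # CFU
    coculture_replicates: int = 9
    blank_od: float = 0.05
    lag_mode: bool = False  # supernatant extends lag instead of scaling mu_max
    seed: int = 0

    def validate(self) -> None:
        if self.blocks * self.replicates_per_block < 3:
            raise ValueError("need at least 3 replicates overall")
        for key, f in self.supernatant_factors.items():
            if f <= 0:
                raise ValueError(f"supernatant factor {key} must be > 0")
        if sorted(self.true_rank) != sorted(self.species):
            raise ValueError("true_rank must be a permutation of species")


def gim_like_spec(seed: int = 0, **overrides) -> CommunitySpec:
    """Default four-species community emulating growth in insect-mimicking medium.

    Gompertz truths are chosen so the 1/T_mid order is B < K < P < C with
    T_mid ratios matching growth multipliers {C: 1, P: 0.84, K: 0.81,
    B: 0.68}; P has a high mu_max but long lag, B is slow throughout.
    """
    spec = CommunitySpec(
        species=["B", "C", "K", "P"],
        gompertz_truth={
            # (A, mu_max, lam): T_mid = A/(2 mu) + lam -> C 4.0, P 5.88, K 6.45, B 11.1 h
            "C": (1.4, 0.35, 2.0),
            "P": (1.3, 0.50, 4.58),
            "K": (1.1, 0.22, 3.95),
            "B": (0.9, 0.15, 8.10),
        },
        supernatant_factors={
            ("K", "B"): 0.5,
            ("K", "C"): 0.5,
            ("K", "P"): 0.5,
            ("B", "P"): 0.6,
        },
        true_rank=["B", "P", "C", "K"],
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(spec, k, v)
    spec.validate()
    return spec


def _curve_truth(spec: CommunitySpec, receiver: str, producer: str | None):
    A, mu, lam = spec.gompertz_truth[receiver]
    if producer is not None:
        f = spec.supernatant_factors.get((producer, receiver), 1.0)
        if spec.lag_mode:
            lam = lam / f
        else:
            mu = mu * f
    return A, mu, lam


def generate_plate(spec: CommunitySpec) -> pd.DataFrame:
    """Long-format plate table (time_h, od, species, replicate, medium,
    treatment, block) for monoculture, control and supernatant conditions."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, 36.0 + 1e-9, 0.25)  # 15-min grid over 36 h
    rows = []
    treatments: list[tuple[str, str | None]] = [("plain", None), ("control", None)]
    for receiver in spec.species:
        conds = treatments + [
            (f"supernatant:{p}", p) for p in spec.species if p != receiver
        ]
        for treatment, producer in conds:
            A, mu, lam = _curve_truth(spec, receiver, producer)
            clean = spec.blank_od + gompertz(times, A, mu, lam)
            for block in range(1, spec.blocks + 1):
                for rep in range(1, spec.replicates_per_block + 1):
                    od = clean + rng.normal(0.0, spec.noise_sd, size=times.size)
                    rows.append(
                        pd.DataFrame(
                            {
                                "time_h": times,
                                "od": np.maximum(od, 0.0),
                                "species": receiver,
                                "replicate": f"b{block}r{rep}",
                                "medium": spec.medium,
                                "treatment": treatment,
                                "block": str(block),
                            }
                        )
                    )
    return pd.concat(rows, ignore_index=True)


def _rank_index(spec: CommunitySpec) -> dict[str, int]:
    return {s: i for i, s in enumerate(spec.true_rank)}


def generate_coculture_counts(spec: CommunitySpec) -> pd.DataFrame:
    """Pairwise co-culture CFU table consistent with the ground-truth rank.

    Start counts are 5e4 CFU per species; end counts are log-normal around
    rank-dependent expectations (one rank step ~ 10-fold).  End counts below
    the detection limit are reported at the limit with ``censored`` flags.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    idx = _rank_index(spec)
    rows = []
    for s1, s2 in itertools.combinations(sorted(spec.species), 2):
        for rep in range(1, spec.coculture_replicates + 1):
            ends = {}
            for s in (s1, s2):
                mean = spec.end_log10_base + spec.end_log10_step * idx[s]
                ends[s] = 10 ** rng.normal(mean, spec.end_log10_sd)
            rows.append(
                {
                    "species1": s1,
                    "species2": s2,
                    "start_cfu1": spec.start_cfu,
                    "start_cfu2": spec.start_cfu,
                    "end_cfu1": max(ends[s1], spec.detection_limit),
                    "end_cfu2": max(ends[s2], spec.detection_limit),
                    "end_cfu1_censored": ends[s1] < spec.detection_limit,
                    "end_cfu2_censored": ends[s2] < spec.detection_limit,
                    "replicate": rep,
                    "medium": spec.medium,
                }
            )
    return pd.DataFrame(rows)


def generate_community_counts(
    spec: CommunitySpec, members: list[str] | None = None
) -> pd.DataFrame:
    """End-point CFU table for a 3-/4-species community co-culture."""
    spec.validate()
    members = sorted(members or spec.species)
    rng = np.random.default_rng(spec.seed + 2)
    idx = _rank_index(spec)
    rows = []
    for rep in range(1, spec.coculture_replicates + 1):
        for s in members:
            mean = spec.end_log10_base + spec.end_log10_step * idx[s]
            end = 10 ** rng.normal(mean, spec.end_log10_sd)
            rows.append(
                {
                    "community": "+".join(members),
                    "species": s,
                    "end_cfu": max(end, spec.detection_limit),
                    "censored": end < spec.detection_limit,
                    "replicate": rep,
                    "medium": spec.medium,
                }
            )
    return pd.DataFrame(rows)
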