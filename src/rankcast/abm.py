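"""Agent-based simulator of toxin-mediated competition on a 2D torus.

Bacteria are disc-shaped agents on a periodic square arena (default
100 x 100 um).  Each cell grows by increasing its radius

    G_t = g * (1 - (sum(T_i) / theta_T) ** kappa) * G_0

where ``g`` is the species-specific growth-rate multiplier, ``G_0`` the
default radius increment per time step (0.5/1200 um), ``sum(T_i)`` the cell's
accumulated toxin molecules of a given type, ``theta_T`` the potency
threshold (molecules needed to kill a cell) and ``kappa = 2`` the latency
exponent.  A cell targeted by several toxin types multiplies their inhibition
factors.  Cells divide at radius 1 um into two daughters of radius 0.5 um
that share the mother's toxin load equally; accumulating beyond ``theta_T``
kills a cell.  Resources are not limited and cells exert no mechanical forces
on each other (overlap is permitted).

Species growth multipliers come from scaled monoculture 1/T_mid values:
``g = 0.5 + 0.5 * Tmid_ref / Tmid_i`` with the fastest species as reference.

Each producer species secretes one kind of toxin molecule; susceptibility is
a property of the receiver, so several :class:`ToxinSpec` entries with the
same producer describe one molecule pool with different kill thresholds per
target (e.g. a K-toxin at theta 1750 against C but 2500 against B and P).
Free molecules are point particles produced at the centers of live producer
cells, moved by Brownian steps (per-axis sd ``sqrt(2 * diffusion)`` per
step, one step = 1 s), and absorbed by a uniformly random overlapping
*susceptible* cell — non-target species, including the producer itself, are
unaffected by and do not take up the molecule.  Absorbed molecules leave the
free pool; molecules inside dying or chemostat-removed cells leave the
system.  Because susceptible slow growers soak up molecules that would
otherwise reach faster-diluting targets, toxin burden is shared across all
susceptible species (the toxin-absorption effect).  A chemostat activates once the population first reaches the cap
(~500 cells) and thereafter removes uniformly random cells down to the cap at
the end of every step.  Integer toxin bookkeeping (produced = free + held by
living cells + removed) is verified at every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "SimConfig",
    "SpeciesSpec",
    "ToxinSpec",
    "SimResult",
    "SimState",
    "ABMError",
    "growth_increment",
    "species_growth_rate",
    "step",
    "run_simulation",
    "calibrate_toxin_potency",
    "HIGH_DIFFUSION",
    "LOW_DIFFUSION",
]

G0_DEFAULT = 0.5 / 1200.0  # um per step
#: molecules emitted per producer cell per step; a platform-specific free
#: parameter, fixed so that kill thresholds in the hundreds-to-thousands
#: range are dynamically meaningful at desk scale (see docs/methods.md)
DEFAULT_PRODUCTION_RATE = 0.75

HIGH_DIFFUSION = (5.0, 10.0)  # (cell D, toxin d) um^2/s, shaken liquid
LOW_DIFFUSION = (0.0, 0.1)  # surface-attached growth


class ABMError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesSpec:
    label: str
    g: float  # growth-rate multiplier in (0, 1]


@dataclass(frozen=True)
class ToxinSpec:
    producer: str
    targets: tuple[str, ...]
    theta: float  # molecules required to kill a target cell
    #: molecules emitted per producer cell per step; fractional parts are
    #: resolved by a Bernoulli draw per cell per step
    production_rate: float = DEFAULT_PRODUCTION_RATE


@dataclass(frozen=True)
class SimConfig:
    species: tuple[SpeciesSpec, ...]
    toxins: tuple[ToxinSpec, ...] = ()
    arena_side: float = 100.0
    g0: float = G0_DEFAULT
    kappa: float = 2.0
    r_init: float = 0.5
    r_div: float = 1.0
    founders_per_species: int = 32
    chemostat_cap: int = 500
    n_steps: int = 30000
    cell_diffusion: float = HIGH_DIFFUSION[0]
    toxin_diffusion: float = HIGH_DIFFUSION[1]
    seed: int = 0

    def validate(self) -> None:
        if not self.species:
            raise ABMError("at least one species required")
        labels = [s.label for s in self.species]
        if len(set(labels)) != len(labels):
            raise ABMError("duplicate species labels")
        for s in self.species:
            if not 0.0 < s.g <= 1.0:
                raise ABMError(f"species {s.label}: g={s.g} outside (0, 1]")
        for t in self.toxins:
            if t.theta <= 0:
                raise ABMError(f"toxin {t.producer}->{t.targets}: theta must be > 0")
            if t.producer not in labels:
                raise ABMError(f"toxin producer {t.producer!r} not a community species")
            for tgt in t.targets:
                if tgt not in labels:
                    raise ABMError(f"toxin target {tgt!r} not a community species")
        if self.cell_diffusion < 0 or self.toxin_diffusion < 0:
            raise ABMError("diffusion coefficients must be >= 0")
        if not 0 < self.r_init < self.r_div:
            raise ABMError("need 0 < r_init < r_div")


def growth_increment(
    g: float,
    toxin_load: float,
    theta_T: float,
    kappa: float = 2.0,
    g0: float = G0_DEFAULT,
) -> float:
    """Radius increment G_t = g * (1 - (load/theta)^kappa) * G_0, clamped at 0."""
    if theta_T <= 0:
        raise ABMError("theta_T must be positive")
    if toxin_load < 0 or g < 0:
        raise ABMError("toxin load and growth rate must be >= 0")
    return max(0.0, g * (1.0 - (toxin_load / theta_T) ** kappa) * g0)


def species_growth_rate(tmid_ref: float, tmid_i: float) -> float:
    """Growth multiplier g = 0.5 + 0.5 * Tmid_ref / Tmid_i (reference = fastest)."""
    if tmid_ref <= 0 or tmid_i <= 0:
        raise ABMError("T_mid values must be positive")
    if tmid_ref > tmid_i:
        raise ABMError("reference T_mid must be the smallest (fastest species)")
    return 0.5 + 0.5 * tmid_ref / tmid_i


# ---------------------------------------------------------------------------
# state


@dataclass
class SimState:
    """Mutable simulation state (positions in [0, side), integer toxin loads)."""

    pos: np.ndarray  # (n_cells, 2) float64
    radius: np.ndarray  # (n_cells,)
    species: np.ndarray  # (n_cells,) int64 index into config.species
    loads: np.ndarray  # (n_cells, n_types) int64
    tox_pos: np.ndarray  # (n_free, 2)
    tox_type: np.ndarray  # (n_free,) int64
    produced: np.ndarray  # (n_types,) int64 cumulative
    removed: np.ndarray  # (n_types,) int64 cumulative (dead + chemostat)
    absorbed_by_species: np.ndarray  # (n_species, n_types) int64 cumulative
    cells_ever: np.ndarray  # (n_species,) int64 founders + divisions
    chemostat_on: bool = False
    step_count: int = 0


def _init_state(config: SimConfig, rng: np.random.Generator) -> SimState:
    n_sp = len(config.species)
    n_types = len({t.producer for t in config.toxins})  # one pool per producer
    n0 = config.founders_per_species * n_sp
    pos = rng.uniform(0.0, config.arena_side, size=(n0, 2))
    species = np.repeat(np.arange(n_sp), config.founders_per_species)
    return SimState(
        pos=pos,
        radius=np.full(n0, config.r_init),
        species=species,
        loads=np.zeros((n0, n_types), dtype=np.int64),
        tox_pos=np.empty((0, 2)),
        tox_type=np.empty(0, dtype=np.int64),
        produced=np.zeros(n_types, dtype=np.int64),
        removed=np.zeros(n_types, dtype=np.int64),
        absorbed_by_species=np.zeros((n_sp, n_types), dtype=np.int64),
        cells_ever=np.full(n_sp, config.founders_per_species, dtype=np.int64),
    )


@njit(cache=True)
def _uptake_kernel(
    tox_pos, tox_type, tox_rand, cell_pos, cell_r, cell_sp, susceptible, side, nbins
):  # pragma: no cover - exercised through step()
    """For each free toxin, pick a uniformly random overlapping susceptible cell.

    ``susceptible`` is a (n_pools, n_species) bool matrix.  Cells are binned
    on a uniform grid (bin size >= max cell radius) so only the 3x3
    neighborhood needs scanning.  Returns the absorbing cell index per toxin,
    or -1.
    """
    n_cells = cell_pos.shape[0]
    n_tox = tox_pos.shape[0]
    chosen = np.full(n_tox, -1, dtype=np.int64)
    if n_cells == 0 or n_tox == 0:
        return chosen
    bs = side / nbins
    nb2 = nbins * nbins
    counts = np.zeros(nb2 + 1, dtype=np.int64)
    cbin = np.empty(n_cells, dtype=np.int64)
    for i in range(n_cells):
        bx = int(cell_pos[i, 0] / bs) % nbins
        by = int(cell_pos[i, 1] / bs) % nbins
        b = bx * nbins + by
        cbin[i] = b
        counts[b + 1] += 1
    for b in range(nb2):
        counts[b + 1] += counts[b]
    order = np.empty(n_cells, dtype=np.int64)
    fill = counts[:-1].copy()
    for i in range(n_cells):
        order[fill[cbin[i]]] = i
        fill[cbin[i]] += 1

    half = side / 2.0
    for m in range(n_tox):
        tx = tox_pos[m, 0]
        ty = tox_pos[m, 1]
        pool = tox_type[m]
        tbx = int(tx / bs) % nbins
        tby = int(ty / bs) % nbins
        # pass 1: count eligible overlapping cells
        n_elig = 0
        for ox in range(-1, 2):
            bx = (tbx + ox) % nbins
            for oy in range(-1, 2):
                by = (tby + oy) % nbins
                b = bx * nbins + by
                for k in range(counts[b], counts[b + 1]):
                    j = order[k]
                    if not susceptible[pool, cell_sp[j]]:
                        continue
                    dx = abs(cell_pos[j, 0] - tx)
                    if dx > half:
                        dx = side - dx
                    dy = abs(cell_pos[j, 1] - ty)
                    if dy > half:
                        dy = side - dy
                    if dx * dx + dy * dy <= cell_r[j] * cell_r[j]:
                        n_elig += 1
        if n_elig == 0:
            continue
        pick = int(tox_rand[m] * n_elig)
        if pick >= n_elig:
            pick = n_elig - 1
        # pass 2: select the pick-th eligible cell
        idx = 0
        done = False
        for ox in range(-1, 2):
            if done:
                break
            bx = (tbx + ox) % nbins
            for oy in range(-1, 2):
                if done:
                    break
                by = (tby + oy) % nbins
                b = bx * nbins + by
                for k in range(counts[b], counts[b + 1]):
                    j = order[k]
                    if not susceptible[pool, cell_sp[j]]:
                        continue
                    dx = abs(cell_pos[j, 0] - tx)
                    if dx > half:
                        dx = side - dx
                    dy = abs(cell_pos[j, 1] - ty)
                    if dy > half:
                        dy = side - dy
                    if dx * dx + dy * dy <= cell_r[j] * cell_r[j]:
                        if idx == pick:
                            chosen[m] = j
                            done = True
                            break
                        idx += 1
    return chosen


def _toxin_pools(config: SimConfig):
    """Collapse ToxinSpec entries into per-producer molecule pools.

    Returns (producer_idx, rate, susceptible, theta_mat) where pools are
    indexed in order of first appearance of their producer; ``theta_mat`` is
    (n_pools, n_species) with +inf for non-targets, and the minimum theta over
    entries when a receiver is named more than once.  A producer's emission
    rate is the maximum over its entries.
    """
    n_sp = len(config.species)
    labels = {s.label: i for i, s in enumerate(config.species)}
    pool_of: dict[str, int] = {}
    for t in config.toxins:
        pool_of.setdefault(t.producer, len(pool_of))
    n_pools = len(pool_of)
    producer = np.zeros(n_pools, dtype=np.int64)
    rate = np.zeros(n_pools)
    susceptible = np.zeros((n_pools, n_sp), dtype=bool)
    theta_mat = np.full((n_pools, n_sp), np.inf)
    for t in config.toxins:
        pi = pool_of[t.producer]
        producer[pi] = labels[t.producer]
        rate[pi] = max(rate[pi], float(t.production_rate))
        for tgt in t.targets:
            susceptible[pi, labels[tgt]] = True
            theta_mat[pi, labels[tgt]] = min(theta_mat[pi, labels[tgt]], float(t.theta))
    return producer, rate, susceptible, theta_mat


def step(state: SimState, config: SimConfig, rng: np.random.Generator) -> SimState:
    """Advance the state by one time step (mutates and returns ``state``).

    Fixed event order: toxin production, toxin diffusion, cell diffusion,
    toxin uptake, toxin-induced death, growth, division, chemostat removal.
    """
    producer, rate, susceptible, theta_mat = _toxin_pools(config)
    n_pools = producer.shape[0]
    side = config.arena_side

    # 1. production: each live producer cell emits `rate` molecules at its center
    if n_pools:
        new_pos = []
        new_pool = []
        for pi in range(n_pools):
            makers = state.pos[state.species == producer[pi]]
            if makers.shape[0] == 0 or rate[pi] == 0:
                continue
            base = int(rate[pi])
            frac = rate[pi] - base
            per_cell = np.full(makers.shape[0], base, dtype=np.int64)
            if frac > 0:
                per_cell += rng.random(makers.shape[0]) < frac
            if per_cell.sum() == 0:
                continue
            reps = np.repeat(makers, per_cell, axis=0)
            new_pos.append(reps)
            new_pool.append(np.full(reps.shape[0], pi, dtype=np.int64))
            state.produced[pi] += reps.shape[0]
        if new_pos:
            state.tox_pos = np.concatenate([state.tox_pos] + new_pos)
            state.tox_type = np.concatenate([state.tox_type] + new_pool)

    # 2. toxin Brownian motion
    if state.tox_pos.shape[0] and config.toxin_diffusion > 0:
        sd = math.sqrt(2.0 * config.toxin_diffusion)
        state.tox_pos = np.mod(
            state.tox_pos + rng.normal(0.0, sd, size=state.tox_pos.shape), side
        )

    # 3. cell Brownian motion
    if state.pos.shape[0] and config.cell_diffusion > 0:
        sd = math.sqrt(2.0 * config.cell_diffusion)
        state.pos = np.mod(state.pos + rng.normal(0.0, sd, size=state.pos.shape), side)

    # 4. uptake: each free molecule overlapping a susceptible cell is absorbed
    #    by one uniformly random overlapping susceptible cell
    if state.tox_pos.shape[0] and state.pos.shape[0]:
        nbins = max(1, int(side // max(config.r_div, 1e-9)))
        chosen = _uptake_kernel(
            state.tox_pos,
            state.tox_type,
            rng.random(state.tox_pos.shape[0]),
            state.pos,
            state.radius,
            state.species,
            susceptible,
            side,
            nbins,
        )
        taken = chosen >= 0
        if np.any(taken):
            np.add.at(state.loads, (chosen[taken], state.tox_type[taken]), 1)
            np.add.at(
                state.absorbed_by_species,
                (state.species[chosen[taken]], state.tox_type[taken]),
                1,
            )
            state.tox_pos = state.tox_pos[~taken]
            state.tox_type = state.tox_type[~taken]

    # 5. toxin-induced death: load beyond the receiver-specific threshold on
    #    any pool kills; the victim's entire load leaves the system
    if n_pools and state.pos.shape[0]:
        dead = np.zeros(state.pos.shape[0], dtype=bool)
        for pi in range(n_pools):
            dead |= state.loads[:, pi] > theta_mat[pi, state.species]
        if np.any(dead):
            state.removed += state.loads[dead].sum(axis=0)
            keep = ~dead
            state.pos = state.pos[keep]
            state.radius = state.radius[keep]
            state.species = state.species[keep]
            state.loads = state.loads[keep]

    n = state.pos.shape[0]
    if n:
        # 6. growth
        g = np.array([s.g for s in config.species])[state.species]
        factor = np.ones(n)
        for pi in range(n_pools):
            theta_i = theta_mat[pi, state.species]
            with np.errstate(invalid="ignore"):
                f = 1.0 - (state.loads[:, pi] / theta_i) ** config.kappa
            factor *= np.where(np.isfinite(theta_i), np.maximum(f, 0.0), 1.0)
        state.radius = state.radius + g * factor * config.g0

        # 7. division
        div = state.radius >= config.r_div - 1e-9
        if np.any(div):
            idx = np.nonzero(div)[0]
            ang = rng.uniform(0.0, 2.0 * math.pi, size=idx.size)
            u = np.column_stack([np.cos(ang), np.sin(ang)]) * config.r_init
            pos_a = np.mod(state.pos[idx] + u, side)
            pos_b = np.mod(state.pos[idx] - u, side)
            half_load = state.loads[idx] // 2
            rem = state.loads[idx] % 2
            coin = rng.integers(0, 2, size=rem.shape).astype(np.int64)
            state.pos[idx] = pos_a
            state.radius[idx] = config.r_init
            state.loads[idx] = half_load + rem * coin
            state.pos = np.concatenate([state.pos, pos_b])
            state.radius = np.concatenate([state.radius, np.full(idx.size, config.r_init)])
            state.species = np.concatenate([state.species, state.species[idx]])
            state.loads = np.concatenate([state.loads, half_load + rem * (1 - coin)])
            np.add.at(state.cells_ever, state.species[idx], 1)

        # 8. chemostat
        n = state.pos.shape[0]
        if not state.chemostat_on and n >= config.chemostat_cap:
            state.chemostat_on = True
        if state.chemostat_on and n > config.chemostat_cap:
            drop = rng.choice(n, size=n - config.chemostat_cap, replace=False)
            keep = np.ones(n, dtype=bool)
            keep[drop] = False
            state.removed += state.loads[~keep].sum(axis=0)
            state.pos = state.pos[keep]
            state.radius = state.radius[keep]
            state.species = state.species[keep]
            state.loads = state.loads[keep]

    state.step_count += 1
    return state


def check_conservation(state: SimState) -> None:
    """Exact integer toxin bookkeeping: produced = free + held + removed."""
    n_types = state.produced.shape[0]
    free = np.bincount(state.tox_type, minlength=n_types).astype(np.int64)
    held = state.loads.sum(axis=0) if state.loads.size else np.zeros(n_types, np.int64)
    if not np.array_equal(state.produced, free + held + state.removed):
        raise RuntimeError(
            f"toxin bookkeeping violated at step {state.step_count}: "
            f"produced={state.produced}, free={free}, held={held}, removed={state.removed}"
        )


@dataclass
class SimResult:
    config: SimConfig
    fractions_over_time: np.ndarray  # (n_recorded, n_species)
    total_counts: np.ndarray  # (n_recorded,)
    mean_fraction: np.ndarray  # (n_species,)
    #: time-average over the run of (molecules held by living cells of the
    #: species / number of living cells); fast dividers dilute their load and
    #: score low, slow growers that soak up toxin score high
    per_capita_toxin_uptake: np.ndarray  # (n_species,)
    #: cumulative molecules absorbed divided by cells that ever lived
    absorbed_per_cell_ever: np.ndarray  # (n_species,)
    absorbed_by_species: np.ndarray  # (n_species, n_types)
    cells_ever: np.ndarray  # (n_species,)
    produced: np.ndarray  # (n_types,)
    removed: np.ndarray  # (n_types,)
    free_at_end: np.ndarray  # (n_types,)
    held_at_end: np.ndarray  # (n_types,)
    extinct: bool = False

    @property
    def species_labels(self) -> list[str]:
        return [s.label for s in self.config.species]


def run_simulation(config: SimConfig, check_every: int = 1) -> SimResult:
    """Run one replicate; fully reproducible from ``config.seed``.

    Species fractions and total counts are recorded at step 0 and after every
    step; toxin bookkeeping is verified every ``check_every`` steps and at the
    end.  If every cell dies the run ends early with ``extinct=True``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = _init_state(config, rng)
    n_sp = len(config.species)

    fractions = np.zeros((config.n_steps + 1, n_sp))
    totals = np.zeros(config.n_steps + 1, dtype=np.int64)
    load_per_cell_sum = np.zeros(n_sp)
    load_steps = np.zeros(n_sp, dtype=np.int64)

    def record(i: int) -> None:
        counts = np.bincount(state.species, minlength=n_sp)
        totals[i] = counts.sum()
        if totals[i]:
            fractions[i] = counts / totals[i]
        if state.loads.size:
            held = np.bincount(
                state.species, weights=state.loads.sum(axis=1), minlength=n_sp
            )
            present = counts > 0
            load_per_cell_sum[present] += held[present] / counts[present]
            load_steps[present] += 1

    record(0)
    extinct = False
    last = config.n_steps
    for i in range(1, config.n_steps + 1):
        step(state, config, rng)
        record(i)
        if check_every and (i % check_every == 0):
            check_conservation(state)
        if totals[i] == 0:
            extinct = True
            last = i
            break
    check_conservation(state)

    fractions = fractions[: last + 1]
    totals = totals[: last + 1]
    n_types = state.produced.shape[0]
    free = np.bincount(state.tox_type, minlength=n_types).astype(np.int64)
    held = state.loads.sum(axis=0) if state.loads.size else np.zeros(n_types, np.int64)
    uptake = load_per_cell_sum / np.maximum(load_steps, 1)
    per_ever = state.absorbed_by_species.sum(axis=1) / np.maximum(state.cells_ever, 1)
    return SimResult(
        config=config,
        fractions_over_time=fractions,
        total_counts=totals,
        mean_fraction=fractions.mean(axis=0),
        per_capita_toxin_uptake=uptake,
        absorbed_per_cell_ever=per_ever,
        absorbed_by_species=state.absorbed_by_species.copy(),
        cells_ever=state.cells_ever.copy(),
        produced=state.produced.copy(),
        removed=state.removed.copy(),
        free_at_end=free,
        held_at_end=held,
        extinct=extinct,
    )


# ---------------------------------------------------------------------------
# potency calibration

NONE_NEEDED = "none-needed"
UNACHIEVABLE = "unachievable"


def calibrate_toxin_potency(
    producer: str,
    target: str,
    base_config: SimConfig,
    sweep=tuple(range(750, 4501, 250)),
    n_replicates: int = 5,
    seed: int = 0,
    production_rate: int = DEFAULT_PRODUCTION_RATE,
) -> float | str:
    """Minimal toxin potency recovering a pairwise competitive outcome.

    Simulates producer-vs-target competitions across the ``sweep`` of
    ``theta_T`` values (high diffusion is the intended regime of
    ``base_config``) and returns the largest theta (weakest toxin) at which
    the producer wins a majority of replicates — low theta means high potency,
    so this is the minimal potency needed.  Returns ``"none-needed"`` when the
    producer already wins without any toxin, ``"unachievable"`` when it loses
    even at the most potent setting.

    The winner of one replicate is the species with the larger mean fraction
    over time.
    """
    sweep = sorted(set(float(v) for v in sweep))
    if not sweep:
        raise ABMError("empty potency sweep")
    by_label = {s.label: s for s in base_config.species}
    if producer not in by_label or target not in by_label:
        raise ABMError(f"{producer!r}/{target!r} not in base config species")
    pair = (by_label[producer], by_label[target])
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates * (len(sweep) + 1))
    seeds = [int(s % (2**31)) for s in seeds]

    def producer_wins(toxins: tuple[ToxinSpec, ...], seed_block: int) -> bool:
        wins = 0
        for r in range(n_replicates):
            cfg = replace(
                base_config,
                species=pair,
                toxins=toxins,
                seed=seeds[seed_block * n_replicates + r],
            )
            res = run_simulation(cfg)
            if res.mean_fraction[0] > res.mean_fraction[1]:
                wins += 1
        return wins > n_replicates / 2

    if producer_wins((), 0):
        return NONE_NEEDED
    for block, theta in enumerate(sorted(sweep, reverse=True), start=1):
        toxins = (
            ToxinSpec(producer, (target,), theta, production_rate=production_rate),
        )
        if producer_wins(toxins, block):
            return theta
    return UNACHIEVABLE
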