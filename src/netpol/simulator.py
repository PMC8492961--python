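"""Stochastic discrete-time model of RNA polymerase II transcription over an
early gene body.

The model tracks a population of identical 1,000-nt synthetic genes. On each
gene, polymerases initiate at position 1, elongate in Poisson-distributed hops,
stall, backtrack, resume, terminate early at a pre-assigned Poisson-located
site, and are removed when they reach the end of the gene. Polymerases occlude
a fixed DNA footprint, so initiation is blocked while a polymerase sits over
position 1 and an elongation attempt is truncated when it would run into the
next polymerase downstream (a collision). Two positional windows allow
different stalling/backtracking/resumption kinetics early and late in the
gene, absorbing (for example) nucleosome effects into window-specific rates.

Collision resolution rules
--------------------------
A collision is always initiated by a MOVING polymerase running into the one
downstream of it:

* MOVING hits MOVING      -> upstream becomes STALLED, downstream unchanged
* MOVING hits STALLED     -> upstream becomes STALLED, downstream terminated
* MOVING hits BACKTRACKED -> upstream becomes STALLED, downstream unchanged

Two engines are provided: a fast numba kernel (default) used for population
sweeps, and a pure-Python reference engine (`initiate`,
`advance_and_transition`, `PolymeraseEnsemble`) that implements the identical
per-step semantics and is used as an independent cross-check in the test
suite.

The primary output is the occupancy profile: the sum over the population of
the active-site positions of engaged polymerases at the final time step, which
is the model's analogue of a NET-seq profile over the first 1,000 nt.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import ConfigError

__all__ = [
    "State",
    "Action",
    "ModelParameters",
    "SimulatedMetrics",
    "OccupancyProfile",
    "PolymeraseEnsemble",
    "resolve_collision",
    "initiate",
    "advance_and_transition",
    "simulate_population",
]


class State(enum.IntEnum):
    """Kinetic state of an engaged polymerase."""

    MOVING = 0
    STALLED = 1
    BACKTRACKED = 2


class Action(enum.IntEnum):
    """Outcome of collision resolution for one of the two parties."""

    UNCHANGED = 0
    STALL = 1
    TERMINATE = 2


@dataclass(frozen=True)
class ModelParameters:
    """Full rate/geometry parameterization of one simulated transcription regime.

    Rates are first-order rates per minute unless noted. ``elongation_rate``
    is in kb/min as conventionally reported for RNAPII. ``window1_end`` is the
    last nucleotide (1-based, from the TSS) governed by window-1 kinetics.
    Early termination: with probability ``early_term_prob`` an initiating
    polymerase is assigned a termination site drawn from
    Poisson(``early_term_mean``), redrawn while the draw is 0 or beyond the
    gene; it terminates on reaching that site.
    """

    initiation_rate: float = 1.0          # events / min
    elongation_rate: float = 2.0          # kb / min
    window1_end: int = 250                # nt
    stall_rate_w1: float = 2.0            # /min, MOVING -> STALLED
    stall_rate_w2: float = 1.0
    backtrack_rate_w1: float = 0.5        # /min, STALLED -> BACKTRACKED
    backtrack_rate_w2: float = 0.5
    resume_stall_w1: float = 4.0          # /min, STALLED -> MOVING
    resume_stall_w2: float = 4.0
    resume_backtrack_w1: float = 1.0      # /min, BACKTRACKED -> MOVING
    resume_backtrack_w2: float = 1.0
    early_term_mean: float = 300.0        # nt
    early_term_prob: float = 0.1
    gene_length: int = 1000               # nt
    footprint: int = 40                   # nt
    dt: float = 0.005                     # min
    total_time: float = 40.0              # min

    def __post_init__(self) -> None:
        rates = (
            self.initiation_rate, self.elongation_rate,
            self.stall_rate_w1, self.stall_rate_w2,
            self.backtrack_rate_w1, self.backtrack_rate_w2,
            self.resume_stall_w1, self.resume_stall_w2,
            self.resume_backtrack_w1, self.resume_backtrack_w2,
        )
        if any(r < 0 or not math.isfinite(r) for r in rates):
            raise ConfigError("all rates must be finite and >= 0")
        if not 0.0 <= self.early_term_prob <= 1.0:
            raise ConfigError("early_term_prob must lie in [0, 1]")
        if not 1 <= self.window1_end <= self.gene_length:
            raise ConfigError("window1_end must lie in [1, gene_length]")
        if self.footprint < 1:
            raise ConfigError("footprint must be >= 1")
        if self.dt <= 0 or self.total_time <= 0:
            raise ConfigError("dt and total_time must be > 0")
        if self.early_term_prob > 0 and self.early_term_mean <= 0:
            raise ConfigError("early_term_mean must be > 0 when early_term_prob > 0")
        # Per-step transition probabilities must be valid Bernoulli
        # probabilities; initiation uses an explicit min(rate*dt, 1) and is
        # exempt.
        for name, r in (
            ("stall_rate_w1", self.stall_rate_w1),
            ("stall_rate_w2", self.stall_rate_w2),
            ("backtrack_rate_w1", self.backtrack_rate_w1),
            ("backtrack_rate_w2", self.backtrack_rate_w2),
            ("resume_stall_w1", self.resume_stall_w1),
            ("resume_stall_w2", self.resume_stall_w2),
            ("resume_backtrack_w1", self.resume_backtrack_w1),
            ("resume_backtrack_w2", self.resume_backtrack_w2),
        ):
            if r * self.dt > 1.0:
                raise ConfigError(
                    f"{name} * dt = {r * self.dt:.3g} > 1; reduce dt or the rate"
                )

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.dt))

    @property
    def hop_mean(self) -> float:
        """Mean elongation hop per step, in nt."""
        return self.elongation_rate * 1000.0 * self.dt

    @property
    def max_polymerases(self) -> int:
        """Upper bound on simultaneously engaged polymerases per gene."""
        return (self.gene_length - 1) // self.footprint + 1

    def with_(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass
class SimulatedMetrics:
    """Measured quantities from one population simulation.

    Moving ratios are (# MOVING)/(# STALLED + # BACKTRACKED) among engaged
    polymerases in each window at the final snapshot; a window with no stopped
    polymerase yields ``inf`` (and ``nan`` if it is empty altogether).
    Processivity is completed/initiated as a percentage.
    """

    initiated: int
    completed: int
    early_terminated: int
    collision_terminated: int
    collisions: int
    moving_w1: int
    stopped_w1: int
    moving_w2: int
    stopped_w2: int

    @property
    def engaged(self) -> int:
        return self.moving_w1 + self.stopped_w1 + self.moving_w2 + self.stopped_w2

    @staticmethod
    def _ratio(moving: int, stopped: int) -> float:
        if stopped > 0:
            return moving / stopped
        return math.inf if moving > 0 else math.nan

    @property
    def moving_ratio_w1(self) -> float:
        return self._ratio(self.moving_w1, self.stopped_w1)

    @property
    def moving_ratio_w2(self) -> float:
        return self._ratio(self.moving_w2, self.stopped_w2)

    @property
    def processivity(self) -> float:
        """Percentage of initiated polymerases that reached the gene end."""
        if self.initiated == 0:
            return math.nan
        return 100.0 * self.completed / self.initiated


@dataclass
class OccupancyProfile:
    """Final-snapshot active-site counts per nt, summed over the population."""

    counts: np.ndarray
    population_size: int
    parameters: ModelParameters

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.parameters.gene_length,):
            raise ConfigError("occupancy length must equal gene_length")
        if (self.counts < 0).any():
            raise ConfigError("occupancy counts must be >= 0")


# ---------------------------------------------------------------------------
# Collision rule table (pure)
# ---------------------------------------------------------------------------

def resolve_collision(upstream_state: State, downstream_state: State) -> tuple[Action, Action]:
    """Resolve a collision of a MOVING polymerase with its downstream neighbor.

    Returns (upstream_action, downstream_action). Only MOVING polymerases can
    collide; any other upstream state is a contract violation.
    """
    if State(upstream_state) is not State.MOVING:
        raise ValueError("only a MOVING polymerase can initiate a collision")
    down = State(downstream_state)
    if down is State.STALLED:
        return (Action.STALL, Action.TERMINATE)
    return (Action.STALL, Action.UNCHANGED)


# ---------------------------------------------------------------------------
# Reference (pure-Python) engine
# ---------------------------------------------------------------------------

@dataclass
class _Pol:
    position: int
    state: State
    early_term_site: int | None = None


@dataclass
class PolymeraseEnsemble:
    """Positions/states of all engaged polymerases across a gene population.

    ``genes[g]`` holds the engaged polymerases of population member ``g``
    ordered most-downstream first; within a gene any two active sites differ
    by at least the footprint. Tallies satisfy, per gene,
    ``initiated == engaged + completed + early_terminated +
    collision_terminated`` at every step.
    """

    params: ModelParameters
    genes: list[list[_Pol]] = field(default_factory=list)
    initiated: np.ndarray | None = None
    completed: np.ndarray | None = None
    early_terminated: np.ndarray | None = None
    collision_terminated: np.ndarray | None = None
    collisions: int = 0

    @classmethod
    def empty(cls, n_genes: int, params: ModelParameters) -> "PolymeraseEnsemble":
        return cls(
            params=params,
            genes=[[] for _ in range(n_genes)],
            initiated=np.zeros(n_genes, dtype=np.int64),
            completed=np.zeros(n_genes, dtype=np.int64),
            early_terminated=np.zeros(n_genes, dtype=np.int64),
            collision_terminated=np.zeros(n_genes, dtype=np.int64),
        )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def check_invariants(self) -> None:
        fp = self.params.footprint
        for g, pols in enumerate(self.genes):
            for a, b in zip(pols, pols[1:]):
                if a.position - b.position < fp:
                    raise AssertionError(f"footprint violation on gene {g}")
            engaged = len(pols)
            total = (self.completed[g] + self.early_terminated[g]
                     + self.collision_terminated[g] + engaged)
            if total != self.initiated[g]:
                raise AssertionError(f"conservation violation on gene {g}")


def _draw_term_site(params: ModelParameters, rng: np.random.Generator) -> int | None:
    if params.early_term_prob <= 0.0 or rng.random() >= params.early_term_prob:
        return None
    site = rng.poisson(params.early_term_mean)
    while site == 0 or site > params.gene_length:
        site = rng.poisson(params.early_term_mean)
    return int(site)


def initiate(ensemble: PolymeraseEnsemble, params: ModelParameters,
             rng: np.random.Generator) -> PolymeraseEnsemble:
    """Attempt initiation on every population member for one time step.

    A new polymerase is placed at position 1 in state MOVING with probability
    min(initiation_rate*dt, 1), unless an engaged polymerase's active site
    lies within footprint nt of position 1 (occlusion), in which case the
    attempt is blocked for this step. The early-termination site, if any, is
    assigned at initiation. Modifies the ensemble in place and returns it.
    """
    p_init = min(params.initiation_rate * params.dt, 1.0)
    for g, pols in enumerate(ensemble.genes):
        if rng.random() >= p_init:
            continue
        if pols and pols[-1].position - 1 < params.footprint:
            continue  # position 1 occluded
        pols.append(_Pol(1, State.MOVING, _draw_term_site(params, rng)))
        ensemble.initiated[g] += 1
    return ensemble


def advance_and_transition(ensemble: PolymeraseEnsemble, params: ModelParameters,
                           rng: np.random.Generator) -> PolymeraseEnsemble:
    """Advance/update every engaged polymerase for one time step.

    Polymerases are updated most-downstream first so that no polymerase moves
    into space vacated by an upstream neighbor in the same step. Window-1
    rates apply at positions <= window1_end, window-2 rates beyond.
    """
    dt = params.dt
    fp = params.footprint
    hop_mean = params.hop_mean
    for g, pols in enumerate(ensemble.genes):
        survivors: list[_Pol] = []
        for pol in pols:
            w1 = pol.position <= params.window1_end
            removed = False
            if pol.state is State.MOVING:
                p_stall = (params.stall_rate_w1 if w1 else params.stall_rate_w2) * dt
                if rng.random() < p_stall:
                    pol.state = State.STALLED
                else:
                    hop = int(rng.poisson(hop_mean))
                    newp = pol.position + hop
                    if survivors:
                        limit = survivors[-1].position - fp
                        if newp > limit:
                            newp = limit
                            if hop > 0:
                                ensemble.collisions += 1
                                up_act, down_act = resolve_collision(
                                    pol.state, survivors[-1].state)
                                if up_act is Action.STALL:
                                    pol.state = State.STALLED
                                if down_act is Action.TERMINATE:
                                    survivors.pop()
                                    ensemble.collision_terminated[g] += 1
                    pol.position = newp
                    if pol.early_term_site is not None and newp >= pol.early_term_site:
                        ensemble.early_terminated[g] += 1
                        removed = True
                    elif newp >= params.gene_length:
                        ensemble.completed[g] += 1
                        removed = True
            elif pol.state is State.STALLED:
                p_back = (params.backtrack_rate_w1 if w1 else params.backtrack_rate_w2) * dt
                p_res = (params.resume_stall_w1 if w1 else params.resume_stall_w2) * dt
                u = rng.random()
                if u < p_back:
                    pol.state = State.BACKTRACKED
                elif u < p_back + (1.0 - p_back) * p_res:
                    pol.state = State.MOVING
            else:  # BACKTRACKED
                p_res = (params.resume_backtrack_w1 if w1 else params.resume_backtrack_w2) * dt
                if rng.random() < p_res:
                    pol.state = State.MOVING
            if not removed:
                survivors.append(pol)
        ensemble.genes[g] = survivors
    return ensemble


def _reference_simulate(params: ModelParameters, population_size: int, seed: int,
                        validate: bool) -> tuple[OccupancyProfile, SimulatedMetrics]:
    rng = np.random.default_rng(seed)
    ens = PolymeraseEnsemble.empty(population_size, params)
    for _ in range(params.n_steps):
        advance_and_transition(ens, params, rng)
        initiate(ens, params, rng)
        if validate:
            ens.check_invariants()
    counts = np.zeros(params.gene_length, dtype=np.int64)
    m1 = s1 = m2 = s2 = 0
    for pols in ens.genes:
        for pol in pols:
            counts[pol.position - 1] += 1
            w1 = pol.position <= params.window1_end
            if pol.state is State.MOVING:
                if w1:
                    m1 += 1
                else:
                    m2 += 1
            else:
                if w1:
                    s1 += 1
                else:
                    s2 += 1
    metrics = SimulatedMetrics(
        initiated=int(ens.initiated.sum()),
        completed=int(ens.completed.sum()),
        early_terminated=int(ens.early_terminated.sum()),
        collision_terminated=int(ens.collision_terminated.sum()),
        collisions=int(ens.collisions),
        moving_w1=m1, stopped_w1=s1, moving_w2=m2, stopped_w2=s2,
    )
    return OccupancyProfile(counts, population_size, params), metrics


# ---------------------------------------------------------------------------
# Fast (numba) engine
# ---------------------------------------------------------------------------

@njit(cache=True)
def _kernel(seed, n_genes, n_steps, p_init, hop_mean, w1_end,
            ps1, pb1, prs1, prb1, ps2, pb2, prs2, prb2,
            p_term, term_mean, gene_length, footprint, validate):
    np.random.seed(seed)
    K = (gene_length - 1) // footprint + 2
    pos = np.zeros((n_genes, K), np.int64)
    st = np.zeros((n_genes, K), np.int64)
    ts = np.full((n_genes, K), -1, np.int64)
    npol = np.zeros(n_genes, np.int64)
    initiated = np.zeros(n_genes, np.int64)
    completed = np.zeros(n_genes, np.int64)
    early = np.zeros(n_genes, np.int64)
    collterm = np.zeros(n_genes, np.int64)
    collisions = 0
    violations = 0
    BIG = np.int64(1) << 40
    for _step in range(n_steps):
        for g in range(n_genes):
            n = npol[g]
            w = 0
            prev_pos = BIG
            for k in range(n):
                p = pos[g, k]
                s = st[g, k]
                t = ts[g, k]
                in_w1 = p <= w1_end
                removed = False
                if s == 0:  # MOVING
                    pstall = ps1 if in_w1 else ps2
                    if np.random.random() < pstall:
                        s = 1
                    else:
                        hop = np.random.poisson(hop_mean)
                        newp = p + hop
                        limit = prev_pos - footprint
                        if newp > limit:
                            newp = limit
                            if hop > 0:
                                collisions += 1
                                s = 1  # upstream stalls in every rule
                                if w > 0 and st[g, w - 1] == 1:
                                    # downstream stalled polymerase terminated
                                    w -= 1
                                    collterm[g] += 1
                                    if w > 0:
                                        prev_pos = pos[g, w - 1]
                                    else:
                                        prev_pos = BIG
                        p = newp
                        if t >= 0 and p >= t:
                            early[g] += 1
                            removed = True
                        elif p >= gene_length:
                            completed[g] += 1
                            removed = True
                elif s == 1:  # STALLED
                    pback = pb1 if in_w1 else pb2
                    pres = prs1 if in_w1 else prs2
                    u = np.random.random()
                    if u < pback:
                        s = 2
                    elif u < pback + (1.0 - pback) * pres:
                        s = 0
                else:  # BACKTRACKED
                    presb = prb1 if in_w1 else prb2
                    if np.random.random() < presb:
                        s = 0
                if not removed:
                    pos[g, w] = p
                    st[g, w] = s
                    ts[g, w] = t
                    prev_pos = p
                    w += 1
            # initiation (blocked while position 1 is occluded)
            if np.random.random() < p_init:
                blocked = w > 0 and (pos[g, w - 1] - 1) < footprint
                if (not blocked) and w < K:
                    pos[g, w] = 1
                    st[g, w] = 0
                    tval = np.int64(-1)
                    if p_term > 0.0 and np.random.random() < p_term:
                        sd = np.random.poisson(term_mean)
                        while sd == 0 or sd > gene_length:
                            sd = np.random.poisson(term_mean)
                        tval = np.int64(sd)
                    ts[g, w] = tval
                    initiated[g] += 1
                    w += 1
            npol[g] = w
            if validate:
                for k in range(1, w):
                    if pos[g, k - 1] - pos[g, k] < footprint:
                        violations += 1
                if initiated[g] != w + completed[g] + early[g] + collterm[g]:
                    violations += 1
    occupancy = np.zeros(gene_length, np.int64)
    m1 = np.int64(0)
    s1c = np.int64(0)
    m2 = np.int64(0)
    s2c = np.int64(0)
    for g in range(n_genes):
        for k in range(npol[g]):
            p = pos[g, k]
            occupancy[p - 1] += 1
            if p <= w1_end:
                if st[g, k] == 0:
                    m1 += 1
                else:
                    s1c += 1
            else:
                if st[g, k] == 0:
                    m2 += 1
                else:
                    s2c += 1
    tallies = np.empty(5, np.int64)
    tallies[0] = initiated.sum()
    tallies[1] = completed.sum()
    tallies[2] = early.sum()
    tallies[3] = collterm.sum()
    tallies[4] = collisions
    states = np.empty(4, np.int64)
    states[0] = m1
    states[1] = s1c
    states[2] = m2
    states[3] = s2c
    return occupancy, tallies, states, violations


def simulate_population(params: ModelParameters, population_size: int, seed: int,
                        engine: str = "fast", validate: bool = False,
                        ) -> tuple[OccupancyProfile, SimulatedMetrics]:
    """Simulate a population of identical synthetic genes to steady state.

    Runs ``total_time/dt`` time steps starting from empty genes and returns
    the final-snapshot occupancy profile (summed over the population) together
    with the measured metrics. Bit-reproducible for a fixed seed and engine.

    Parameters
    ----------
    engine:
        ``"fast"`` (numba kernel, default) or ``"reference"`` (pure Python;
        identical per-step semantics, different random stream).
    validate:
        Check the footprint-exclusion and conservation invariants at every
        time step and raise if any is violated.
    """
    if population_size < 1:
        raise ConfigError("population_size must be >= 1")
    if engine == "reference":
        return _reference_simulate(params, population_size, seed, validate)
    if engine != "fast":
        raise ConfigError(f"unknown engine {engine!r}")
    occupancy, tallies, states, violations = _kernel(
        int(seed) & 0x7FFFFFFF, int(population_size), params.n_steps,
        min(params.initiation_rate * params.dt, 1.0), params.hop_mean,
        int(params.window1_end),
        params.stall_rate_w1 * params.dt, params.backtrack_rate_w1 * params.dt,
        params.resume_stall_w1 * params.dt, params.resume_backtrack_w1 * params.dt,
        params.stall_rate_w2 * params.dt, params.backtrack_rate_w2 * params.dt,
        params.resume_stall_w2 * params.dt, params.resume_backtrack_w2 * params.dt,
        params.early_term_prob, params.early_term_mean,
        int(params.gene_length), int(params.footprint), validate,
    )
    if validate and violations:
        raise AssertionError(f"{violations} invariant violations during run")
    metrics = SimulatedMetrics(
        initiated=int(tallies[0]), completed=int(tallies[1]),
        early_terminated=int(tallies[2]), collision_terminated=int(tallies[3]),
        collisions=int(tallies[4]),
        moving_w1=int(states[0]), stopped_w1=int(states[1]),
        moving_w2=int(states[2]), stopped_w2=int(states[3]),
    )
    return OccupancyProfile(occupancy, population_size, params), metrics
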