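"""Population state and forward-time dynamics of a single non-genic locus.

The model follows a well-mixed, fixed-size population of N asexual
haploids.  Only the fitness contribution F of one locus is tracked; it
decomposes as F = A * E into the adaptive value A of the expression
product and its expression level E.  One model time-step is the waiting
time for one mutation at the locus, so every offspring incurs exactly
one fitness-effect draw per step (and one expression-effect draw).
Offspring may also lose the locus entirely through a structural
variation, with probability d per offspring per step; a lost locus
contributes F = 0 forever after along that lineage.

Two reproduction regimes are modelled:

``high``
    fewer than ~2000 generations pass between mutations, so many locus
    variants coexist; each of the N offspring independently picks a
    parent with probability proportional to relative fitness.
``low``
    more than ~2000 generations pass between mutations, so a single
    variant fixes before the next mutation arrives; one parent is drawn
    (probability proportional to relative fitness) and all N offspring
    descend from it.

Individuals with F <= -1 are lethal: they remain in the state vector but
receive zero selection weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .ancestry import AncestryLog, LCAResult, crossed_and_retained, trace_last_common_ancestor
from .dfe import DFEParams, draw_fitness_effects
from .expression import draw_expression_effect

__all__ = [
    "SimConfig",
    "PopulationState",
    "StepOutcome",
    "ReplicateResult",
    "ExtinctionError",
    "relative_fitness",
    "initialize_population",
    "select_parents",
    "advance_step",
    "run_replicate",
]

Regime = Literal["high", "low"]


class ExtinctionError(RuntimeError):
    """Raised when no viable individual (F > -1) remains."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration.

    Parameters
    ----------
    N : int
        Population size.
    T : int
        Number of mutational time-steps (default 1000).
    regime : {"high", "low"}
        Mutation-rate regime (see module docstring).
    d : float
        Per-offspring, per-step locus deletion probability.
    fitness_threshold : float
        Adaptation threshold on the fixed variant's fitness (default 0.1).
    neutral_threshold : float
        Neutrality band half-width for mutation classification (5e-4).
    E0 : float
        Initial expression level, representing leaky expression (1e-3).
    E_min, E_max : float
        Expression bounds; updates leaving [E_min, E_max] are clipped.
    alpha : float
        Power-law exponent of the |dE| magnitude distribution (2.25).
    delta_E_min : float
        Lower cutoff of the |dE| power law (required for normalizability;
        default 1e-6, small enough that expression stays far below its
        ceiling in standard runs).
    jump_prob, jump_effect : float
        Optional rare-jump augmentation of the DFE: with probability
        ``jump_prob`` the fitness effect of a mutation is replaced by
        ``jump_effect``.  Both default to the unaugmented model.
    seed : int or None
        Base seed recorded in manifests; run functions take explicit seeds.
    """

    N: int = 1000
    T: int = 1000
    regime: Regime = "high"
    d: float = 0.0
    fitness_threshold: float = 0.1
    neutral_threshold: float = 0.5e-3
    E0: float = 1e-3
    E_min: float = 1e-3
    E_max: float = 1.0
    alpha: float = 2.25
    delta_E_min: float = 1e-6
    jump_prob: float = 0.0
    jump_effect: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1 or self.T < 1:
            raise ValueError("N and T must be at least 1")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"deletion probability d={self.d} outside [0, 1]")
        if not self.E_min <= self.E0 <= self.E_max:
            raise ValueError("require E_min <= E0 <= E_max")
        if self.alpha <= 1.0:
            raise ValueError("power-law exponent alpha must exceed 1")
        if self.delta_E_min <= 0:
            raise ValueError("delta_E_min must be positive")
        if self.regime not in ("high", "low"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0.0 <= self.jump_prob <= 1.0:
            raise ValueError("jump_prob outside [0, 1]")


@dataclass
class PopulationState:
    """Per-individual locus state at one time-step.

    F is the locus fitness contribution, E the expression level, and L
    the locus-presence flag; L = 0 forces F = E = 0.  The adaptive value
    A = F / E is derived, never stored.
    """

    F: np.ndarray
    E: np.ndarray
    L: np.ndarray  # boolean carrier flags
    t: int = 0

    @property
    def A(self) -> np.ndarray:
        """Adaptive values F / E; NaN for locus-free individuals."""
        return np.where(self.L, self.F / np.where(self.L, self.E, 1.0), np.nan)

    @property
    def n_carriers(self) -> int:
        return int(self.L.sum())


@dataclass
class StepOutcome:
    """Result of one time-step update."""

    next_state: PopulationState
    parents: np.ndarray
    delta_F: np.ndarray
    delta_E: np.ndarray | None


def relative_fitness(F: np.ndarray) -> np.ndarray:
    """Normalized selection weights from locus fitness contributions.

    Viable individuals (F > -1) get weight (1 + F - minfit) / allfit,
    where minfit is the minimum fitness among viable individuals and
    allfit normalizes the weights to sum to 1.  Lethal individuals
    (F <= -1) get weight 0.  Note a weight can be positive even at F = 0
    (e.g. after locus deletion) whenever minfit < 0.

    Raises
    ------
    ExtinctionError
        If no viable individual exists.
    """
    w, wsum = _selection_weights(np.asarray(F, dtype=float))
    return w / wsum


def _selection_weights(F: np.ndarray) -> tuple[np.ndarray, float]:
    """Unnormalized selection weights (1 + F - minfit for viable, else 0)
    and their sum; single source for the relative-fitness formula."""
    viable = F > -1.0
    minfit = np.where(viable, F, np.inf).min()
    if not np.isfinite(minfit):
        raise ExtinctionError("no viable individual (all F <= -1)")
    w = (1.0 + F - minfit) * viable
    return w, float(np.add.reduce(w))


def initialize_population(config: SimConfig) -> PopulationState:
    """Clonal initial population: A = 0, E = E0, locus present everywhere."""
    N = config.N
    return PopulationState(
        F=np.zeros(N),
        E=np.full(N, config.E0),
        L=np.ones(N, dtype=bool),
        t=0,
    )


def select_parents(
    relfit: np.ndarray, regime: Regime, N: int, rng: np.random.Generator
) -> np.ndarray:
    """Parent indices for the next time-step.

    High regime: N independent categorical draws from ``relfit``.
    Low regime: one categorical draw, replicated N times (a single
    variant fixes between mutational time-steps).

    Draws use vectorized rejection sampling (exact for any categorical
    distribution) while the weights are well spread, falling back to
    inverse-CDF search when they are concentrated on few individuals.
    """
    w = np.asarray(relfit, dtype=float)
    if regime == "low":
        one = _categorical(w, 1, rng)[0]
        return np.full(N, one, dtype=np.intp)
    return _categorical(w, N, rng)


def _categorical(w: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    k = w.size
    wmax = w.max()
    wsum = w.sum()
    accept_rate = wsum / (k * wmax)
    if size >= 16 and accept_rate >= 0.25:
        out = np.empty(size, dtype=np.intp)
        filled = 0
        while filled < size:
            m = int(1.2 * (size - filled) / accept_rate) + 16
            idx = rng.integers(0, k, m)
            acc = idx[rng.random(m) * wmax < w[idx]][: size - filled]
            out[filled : filled + acc.size] = acc
            filled += acc.size
        return out
    cdf = np.cumsum(w)
    cdf[-1] = wsum  # guard against round-off at the top
    return np.searchsorted(cdf, rng.random(size) * wsum, side="right").astype(np.intp)


def _mutation_effects(
    dfe: DFEParams, config: SimConfig, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Fitness-effect draws, with the optional rare large-jump atom."""
    dF = draw_fitness_effects(dfe, count, rng)
    if config.jump_prob > 0.0:
        jump = rng.random(count) < config.jump_prob
        dF = np.where(jump, config.jump_effect, dF)
    return dF


def advance_step(
    state: PopulationState,
    dfe: DFEParams,
    config: SimConfig,
    rng: np.random.Generator,
    track_expression: bool = True,
) -> StepOutcome:
    """Advance the population by one mutational time-step.

    Per offspring, events happen in the order: inherit from the selected
    parent, locus-deletion test (probability d; a deleted locus, whether
    inherited as lost or lost now, suppresses mutation and zeroes F and
    E), then one fitness-effect mutation and one expression-effect
    mutation, with E clipped to [E_min, E_max].
    """
    N = config.N
    # selection on unnormalized weights (equivalent to relative_fitness,
    # which only rescales them)
    w, _ = _selection_weights(state.F)
    if config.regime == "low":
        parents = np.full(N, _categorical(w, 1, rng)[0], dtype=np.intp)
    else:
        parents = _categorical(w, N, rng)

    carrier = state.L[parents]
    if config.d > 0.0:
        carrier = carrier & (rng.random(N) >= config.d)

    dF = _mutation_effects(dfe, config, N, rng)
    F_new = np.where(carrier, state.F[parents] + dF, 0.0)

    if track_expression:
        dE = draw_expression_effect(config, N, rng)
        E_new = np.where(
            carrier,
            np.clip(state.E[parents] + dE, config.E_min, config.E_max),
            0.0,
        )
    else:
        dE = None
        E_new = np.where(carrier, config.E0, 0.0)

    next_state = PopulationState(F=F_new, E=E_new, L=carrier, t=state.t + 1)
    return StepOutcome(next_state=next_state, parents=parents, delta_F=dF, delta_E=dE)


@dataclass
class ReplicateResult:
    """Outcome and trajectory summaries of one replicate.

    ``crossed`` means the locus was retained at T and the last common
    ancestor of the final population was fitter than the threshold.
    ``crossed_ever`` additionally flags replicates whose fixed variant
    exceeded the threshold at any time-step; in the low regime the fixed
    variant is tracked every step, in the high regime only the final LCA
    is traced, so there ``crossed_ever == crossed``.
    """

    crossed: bool
    retained: bool
    extinct: bool
    crossed_ever: bool
    lca: LCAResult | None
    seed: object
    n_steps: int
    mean_F: np.ndarray  # length n_steps + 1, population mean over all N
    sd_F: np.ndarray | None  # recorded only with expression tracking
    mean_E: np.ndarray | None  # carrier means; NaN where no carriers
    mean_A: np.ndarray | None
    n_carriers: np.ndarray
    fixed_fitness: np.ndarray | None = None  # low regime: per-step fixed variant F
    delta_a: np.ndarray | None = None
    ancestry: AncestryLog | None = None
    final_state: PopulationState | None = field(default=None, repr=False)

    @property
    def min_mean_fitness(self) -> float:
        return float(self.mean_F.min())

    @property
    def time_of_min(self) -> int:
        """Earliest time-step at which the population-mean fitness is minimal."""
        return int(self.mean_F.argmin())


def run_replicate(
    dfe: DFEParams,
    config: SimConfig,
    seed,
    *,
    track_expression: bool = True,
    collect_delta_a: bool = False,
    keep_ancestry: bool = False,
    keep_final_state: bool = False,
) -> ReplicateResult:
    """Run one replicate for T time-steps and trace the fixed variant.

    ``seed`` may be an int, a SeedSequence or a Generator.  Trajectory
    means of E and A (over carriers) are recorded only when expression is
    tracked.  ``collect_delta_a`` pools the per-offspring adaptive-value
    increments dA = A_child - A_parent over all carrier-to-carrier
    transitions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N, T = config.N, config.T
    state = initialize_population(config)

    parents_log = np.empty((T, N), dtype=np.int16 if N < 2**15 else np.int32)
    F_archive = np.empty((T + 1, N))
    F_archive[0] = state.F
    mean_F = np.empty(T + 1)
    n_carriers = np.empty(T + 1, dtype=np.intp)
    mean_F[0], n_carriers[0] = 0.0, N
    if track_expression:
        sd_F = np.empty(T + 1)
        mean_E = np.empty(T + 1)
        mean_A = np.empty(T + 1)
        sd_F[0], mean_E[0], mean_A[0] = 0.0, config.E0, 0.0
    else:
        sd_F = mean_E = mean_A = None
    fixed_fitness = np.full(T + 1, np.nan) if config.regime == "low" else None
    delta_a_chunks: list[np.ndarray] = [] if collect_delta_a else None

    extinct = False
    t_stop = T
    for t in range(T):
        try:
            out = advance_step(state, dfe, config, rng, track_expression)
        except ExtinctionError:
            extinct = True
            t_stop = t
            break
        prev = state
        state = out.next_state
        parents_log[t] = out.parents
        F_archive[t + 1] = state.F
        mean_F[t + 1] = np.add.reduce(state.F) / N
        nc = int(np.count_nonzero(state.L))
        n_carriers[t + 1] = nc
        if track_expression:
            sd_F[t + 1] = state.F.std()
            if nc:
                mean_E[t + 1] = np.add.reduce(state.E) / nc  # E = 0 off-locus
                mean_A[t + 1] = (
                    np.add.reduce(
                        np.where(state.L, state.F / np.where(state.L, state.E, 1.0), 0.0)
                    )
                    / nc
                )
            else:
                mean_E[t + 1] = np.nan
                mean_A[t + 1] = np.nan
        if fixed_fitness is not None:
            # low regime: the variant fixed at step t+1 is the single parent
            fixed_fitness[t + 1] = prev.F[out.parents[0]]
        if collect_delta_a and nc:
            mask = state.L
            par = out.parents[mask]
            da = state.F[mask] / state.E[mask] - prev.F[par] / prev.E[par]
            delta_a_chunks.append(da)

    if extinct:
        sl = slice(0, t_stop + 1)
        return ReplicateResult(
            crossed=False,
            retained=False,
            extinct=True,
            crossed_ever=False,
            lca=None,
            seed=seed,
            n_steps=t_stop,
            mean_F=mean_F[sl],
            sd_F=sd_F[sl] if track_expression else None,
            mean_E=mean_E[sl] if track_expression else None,
            mean_A=mean_A[sl] if track_expression else None,
            n_carriers=n_carriers[sl],
            fixed_fitness=fixed_fitness[sl] if fixed_fitness is not None else None,
            delta_a=np.concatenate(delta_a_chunks) if delta_a_chunks else None,
        )

    log = AncestryLog(parents=parents_log, fitness_archive=F_archive)
    lca = trace_last_common_ancestor(log, T)
    crossed, retained = crossed_and_retained(log, state.L, config, lca=lca)
    if config.regime == "low":
        crossed_ever = bool(np.nanmax(fixed_fitness) > config.fitness_threshold)
    else:
        crossed_ever = crossed
    return ReplicateResult(
        crossed=crossed,
        retained=retained,
        extinct=False,
        crossed_ever=crossed_ever,
        lca=lca,
        seed=seed,
        n_steps=T,
        mean_F=mean_F,
        sd_F=sd_F,
        mean_E=mean_E,
        mean_A=mean_A,
        n_carriers=n_carriers,
        fixed_fitness=fixed_fitness,
        delta_a=(
            np.concatenate(delta_a_chunks)
            if delta_a_chunks
            else (np.empty(0) if collect_delta_a else None)
        ),
        ancestry=log if keep_ancestry else None,
        final_state=state if keep_final_state else None,
    )
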