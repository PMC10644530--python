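"""Parentage records and last-common-ancestor (fixed variant) tracing.

The variant carried by the most recent single individual from which the
whole population descends is, by definition, fixed.  The tracer walks
the per-step parent vectors backwards, shrinking the set of unique
ancestors until it first becomes a singleton; the locus fitness of that
individual decides whether the replicate counts as having crossed the
adaptation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AncestryLog",
    "LCAResult",
    "trace_last_common_ancestor",
    "crossed_and_retained",
]


@dataclass
class AncestryLog:
    """Per-time-step parentage and fitness archive of one replicate.

    ``parents[k]`` holds, for each individual of step k+1, the index of
    its parent in the step-k population (all entries equal in the low
    mutation-rate regime).  ``fitness_archive[k]`` is the locus fitness
    vector F at step k, k = 0..T.
    """

    parents: np.ndarray  # (T, N) integer
    fitness_archive: np.ndarray  # (T+1, N) float

    @property
    def n_steps(self) -> int:
        return self.parents.shape[0]


@dataclass(frozen=True)
class LCAResult:
    """Last common ancestor of the population at some time-step.

    ``lca_time`` and ``lca_index`` identify the ancestor individual;
    ``coalesced`` is False when the backward trace reaches the clonal
    initial population without finding a singleton ancestor set, in
    which case the (de facto common) initial state with fitness 0 is
    reported.
    """

    lca_time: int
    lca_index: int
    lca_fitness: float
    coalesced: bool


def trace_last_common_ancestor(log: AncestryLog, t: int | None = None) -> LCAResult:
    """Trace the last common ancestor of all individuals at step ``t``.

    Starting from the unique parents of the step-``t`` individuals, the
    unique-ancestor set is followed backwards until it first becomes a
    singleton {i}; that individual, living at some step u < t, is the
    LCA and its fitness F_u(i) is the fitness of the fixed variant.  In
    the low mutation-rate regime every parent vector is constant, so the
    trace terminates at the immediately preceding step.
    """
    if t is None:
        t = log.n_steps
    if not 1 <= t <= log.n_steps:
        raise ValueError(f"time-step {t} outside recorded range 1..{log.n_steps}")
    # X below holds indices of individuals at step `step`
    X = np.unique(log.parents[t - 1])
    step = t - 1
    while X.size > 1 and step > 0:
        X = np.unique(log.parents[step - 1][X])
        step -= 1
    if X.size == 1:
        i = int(X[0])
        return LCAResult(
            lca_time=step,
            lca_index=i,
            lca_fitness=float(log.fitness_archive[step, i]),
            coalesced=True,
        )
    # reached the clonal initial population without coalescing
    return LCAResult(lca_time=0, lca_index=int(X[0]), lca_fitness=0.0, coalesced=False)


def crossed_and_retained(
    log: AncestryLog,
    final_carriers: np.ndarray,
    config,
    lca: LCAResult | None = None,
) -> tuple[bool, bool]:
    """Replicate outcome flags.

    ``retained``: at least one individual still carries the locus at the
    final step.  ``crossed``: retained, and the last common ancestor of
    the final population is strictly fitter than the adaptation
    threshold.
    """
    retained = bool(np.asarray(final_carriers).any())
    if not retained:
        return False, False
    if lca is None:
        lca = trace_last_common_ancestor(log)
    return lca.lca_fitness > config.fitness_threshold, retained
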