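"""Mutational effects on expression level and derived adaptive values.

Expression changes dE have power-law magnitudes, Pr(|dE| = x) ~ x**-2.25
(measured for expression from random sequences), with a random sign
(negative with probability 0.5).  The power law needs a lower cutoff to
be normalizable; it is configurable (``SimConfig.delta_E_min``) and
defaults to 1e-6.  The reflected walk of E above its leaky floor is
scale-invariant in the cutoff, so the cutoff mainly sets how far
expression drifts upward over a run; at the default, E stays orders of
magnitude below its ceiling in standard runs.  Expression is clipped to
[E_min, E_max] after every update, and the adaptive value is derived as
A = F / E for locus carriers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "draw_expression_effect",
    "update_expression",
    "derive_adaptive_value",
    "collect_delta_A",
    "pareto_magnitudes",
]


def pareto_magnitudes(
    alpha: float, x_min: float, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw magnitudes with density proportional to x**-alpha on [x_min, inf).

    Inverse-CDF sampling: x = x_min * (1 - u) ** (-1 / (alpha - 1)).
    """
    if alpha <= 1.0:
        raise ValueError("alpha must exceed 1 for a normalizable power law")
    if x_min <= 0:
        raise ValueError("x_min must be positive")
    u = rng.random(count)
    return x_min * (1.0 - u) ** (-1.0 / (alpha - 1.0))


def draw_expression_effect(
    config, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Signed expression changes: power-law magnitude, fair random sign."""
    mags = pareto_magnitudes(config.alpha, config.delta_E_min, count, rng)
    signs = np.where(rng.random(count) < 0.5, -1.0, 1.0)
    return mags * signs


def update_expression(E_parent, delta_E, config):
    """Apply an expression change and clip to [E_min, E_max]."""
    return np.clip(E_parent + delta_E, config.E_min, config.E_max)


def derive_adaptive_value(F, E):
    """Adaptive value A = F / E; requires E > 0 (locus present)."""
    E_arr = np.asarray(E, dtype=float)
    if np.any(E_arr <= 0):
        raise ValueError("adaptive value undefined for locus-free individuals (E = 0)")
    return np.asarray(F, dtype=float) / E_arr


def collect_delta_A(results) -> np.ndarray:
    """Pool per-offspring adaptive-value increments across replicates.

    Each replicate must have been run with ``collect_delta_a=True``;
    increments exist only for carrier-to-carrier transitions (deletion
    events and extinct tails contribute nothing).
    """
    chunks = []
    for r in results:
        if r.delta_a is None:
            raise ValueError(
                "replicate was run without delta-A tracking; "
                "re-run with collect_delta_a=True"
            )
        chunks.append(r.delta_a)
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)
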