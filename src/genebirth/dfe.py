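"""Two-sided gamma distributions of mutational fitness effects (DFEs).

A locus is characterized by a four-parameter DFE: a new mutation is
beneficial with probability ``f`` and its effect is then drawn from a
gamma distribution with shape ``s`` and mean ``p``; otherwise the effect
is minus a gamma draw with shape ``s`` and mean ``n``.  Small ``s`` gives
long-tailed distributions.  Mutations with absolute effect below a neutrality
threshold (default 5e-4, stringent for N = 1000) are effectively
invisible to selection and are counted as neutral.

The module provides the sampler, the classifier, exact incomplete-gamma
expressions for the class fractions and truncated class means, the
parameter grid surveyed in the accompanying experiments, and a census of
that grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaincc

__all__ = [
    "DFEParams",
    "EffectClassification",
    "ParameterGrid",
    "draw_fitness_effects",
    "classify_effects",
    "analytic_fractions",
    "enumerate_grid",
    "grid_classification_census",
    "census_aggregates",
    "DEFAULT_NEUTRAL_THRESHOLD",
]

DEFAULT_NEUTRAL_THRESHOLD = 0.5e-3

# Parameter values surveyed (mean beneficial effect p, beneficial fraction f,
# mean deleterious magnitude n, gamma shape s) and locus-deletion
# probabilities d.
GRID_P = (0.001, 0.003, 0.005)
GRID_F = (0.25, 0.5, 0.75)
GRID_N = (0.001, 0.005, 0.01)
GRID_S_N1000 = (0.1, 0.3, 0.6, 0.9)
GRID_S_N100 = (0.3, 0.6, 0.9)
GRID_D = (0.0, 0.005, 0.01, 0.05)


@dataclass(frozen=True)
class DFEParams:
    """Parameters of a two-sided gamma DFE.

    Attributes
    ----------
    p : float
        Mean effect of beneficial mutations (fitness units, > 0).
    f : float
        Probability that a mutation is beneficial, in [0, 1].
    n : float
        Mean absolute effect of deleterious mutations (> 0).
    s : float
        Gamma shape parameter (> 0); both branches share it.
    """

    p: float
    f: float
    n: float
    s: float

    def __post_init__(self) -> None:
        if not (self.p > 0 and self.n > 0 and self.s > 0):
            raise ValueError(
                f"DFE parameters p, n, s must be positive, got "
                f"p={self.p}, n={self.n}, s={self.s}"
            )
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"beneficial fraction f must lie in [0, 1], got {self.f}")

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.p, self.f, self.n, self.s)


#: DFE closest to the one measured for Chlamydomonas reinhardtii.
CHLAMYDOMONAS = DFEParams(p=0.001, f=0.75, n=0.01, s=0.3)


@dataclass(frozen=True)
class EffectClassification:
    """Counts and mean magnitudes of classified fitness effects."""

    n_positive: int
    n_neutral: int
    n_negative: int
    mean_abs_positive: float  # nan when n_positive == 0
    mean_abs_negative: float  # nan when n_negative == 0

    @property
    def total(self) -> int:
        return self.n_positive + self.n_neutral + self.n_negative


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered survey grid of DFE parameter sets and deletion probabilities."""

    dfe_sets: tuple[DFEParams, ...]
    deletion_probs: tuple[float, ...]
    population_size: int


def draw_fitness_effects(
    params: DFEParams, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` i.i.d. fitness effects from a two-sided gamma DFE.

    Each draw is +Gamma(shape=s, scale=p/s) with probability f, and
    -Gamma(shape=s, scale=n/s) otherwise, so the beneficial branch has
    mean p and the deleterious branch mean magnitude n.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    beneficial = rng.random(count) < params.f
    # float32 variates are upcast by the float64 scale; their ~1e-7
    # relative granularity is immaterial at the effect scales modelled
    g = rng.standard_gamma(params.s, count, dtype=np.float32)
    scale = np.where(beneficial, params.p / params.s, -params.n / params.s)
    return g * scale


def classify_effects(
    effects: np.ndarray, neutral_threshold: float = DEFAULT_NEUTRAL_THRESHOLD
) -> EffectClassification:
    """Classify effects as positive (>= threshold), negative (<= -threshold)
    or neutral (strictly inside the band); boundaries are inclusive."""
    if neutral_threshold <= 0:
        raise ValueError("neutral_threshold must be positive")
    effects = np.asarray(effects, dtype=float)
    pos = effects >= neutral_threshold
    neg = effects <= -neutral_threshold
    n_pos = int(pos.sum())
    n_neg = int(neg.sum())
    return EffectClassification(
        n_positive=n_pos,
        n_neutral=int(effects.size - n_pos - n_neg),
        n_negative=n_neg,
        mean_abs_positive=float(effects[pos].mean()) if n_pos else float("nan"),
        mean_abs_negative=float(-effects[neg].mean()) if n_neg else float("nan"),
    )


def _gamma_sf(s: float, mean: float, x: float) -> float:
    """P(X >= x) for X ~ Gamma(shape=s, scale=mean/s)."""
    return float(gammaincc(s, x * s / mean))


def _gamma_truncated_mean(s: float, mean: float, x: float) -> float:
    """E[X | X >= x] for X ~ Gamma(shape=s, scale=mean/s).

    Uses E[X 1(X>=x)] = mean * Q(s+1, x s / mean) with Q the regularized
    upper incomplete gamma function.
    """
    tail = gammaincc(s, x * s / mean)
    if tail == 0.0:
        return float("nan")
    return float(mean * gammaincc(s + 1, x * s / mean) / tail)


def analytic_fractions(
    params: DFEParams, neutral_threshold: float = DEFAULT_NEUTRAL_THRESHOLD
) -> tuple[float, float, float, float, float]:
    """Closed-form class fractions and truncated class means of a DFE.

    Returns ``(frac_positive, frac_neutral, frac_negative,
    mean_abs_positive, mean_abs_negative)`` where the fractions refer to
    classification at ``neutral_threshold`` and the means are the
    conditional mean magnitudes of the classified (non-neutral) draws.
    """
    if neutral_threshold < 0:
        raise ValueError("neutral_threshold must be non-negative")
    c = neutral_threshold
    frac_pos = params.f * _gamma_sf(params.s, params.p, c)
    frac_neg = (1.0 - params.f) * _gamma_sf(params.s, params.n, c)
    frac_neu = 1.0 - frac_pos - frac_neg
    mean_pos = _gamma_truncated_mean(params.s, params.p, c)
    mean_neg = _gamma_truncated_mean(params.s, params.n, c)
    return frac_pos, frac_neu, frac_neg, mean_pos, mean_neg


def enumerate_grid(population_size: int) -> ParameterGrid:
    """The ordered survey grid for a supported population size.

    N=1000 spans 3x3x3x4 = 108 DFE sets; N=100 restricts the shape values
    to {0.3, 0.6, 0.9} (81 sets).  Ordering is lexicographic in
    (p, f, n, s) so per-index results are reproducible.
    """
    if population_size == 1000:
        s_values: Sequence[float] = GRID_S_N1000
    elif population_size == 100:
        s_values = GRID_S_N100
    else:
        raise ValueError(f"unsupported population size {population_size}")
    sets = tuple(
        DFEParams(p=p, f=f, n=n, s=s)
        for p, f, n, s in product(GRID_P, GRID_F, GRID_N, s_values)
    )
    return ParameterGrid(
        dfe_sets=sets, deletion_probs=GRID_D, population_size=population_size
    )


def grid_classification_census(
    grid: ParameterGrid,
    neutral_threshold: float = DEFAULT_NEUTRAL_THRESHOLD,
    mc_draws: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-DFE classification table over a parameter grid.

    One row per DFE set with the closed-form class fractions, truncated
    class means, and boolean class flags:

    ``neutral_majority``
        neutral fraction strictly exceeds both other fractions;
    ``negative_more_numerous``
        negative fraction strictly exceeds the positive fraction;
    ``negative_larger``
        negative-class mean magnitude strictly exceeds the positive one;
    ``magnitude_tied`` / ``fraction_tied``
        the compared quantities are exactly equal (p == n ties).

    When ``mc_draws`` > 0, Monte-Carlo counterparts of the fractions,
    means and flags (columns prefixed ``mc_``) are computed from that
    many draws per DFE, mirroring a finite-sample census in which tied
    sets split evenly.
    """
    rows = []
    for idx, dfe in enumerate(grid.dfe_sets):
        fp, fneu, fn, mp, mn = analytic_fractions(dfe, neutral_threshold)
        row = {
            "dfe_index": idx,
            "p": dfe.p,
            "f": dfe.f,
            "n": dfe.n,
            "s": dfe.s,
            "frac_pos": fp,
            "frac_neutral": fneu,
            "frac_neg": fn,
            "mean_abs_pos": mp,
            "mean_abs_neg": mn,
            "neutral_majority": fneu > fp and fneu > fn,
            "negative_more_numerous": fn > fp,
            "negative_larger": mn > mp,
            "fraction_tied": fn == fp,
            "magnitude_tied": mn == mp,
        }
        if mc_draws > 0:
            if rng is None:
                raise ValueError("rng is required when mc_draws > 0")
            cls = classify_effects(
                draw_fitness_effects(dfe, mc_draws, rng), neutral_threshold
            )
            row.update(
                mc_frac_pos=cls.n_positive / mc_draws,
                mc_frac_neutral=cls.n_neutral / mc_draws,
                mc_frac_neg=cls.n_negative / mc_draws,
                mc_mean_abs_pos=cls.mean_abs_positive,
                mc_mean_abs_neg=cls.mean_abs_negative,
            )
            row["mc_neutral_majority"] = (
                row["mc_frac_neutral"] > row["mc_frac_pos"]
                and row["mc_frac_neutral"] > row["mc_frac_neg"]
            )
            row["mc_negative_more_numerous"] = row["mc_frac_neg"] > row["mc_frac_pos"]
            row["mc_negative_larger"] = row["mc_mean_abs_neg"] > row["mc_mean_abs_pos"]
        rows.append(row)
    return pd.DataFrame(rows)


def census_aggregates(census: pd.DataFrame) -> dict[str, float]:
    """Aggregate counts over a census table.

    Strict counts use the closed-form flags.  ``expected_*`` counts add
    one half for each exactly tied comparison — the expectation of the
    corresponding finite-sample census, since tied DFEs (p == n) split
    evenly under any number of draws.  The two joint classes are the
    "strictest" DFEs (neutral-majority with larger and more numerous
    negative effects) and their full complement (neutral-minority with
    smaller and fewer negative effects).
    """
    c = census
    n_total = len(c)
    joint_strict = (
        c.neutral_majority & c.negative_more_numerous & c.negative_larger
    ).sum()
    joint_complement = (
        (c.frac_neutral < c.frac_pos)
        & (c.frac_neutral < c.frac_neg)
        & (c.frac_neg < c.frac_pos)
        & (c.mean_abs_neg < c.mean_abs_pos)
    ).sum()
    out = {
        "n_dfes": n_total,
        "neutral_majority": int(c.neutral_majority.sum()),
        "negative_more_numerous": int(c.negative_more_numerous.sum()),
        "negative_larger": int(c.negative_larger.sum()),
        "joint_neutral_majority_negative_dominant": int(joint_strict),
        "joint_neutral_minority_positive_dominant": int(joint_complement),
        "expected_negative_larger": float(
            c.negative_larger.sum() + 0.5 * c.magnitude_tied.sum()
        ),
        "expected_negative_more_numerous": float(
            c.negative_more_numerous.sum() + 0.5 * c.fraction_tied.sum()
        ),
    }
    if "mc_neutral_majority" in c.columns:
        out.update(
            mc_neutral_majority=int(c.mc_neutral_majority.sum()),
            mc_negative_more_numerous=int(c.mc_negative_more_numerous.sum()),
            mc_negative_larger=int(c.mc_negative_larger.sum()),
        )
    return out
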