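"""Replicate ensembles, parameter sweeps, and downstream analyses.

Orchestrates the quantities the simulator is built to measure: the
*conducivity* of a DFE parameter set (fraction of replicate populations
whose fixed variant crosses the adaptation threshold), retention/loss of
the locus under structural deletion, fitness-trajectory summaries
(minimum mean fitness and its time), correlations between conducivity
and mutation-class structure, the shape of the pooled adaptive-value
increment (dA) distribution, and the rare-large-jump scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dfe import DFEParams, ParameterGrid, grid_classification_census
from .expression import collect_delta_A
from .population import ReplicateResult, SimConfig, run_replicate
from .io_utils import derive_rng

__all__ = [
    "run_ensemble",
    "conducivity",
    "trajectory_summary",
    "run_sweep",
    "loss_classification",
    "sweep_correlations",
    "fit_delta_A_shape",
    "TailFit",
    "trajectory_driver_correlations",
    "rare_jump_scenario",
]


def run_ensemble(
    dfe: DFEParams,
    config: SimConfig,
    n_replicates: int,
    seed_base: int,
    key: tuple[int, ...] = (),
    **replicate_kwargs,
) -> list[ReplicateResult]:
    """Run independent replicates with deterministically derived seeds.

    Replicate r uses the stream derived from ``(seed_base, *key, r)``, so
    partial runs match full runs replicate-for-replicate and results are
    order-stable.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    return [
        run_replicate(dfe, config, derive_rng(seed_base, *key, r), **replicate_kwargs)
        for r in range(n_replicates)
    ]


def conducivity(results: list[ReplicateResult]) -> tuple[float, bool]:
    """Fraction of replicates that crossed the threshold, and whether the
    parameter set counts as conducive (fraction >= 0.5)."""
    if not results:
        raise ValueError("need at least one replicate")
    frac = sum(r.crossed for r in results) / len(results)
    return frac, frac >= 0.5


def trajectory_summary(replicate: ReplicateResult) -> tuple[float, int]:
    """Minimum of the population-mean fitness trajectory and the earliest
    time-step at which it is attained."""
    return replicate.min_mean_fitness, replicate.time_of_min


def run_sweep(
    grid: ParameterGrid,
    config: SimConfig,
    n_replicates: int,
    seed_base: int,
    deletion_probs: tuple[float, ...] | None = None,
    track_expression: bool = False,
) -> pd.DataFrame:
    """Sweep every (DFE, d) pair of the grid; one aggregate row each.

    Per row: conducivity at the final step, ever-crossing conducivity
    (low regime: the fixed variant exceeded the threshold at any step),
    locus-loss fraction, extinction count, and replicate-averaged
    minimum mean fitness and time of minimum.  Deterministic given
    ``seed_base``: replicate r of DFE i at deletion index j uses the
    stream derived from (seed_base, regime, i, j, r).
    """
    if deletion_probs is None:
        deletion_probs = grid.deletion_probs
    regime_id = 0 if config.regime == "high" else 1
    rows = []
    for i, dfe in enumerate(grid.dfe_sets):
        for j, d in enumerate(deletion_probs):
            cfg = replace(config, N=grid.population_size, d=d)
            results = run_ensemble(
                dfe,
                cfg,
                n_replicates,
                seed_base,
                key=(regime_id, i, j),
                track_expression=track_expression,
            )
            frac, flag = conducivity(results)
            rows.append(
                {
                    "dfe_index": i,
                    "p": dfe.p,
                    "f": dfe.f,
                    "n": dfe.n,
                    "s": dfe.s,
                    "d": d,
                    "regime": config.regime,
                    "n_replicates": n_replicates,
                    "conducivity": frac,
                    "conducive": flag,
                    "conducivity_ever": sum(r.crossed_ever for r in results)
                    / len(results),
                    "loss_fraction": sum(not r.retained for r in results)
                    / len(results),
                    # loss among the replicates that crossed at some point:
                    # "subsequently lost" in the crossed-then-lost sense
                    "loss_fraction_crossed": (
                        sum(r.crossed_ever and not r.retained for r in results)
                        / max(1, sum(r.crossed_ever for r in results))
                    ),
                    "n_extinct": sum(r.extinct for r in results),
                    "mean_min_fitness": float(
                        np.mean([r.min_mean_fitness for r in results])
                    ),
                    "mean_time_of_min": float(
                        np.mean([r.time_of_min for r in results])
                    ),
                }
            )
    return pd.DataFrame(rows)


def loss_classification(
    sweep: pd.DataFrame, loss_cutoff: float = 0.95, cross_cutoff: float = 0.5
) -> pd.Series:
    """Classify sweep rows by crossing and subsequent locus loss.

    ``crossed-then-lost``: the threshold was crossed in more than
    ``cross_cutoff`` of replicates (at any time-step) but the locus was
    subsequently lost from more than ``loss_cutoff`` of them;
    ``retained-conducive``: crossed and mostly retained; ``not-crossed``
    otherwise.
    """
    crossed = sweep["conducivity_ever"] > cross_cutoff
    lost = sweep["loss_fraction"] > loss_cutoff
    out = pd.Series("not-crossed", index=sweep.index, name="loss_class")
    out[crossed & lost] = "crossed-then-lost"
    out[crossed & ~lost] = "retained-conducive"
    return out


def _pearson(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, pval = stats.pearsonr(x, y)
    return float(r), float(pval)


def sweep_correlations(
    sweep: pd.DataFrame, census: pd.DataFrame | None = None
) -> dict[str, tuple[float, float]]:
    """Pearson correlations (r, two-sided p) behind the sweep analyses.

    Correlates conducivity with the closed-form mutation-class fractions
    of each DFE, restricted-subset conducivity with the negative-class
    fraction for the "stringent" DFEs (negative effects both more
    numerous and larger), and the per-DFE mean minimum fitness with the
    mean time of minimum.  Undefined correlations (constant inputs) are
    reported as NaN.
    """
    out: dict[str, tuple[float, float]] = {}
    out["min_fitness_vs_time_of_min"] = _pearson(
        sweep["mean_min_fitness"], sweep["mean_time_of_min"]
    )
    if census is not None:
        merged = sweep.merge(
            census[
                ["dfe_index", "frac_pos", "frac_neutral", "frac_neg",
                 "negative_more_numerous", "negative_larger"]
            ],
            on="dfe_index",
        )
        for frac in ("frac_pos", "frac_neutral", "frac_neg"):
            out[f"conducivity_vs_{frac}"] = _pearson(
                merged["conducivity"], merged[frac]
            )
        stringent = merged[
            merged["negative_more_numerous"] & merged["negative_larger"]
        ]
        out["stringent_conducivity_vs_frac_neg"] = _pearson(
            stringent["conducivity"], stringent["frac_neg"]
        )
    return out


@dataclass(frozen=True)
class TailFit:
    """Maximum-likelihood tail fit of |dA| above a common threshold."""

    law: str  # "exponential" or "power-law"
    threshold: float
    n_tail: int
    exponential_rate: float
    powerlaw_exponent: float
    loglik_exponential: float
    loglik_powerlaw: float
    ks_exponential: float
    ks_powerlaw: float


def _tail_fits(tail: np.ndarray, x_min: float):
    """MLE and KS distance of both candidate laws on one tail sample."""
    m = tail.size
    shifted = tail - x_min
    rate = 1.0 / shifted.mean()
    logs = np.log(tail / x_min)
    alpha = 1.0 + m / logs.sum()

    sorted_tail = np.sort(tail)
    ecdf_hi = np.arange(1, m + 1) / m
    ecdf_lo = np.arange(0, m) / m
    cdf_exp = 1.0 - np.exp(-rate * (sorted_tail - x_min))
    cdf_pl = 1.0 - (sorted_tail / x_min) ** (1.0 - alpha)
    ks_exp = max(np.abs(cdf_exp - ecdf_hi).max(), np.abs(cdf_exp - ecdf_lo).max())
    ks_pl = max(np.abs(cdf_pl - ecdf_hi).max(), np.abs(cdf_pl - ecdf_lo).max())

    ll_exp = m * np.log(rate) - rate * shifted.sum()
    ll_pl = m * np.log((alpha - 1.0) / x_min) - alpha * logs.sum()
    return rate, alpha, ll_exp, ll_pl, ks_exp, ks_pl


def fit_delta_A_shape(
    delta_a: np.ndarray,
    min_samples: int = 1000,
    quantiles: np.ndarray | None = None,
) -> TailFit:
    """Decide whether adaptive-value gains are exponential or power-law.

    Fits the positive increments (the gains that drive adaptation; the
    loss side mirrors the deleterious mutation branch and mixing the two
    scales would masquerade as a heavy tail).  The threshold is selected
    automatically over candidate quantiles spanning the bulk of the
    distribution — the claim concerns the distribution's overall
    character, not an extreme-tail regime — keeping the threshold whose
    better-fitting law minimizes the Kolmogorov-Smirnov distance.  The
    winner at that threshold is the law with the higher log-likelihood
    (both laws have one free parameter on the identical sample, so no
    complexity penalty is needed).
    """
    x = np.asarray(delta_a, dtype=float)
    x = x[x > 0]
    if x.size < min_samples:
        raise ValueError(
            f"too few positive dA samples ({x.size} < {min_samples}) for a shape fit"
        )
    if quantiles is None:
        quantiles = np.array([0.02, 0.05, 0.10, 0.25, 0.50])

    best: TailFit | None = None
    best_ks = np.inf
    for q in quantiles:
        x_min = float(np.quantile(x, q))
        if x_min <= 0:
            continue
        tail = x[x >= x_min]
        if tail.size < 100:
            continue
        rate, alpha, ll_exp, ll_pl, ks_exp, ks_pl = _tail_fits(tail, x_min)
        ks = min(ks_exp, ks_pl)
        if ks < best_ks:
            best_ks = ks
            best = TailFit(
                law="exponential" if ll_exp >= ll_pl else "power-law",
                threshold=x_min,
                n_tail=int(tail.size),
                exponential_rate=float(rate),
                powerlaw_exponent=float(alpha),
                loglik_exponential=float(ll_exp),
                loglik_powerlaw=float(ll_pl),
                ks_exponential=float(ks_exp),
                ks_powerlaw=float(ks_pl),
            )
    if best is None:
        raise ValueError("no usable tail threshold found")
    return best


def trajectory_driver_correlations(
    replicate: ReplicateResult,
) -> tuple[float, float]:
    """Correlations of the mean-fitness trajectory with the mean-expression
    and mean-adaptive-value trajectories.

    The two coefficients place a replicate in a driver quadrant at zero
    thresholds: fitness change driven by expression (corr_E > 0 only),
    by adaptive value (corr_A > 0 only), or by both.  NaN for constant
    (or untracked) trajectories.
    """
    if replicate.mean_E is None or replicate.mean_A is None:
        raise ValueError("replicate was run without expression tracking")
    corr_E, _ = _pearson(replicate.mean_F, replicate.mean_E)
    corr_A, _ = _pearson(replicate.mean_F, replicate.mean_A)
    return corr_E, corr_A


#: Non-conducive DFE used by the rare-jump scenario.
RARE_JUMP_DFE = DFEParams(p=0.001, f=0.25, n=0.005, s=0.1)


def rare_jump_scenario(
    config: SimConfig,
    n_replicates: int,
    seed_base: int,
    jump_prob: float = 1e-4,
    jump_effect: float = 0.15,
) -> float:
    """Conducivity of a non-conducive DFE augmented with rare large jumps.

    With probability ``jump_prob`` a mutation's fitness effect is
    replaced by the fixed ``jump_effect`` (+0.15); the base DFE is
    (p=0.001, f=0.25, n=0.005, s=0.1).  High mutation-rate regime only.
    """
    if config.regime != "high":
        raise ValueError("the rare-jump scenario is defined for the high regime")
    cfg = replace(config, jump_prob=jump_prob, jump_effect=jump_effect)
    results = run_ensemble(
        RARE_JUMP_DFE, cfg, n_replicates, seed_base, key=(9,), track_expression=False
    )
    return conducivity(results)[0]
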