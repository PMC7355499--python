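"""Activation-order statistics.

Within each catheter loop, exactly one of the D = 5 bipolar pairs is
activated first (and one last) in every activation cycle, so first/last
events over T cycles follow a multinomial distribution with per-pair
probabilities ``p_{i,j}``.  This module estimates those probabilities
robustly:

1. binary first/last indicators per (loop, pair, activation);
2. nonparametric confidence bounds on each ``p_{i,j}`` from the profile
   empirical likelihood of the indicator mean (Owen's construction,
   χ²₁ calibration at level 1 − α);
3. a box-constrained multinomial maximum-likelihood estimate pooling M
   noise-perturbed resamples of the LAT table, solved exactly via the
   KKT water-filling form ``p_j = clip(c_j / λ, lb_j, ub_j)``;
4. a z-test of each estimated probability against the chance level 1/D:
   ``z = D·p*``, one-sided upper-tail normal p-value.

The test in (4) is deliberately simple — a probability at chance level
(p* = 1/D) maps to z = 1, p-value ≈ 0.16 — and its p-values are reported
rounded to two decimals with a floor of 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2, norm

from .activation import ActivationMatrix
from .geometry import INNER_PAIR_INDICES, OUTER_PAIR_INDICES, PAIRS_PER_LOOP

__all__ = [
    "IndicatorSample",
    "CountVector",
    "StatsConfig",
    "ProbabilityEstimate",
    "resample_lats",
    "compute_indicators",
    "count_first_last",
    "el_mean_interval",
    "el_probability_bounds",
    "multinomial_mle",
    "activation_pvalue",
    "reported_pvalue",
    "significant_pairs",
    "estimate_probabilities",
]

LOOPS = ("outer", "inner")
LOOP_PAIRS = {"inner": np.array(INNER_PAIR_INDICES), "outer": np.array(OUTER_PAIR_INDICES)}


@dataclass(frozen=True)
class StatsConfig:
    """Monte-Carlo and inference settings.

    ``n_resamples_M`` perturbed copies of the LAT table are drawn, each
    restricted to ``trials_T`` randomly selected activations with i.i.d.
    N(0, σ²) noise added; ``alpha`` is both the EL confidence level
    (1 − α) and the significance threshold of the activation test.
    """

    n_resamples_M: int = 100
    trials_T: int = 30
    alpha: float = 0.1
    lat_sd_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples_M < 1 or self.trials_T < 1:
            raise ValueError("M and T must be at least 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lat_sd_sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass(frozen=True)
class IndicatorSample:
    """Binary first/last indicators Z: per loop a (T, 5) matrix."""

    mode: str  # "first" | "last"
    indicators: dict  # loop -> (T, 5) 0/1 array, columns in ascending pair index

    def __post_init__(self) -> None:
        if self.mode not in ("first", "last"):
            raise ValueError("mode must be 'first' or 'last'")
        for loop, z in self.indicators.items():
            z = np.asarray(z)
            if z.ndim != 2 or z.shape[1] != PAIRS_PER_LOOP:
                raise ValueError(f"{loop}: indicators must be (T, {PAIRS_PER_LOOP})")
            if not np.array_equal(z.sum(axis=1), np.ones(z.shape[0])):
                raise ValueError(f"{loop}: exactly one pair must be indicated per activation")

    @property
    def n_activations(self) -> int:
        return next(iter(self.indicators.values())).shape[0]


@dataclass(frozen=True)
class CountVector:
    """First/last event counts n_{i,j} per loop; rows of counts sum to T."""

    counts: dict  # loop -> (5,) int array
    total_T: int

    def __post_init__(self) -> None:
        for loop, n in self.counts.items():
            if int(np.sum(n)) != self.total_T:
                raise ValueError(f"{loop}: counts sum to {np.sum(n)}, expected T = {self.total_T}")


@dataclass(frozen=True)
class ProbabilityEstimate:
    """Per-loop, per-pair probability estimates with EL bounds and p-values."""

    mode: str
    p_star: dict  # loop -> (5,)
    lb: dict
    ub: dict
    p_value: dict  # raw (un-floored) upper-tail p-values

    def pairs(self, loop: str) -> np.ndarray:
        return LOOP_PAIRS[loop]


def resample_lats(matrix: ActivationMatrix, config: StatsConfig) -> list[ActivationMatrix]:
    """M perturbed copies of the LAT table.

    Each copy keeps ``trials_T`` activations chosen uniformly without
    replacement and adds i.i.d. N(0, σ²) perturbations — the Monte-Carlo
    device that propagates LAT uncertainty into the order statistics.
    """
    if config.trials_T > matrix.n_activations:
        raise ValueError(
            f"requested T = {config.trials_T} activations but only {matrix.n_activations} are available"
        )
    rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.n_resamples_M):
        rows = np.sort(rng.choice(matrix.n_activations, size=config.trials_T, replace=False))
        sub = matrix.subset(rows)
        lat = sub.lat + rng.normal(0.0, config.lat_sd_sigma, size=sub.lat.shape)
        out.append(ActivationMatrix(lat, sub.activation_ids, sub.source_of_record))
    return out


def compute_indicators(matrix: ActivationMatrix, mode: str) -> IndicatorSample:
    """First (argmin) or last (argmax) activated pair per loop per cycle.

    Exact LAT ties break toward the smallest pair index.
    """
    if mode not in ("first", "last"):
        raise ValueError("mode must be 'first' or 'last'")
    indicators = {}
    for loop in LOOPS:
        block = matrix.loop_lat(loop)  # (T, 5), ascending pair index
        pick = np.argmin(block, axis=1) if mode == "first" else np.argmax(block, axis=1)
        z = np.zeros_like(block, dtype=int)
        z[np.arange(block.shape[0]), pick] = 1
        indicators[loop] = z
    return IndicatorSample(mode=mode, indicators=indicators)


def count_first_last(sample: IndicatorSample) -> CountVector:
    """n_{i,j} = Σ_t Z_{i,j}(t); per loop the counts sum to T."""
    counts = {loop: z.sum(axis=0) for loop, z in sample.indicators.items()}
    return CountVector(counts=counts, total_T=sample.n_activations)


def _owen_log_elr(z: np.ndarray, mu: float) -> float:
    """−2 log empirical-likelihood ratio for the mean of sample ``z`` at ``mu``.

    Profiles the weights via the 1-D dual: w_t ∝ 1 / (1 + λ(z_t − mu)) with
    λ solving Σ (z_t − mu)/(1 + λ(z_t − mu)) = 0 (bisection/Brent on the
    bracket enforcing positive weights).
    """
    z = np.asarray(z, dtype=float)
    zmin, zmax = z.min(), z.max()
    if not (zmin < mu < zmax):
        return np.inf

    def score(lam: float) -> float:
        return float(np.sum((z - mu) / (1.0 + lam * (z - mu))))

    # bracket keeps every weight strictly positive: 1 + lam (z - mu) >= 1e-10
    lo = -(1.0 - 1e-10) / (zmax - mu)
    hi = (1.0 - 1e-10) / (mu - zmin)
    lam = brentq(score, lo, hi, xtol=1e-14)
    return float(2.0 * np.sum(np.log1p(lam * (z - mu))))


def el_mean_interval(z: np.ndarray, alpha: float) -> tuple[float, float]:
    """Empirical-likelihood confidence interval for E[z] at level 1 − α.

    Bounds are the extreme weighted means achievable by weight vectors
    whose EL ratio statistic stays within the χ²₁ quantile; found by root
    search on the profile.  For all-zero (all-one) binary samples the
    interval is widened one-sidedly by the continuity limit
    1 − exp(−χ²/(2T)) rather than collapsing to a point.
    """
    z = np.asarray(z, dtype=float)
    T = len(z)
    if T < 2:
        raise ValueError("need at least two observations")
    q = chi2.ppf(1.0 - alpha, df=1)
    mean = float(z.mean())
    zmin, zmax = float(z.min()), float(z.max())
    edge = 1.0 - np.exp(-q / (2.0 * T))  # one-sided reach of a degenerate sample
    if zmin == zmax:  # degenerate: all observations equal
        if set(np.unique(z)) <= {0.0, 1.0}:
            return (0.0, min(edge, 1.0)) if mean == 0.0 else (max(1.0 - edge, 0.0), 1.0)
        return (mean, mean)
    if q <= 1e-12:
        return (mean, mean)

    def profile(mu: float) -> float:
        return _owen_log_elr(z, mu) - q

    span = zmax - zmin
    tiny = 1e-10 * span
    lb = brentq(profile, zmin + tiny, mean, xtol=1e-12) if profile(zmin + tiny) > 0 else zmin
    ub = brentq(profile, mean, zmax - tiny, xtol=1e-12) if profile(zmax - tiny) > 0 else zmax
    return float(lb), float(ub)


def el_probability_bounds(sample: IndicatorSample, alpha: float = 0.1) -> dict:
    """Robust per-pair probability boundaries [lb, ub] at level 1 − α.

    Each pair's bound profiles its own binary indicator vector with a
    1-degree-of-freedom χ² calibration; bounds are clipped to [0, 1].
    """
    out = {}
    for loop, z in sample.indicators.items():
        lbs, ubs = np.empty(PAIRS_PER_LOOP), np.empty(PAIRS_PER_LOOP)
        for j in range(PAIRS_PER_LOOP):
            lb, ub = el_mean_interval(z[:, j], alpha)
            lbs[j], ubs[j] = np.clip(lb, 0.0, 1.0), np.clip(ub, 0.0, 1.0)
        out[loop] = (lbs, ubs)
    return out


def multinomial_mle(counts: list[CountVector], bounds: dict | None = None) -> dict:
    """Box-constrained multinomial MLE, counts pooled over the M resamples.

    Maximizes Σ_l Σ_j n_{j,l} log p_j on the simplex intersected with the
    per-pair box [lb_j, ub_j].  The KKT stationarity condition gives
    ``p_j = clip(c_j/λ, lb_j, ub_j)`` with ``c_j`` the pooled count; the
    scalar λ is found by Brent's method so the probabilities sum to one.
    Without an active box this reduces to the closed form c_j / Σ c.
    """
    if not counts:
        raise ValueError("need at least one count vector")
    loops = list(counts[0].counts)
    p_star = {}
    for loop in loops:
        c = np.sum([cv.counts[loop] for cv in counts], axis=0).astype(float)
        if bounds is None:
            lb, ub = np.zeros(len(c)), np.ones(len(c))
        else:
            lb, ub = np.asarray(bounds[loop][0], float), np.asarray(bounds[loop][1], float)
        if lb.sum() > 1.0 + 1e-12:
            raise ValueError(f"{loop}: infeasible box, lower bounds sum to {lb.sum():.4f} > 1")
        if ub.sum() < 1.0 - 1e-12:
            raise ValueError(f"{loop}: infeasible box, upper bounds sum to {ub.sum():.4f} < 1")
        total = c.sum()
        if total <= 0:
            raise ValueError(f"{loop}: no events counted")
        free = c / total
        if np.all((free >= lb - 1e-15) & (free <= ub + 1e-15)):
            p = np.clip(free, lb, ub)
        else:

            def simplex_gap(lam: float) -> float:
                return float(np.sum(np.clip(c / lam, lb, ub)) - 1.0)

            lam_lo, lam_hi = 1e-9, max(total, 1.0)
            while simplex_gap(lam_hi) > 0:  # extend until Σp < 1
                lam_hi *= 2.0
            lam = brentq(simplex_gap, lam_lo, lam_hi, xtol=1e-14)
            p = np.clip(c / lam, lb, ub)
        p_star[loop] = p / p.sum()  # remove residual root-finding slack
    return p_star


def activation_pvalue(p_star: float, D: int = PAIRS_PER_LOOP) -> float:
    """Upper-tail normal p-value of the chance-ratio statistic z = D·p*.

    The estimated probability is compared against the uniform chance level
    1/D; a pair never activated first (p* = 0) yields z = 0 and p = 0.5.
    """
    if not 0.0 <= p_star <= 1.0:
        raise ValueError("p_star must lie in [0, 1]")
    if D < 2:
        raise ValueError("need at least two pairs per loop")
    return float(norm.sf(p_star * D))


def reported_pvalue(raw: float) -> float:
    """Table-formatting convention: round to 2 decimals, floor at 0.01."""
    return max(round(raw, 2), 0.01)


def significant_pairs(estimate: ProbabilityEstimate, alpha: float = 0.1) -> dict:
    """Per loop, pair indices with p-value < α, ordered by descending p*."""
    out = {}
    for loop in estimate.p_star:
        pairs = estimate.pairs(loop)
        p, pv = estimate.p_star[loop], estimate.p_value[loop]
        sig = np.nonzero(pv < alpha)[0]
        order = sig[np.lexsort((pairs[sig], -p[sig]))]
        out[loop] = [int(pairs[k]) for k in order]
    return out


def estimate_probabilities(matrix: ActivationMatrix, config: StatsConfig, mode: str) -> ProbabilityEstimate:
    """Full inference chain for one mode (first or last).

    EL bounds come from the observed (unperturbed) indicator sample; the
    MLE pools first/last counts over the M noise-perturbed resamples and
    is constrained to the EL box.
    """
    observed = compute_indicators(matrix, mode)
    bounds = el_probability_bounds(observed, config.alpha)
    resamples = resample_lats(matrix, config)
    counts = [count_first_last(compute_indicators(m, mode)) for m in resamples]
    p_star = multinomial_mle(counts, bounds)
    p_value = {loop: np.array([activation_pvalue(p) for p in p_star[loop]]) for loop in p_star}
    return ProbabilityEstimate(
        mode=mode,
        p_star=p_star,
        lb={loop: bounds[loop][0] for loop in bounds},
        ub={loop: bounds[loop][1] for loop in bounds},
        p_value=p_value,
    )
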