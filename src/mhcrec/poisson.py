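"""Poisson fit to the recombination spectrum and per-generation rate algebra.

Under the rare-event model — a constant per-meiosis crossover probability,
no interference between events, and neutrality of recombinants — the number
of crossovers accumulated per transmitted lineage over the post-founding
period is Poisson.  The intensity λ is therefore estimated as the mean of
the observed per-haplotype switch counts, its Wald confidence interval
follows from the asymptotic normality of the MLE, and dividing λ̂ by the
number of elapsed generations gives the per-generation rate.  Crossovers in
founder-homozygous carriers leave no trace, so the detectable rate is
deflated by the heterozygote frequency; dividing by that frequency recovers
the total rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .haplotypes import RecombinationCountVector

__all__ = [
    "PoissonFit",
    "GofResult",
    "MergedBin",
    "RateEstimate",
    "fit_lambda",
    "lambda_ci",
    "expected_counts",
    "merge_bins",
    "gof_test",
    "per_generation_rate",
    "homozygosity_correction",
    "rate_estimate",
]


@dataclass(frozen=True)
class PoissonFit:
    lambda_hat: float
    n: int
    ci_low: float
    ci_high: float
    alpha: float

    @classmethod
    def from_spectrum(
        cls, counts: RecombinationCountVector, alpha: float = 0.05
    ) -> "PoissonFit":
        lam = fit_lambda(counts)
        low, high = lambda_ci(lam, counts.n, alpha)
        return cls(lambda_hat=lam, n=counts.n, ci_low=low, ci_high=high, alpha=alpha)


@dataclass(frozen=True)
class MergedBin:
    """One goodness-of-fit cell: counts k in [k_lo, k_hi), open-ended if k_hi is None."""

    k_lo: int
    k_hi: int | None
    observed: float
    expected: float


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p_value: float
    merged_bins: tuple[MergedBin, ...]
    lambda_used: float


@dataclass(frozen=True)
class RateEstimate:
    """Per-generation recombination rate for one generation-time scenario."""

    detectable: float
    corrected: float
    generations: float
    generation_time: float
    elapsed_years: float
    heterozygote_frequency: float


def fit_lambda(counts: RecombinationCountVector) -> float:
    """Maximum-likelihood Poisson intensity: the spectrum mean Σ k·n_k / n."""
    arr = counts.as_array()
    return float(np.dot(np.arange(len(arr)), arr) / counts.n)


def lambda_ci(lambda_hat: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wald interval λ̂ ∓ u_{α/2}·sqrt(λ̂/n), floored at zero.

    The Fisher information of a Poisson mean is n/λ, so the asymptotic
    standard error of λ̂ is sqrt(λ̂/n).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if lambda_hat < 0:
        raise ValueError("lambda must be non-negative")
    u = stats.norm.ppf(1 - alpha / 2)
    half = u * np.sqrt(lambda_hat / n)
    return (max(0.0, float(lambda_hat - half)), float(lambda_hat + half))


def expected_counts(
    lam: float, n: int, k_max: int, include_tail: bool = False
) -> np.ndarray:
    """Expected spectrum n·P(K = k) for k = 0..k_max under Poisson(λ).

    With ``include_tail`` the last entry becomes the open-ended bin
    n·P(K ≥ k_max), so the vector sums exactly to n.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if n <= 0:
        raise ValueError("n must be positive")
    k = np.arange(k_max + 1)
    exp = n * stats.poisson.pmf(k, lam)
    if include_tail:
        exp[-1] = n * stats.poisson.sf(k_max - 1, lam)
    return exp


def merge_bins(
    observed: np.ndarray | list[float],
    expected: np.ndarray | list[float],
    min_expected: float = 5.0,
) -> list[MergedBin]:
    """Pool spectrum cells until every expected count reaches ``min_expected``.

    Pooling proceeds from the upper tail downward — sparse high-k cells
    collapse into an open-ended final bin — and continues through interior
    cells if any remain below the threshold.  Totals are preserved.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have the same length")
    if exp.sum() < min_expected:
        raise ValueError("total expected count below min_expected: no valid bin")
    bins: list[MergedBin] = []
    hi: int | None = None  # open-ended top bin
    acc_o = acc_e = 0.0
    for k in range(len(obs) - 1, -1, -1):
        acc_o += obs[k]
        acc_e += exp[k]
        if acc_e >= min_expected:
            bins.append(MergedBin(k, hi, acc_o, acc_e))
            hi = k
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:
        # leftover low-k remainder below threshold: fold into the lowest bin
        low = bins.pop()
        bins.append(
            MergedBin(0, low.k_hi, low.observed + acc_o, low.expected + acc_e)
        )
    bins.reverse()
    return bins


def gof_test(
    counts: RecombinationCountVector,
    lam: float | None = None,
    min_expected: float = 5.0,
) -> GofResult:
    """Pearson chi-square goodness of fit of the spectrum to Poisson(λ).

    λ defaults to the MLE of the spectrum itself.  The expected vector closes
    with the open tail n·P(K ≥ k_max) so observed and expected totals agree;
    cells are pooled to ``min_expected``.  df = bins − 2: one for the usual
    constraint, one for the estimated intensity (kept also when λ is
    supplied, so fixed-λ runs are comparable with fitted ones).
    """
    if lam is None:
        lam = fit_lambda(counts)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    obs = counts.as_array()
    exp = expected_counts(lam, counts.n, counts.k_max, include_tail=True)
    bins = merge_bins(obs, exp, min_expected)
    df = len(bins) - 2
    if df < 1:
        raise ValueError(
            "spectrum too coarse after pooling: fewer than three bins leave "
            "no degree of freedom for the test"
        )
    statistic = float(
        sum((b.observed - b.expected) ** 2 / b.expected for b in bins)
    )
    p = float(stats.chi2.sf(statistic, df))
    return GofResult(
        statistic=statistic,
        df=df,
        p_value=p,
        merged_bins=tuple(bins),
        lambda_used=float(lam),
    )


def per_generation_rate(
    lambda_hat: float, elapsed_years: float, generation_time: float
) -> float:
    """Convert the cumulative intensity to a per-generation rate λ̂/G, G = years/gen-time."""
    if elapsed_years <= 0 or generation_time <= 0:
        raise ValueError("elapsed time and generation time must be positive")
    if lambda_hat < 0:
        raise ValueError("lambda must be non-negative")
    return lambda_hat / (elapsed_years / generation_time)


def homozygosity_correction(rate: float, heterozygote_frequency: float) -> float:
    """Total rate from the detectable rate: divide by the heterozygote frequency."""
    if not 0 < heterozygote_frequency <= 1:
        raise ValueError("heterozygote frequency must lie in (0, 1]")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return rate / heterozygote_frequency


def rate_estimate(
    lambda_hat: float,
    elapsed_years: float,
    generation_time: float,
    heterozygote_frequency: float = 0.90,
) -> RateEstimate:
    """Bundle the detectable and homozygosity-corrected per-generation rates."""
    detectable = per_generation_rate(lambda_hat, elapsed_years, generation_time)
    corrected = homozygosity_correction(detectable, heterozygote_frequency)
    return RateEstimate(
        detectable=detectable,
        corrected=corrected,
        generations=elapsed_years / generation_time,
        generation_time=generation_time,
        elapsed_years=elapsed_years,
        heterozygote_frequency=heterozygote_frequency,
    )
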