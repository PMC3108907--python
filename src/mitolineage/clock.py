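"""Waiting-time divergence dating from a distribution of substitution rates.

Given per-species neutral substitution rates r_i (substitutions per
third-codon site per year) and a number of third-codon sites L, the
expected waiting time until one synonymous substitution is observed in a
lineage is t_i = 1 / (r_i * L) years.  A lognormal is fitted to the
waiting times by maximum likelihood on the log scale; the point estimate
of the waiting time is the lognormal mode exp(mu - sigma^2) and the 95%
interval is the fitted 0.025/0.975 quantiles exp(mu + z * sigma).  A
divergence date for lineages separated by k synonymous substitutions is
k times the modal waiting time, with the interval scaled likewise.

The waiting times scale exactly as 1/L, so refitting for a different
site count just rescales mode and quantiles by L1/L2: sequencing the
whole mitogenome instead of one gene divides the dating uncertainty by
the ratio of usable third-codon sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RateDistribution",
    "WaitingTimeFit",
    "TmrcaEstimate",
    "read_rate_table",
    "waiting_times",
    "fit_lognormal",
    "mode_and_ci",
    "fit_waiting_times",
    "lognormal_from_ci",
    "tmrca",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass
class RateDistribution:
    """Per-species substitution rates (substitutions/site/year)."""

    rates: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates <= 0):
            raise ValueError("rates must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.rates)


@dataclass
class WaitingTimeFit:
    sites: int  # L
    mu: float  # mean of ln t
    sigma: float  # sd of ln t (ML, denominator n)
    degenerate: bool = False  # sigma == 0

    @property
    def mode(self) -> float:
        return float(np.exp(self.mu - self.sigma**2))

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    @property
    def q025(self) -> float:
        return float(np.exp(self.mu - _Z975 * self.sigma))

    @property
    def q975(self) -> float:
        return float(np.exp(self.mu + _Z975 * self.sigma))

    def rescaled(self, new_sites: int) -> "WaitingTimeFit":
        """Exact refit for a different site count (t scales as 1/L)."""
        return WaitingTimeFit(
            sites=new_sites,
            mu=self.mu + np.log(self.sites / new_sites),
            sigma=self.sigma,
            degenerate=self.degenerate,
        )


@dataclass
class TmrcaEstimate:
    k: float  # mean synonymous differences from the common ancestor
    years: float
    low: float
    high: float


def read_rate_table(path: str | Path) -> RateDistribution:
    """Read a species/rate TSV (columns: species, rate)."""
    df = pd.read_csv(path, sep="\t")
    if "rate" not in df.columns:
        raise ValueError("rate table needs a 'rate' column")
    return RateDistribution(df["rate"].to_numpy(), source=str(path))


def waiting_times(rates: RateDistribution, sites: int) -> np.ndarray:
    """Years until one substitution is expected over ``sites`` positions."""
    if sites < 1:
        raise ValueError("site count must be >= 1")
    return 1.0 / (rates.rates * sites)


def fit_lognormal(times: np.ndarray) -> tuple[float, float]:
    """ML lognormal parameters (mu, sigma) of positive waiting times."""
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise ValueError("need >= 2 waiting times")
    if np.any(times <= 0):
        raise ValueError("waiting times must be positive")
    logs = np.log(times)
    return float(logs.mean()), float(logs.std(ddof=0))


def mode_and_ci(fit: WaitingTimeFit) -> tuple[float, float, float]:
    """(mode, 2.5% quantile, 97.5% quantile) of the fitted lognormal."""
    return fit.mode, fit.q025, fit.q975


def fit_waiting_times(rates: RateDistribution, sites: int) -> WaitingTimeFit:
    """Rescale rates to waiting times for ``sites`` positions and fit."""
    t = waiting_times(rates, sites)
    mu, sigma = fit_lognormal(t)
    return WaitingTimeFit(sites=sites, mu=mu, sigma=sigma, degenerate=sigma == 0.0)


def lognormal_from_ci(q025: float, q975: float, sites: int = 0) -> WaitingTimeFit:
    """Back-solve (mu, sigma) from printed 95% interval endpoints.

    Inverts q = exp(mu + z*sigma): mu is the midpoint of the log
    endpoints and sigma their half-spread over z_0.975.  Useful for
    checking a reported mode against its reported interval.
    """
    if not 0 < q025 < q975:
        raise ValueError("need 0 < q025 < q975")
    lo, hi = np.log(q025), np.log(q975)
    return WaitingTimeFit(
        sites=sites, mu=float((lo + hi) / 2), sigma=float((hi - lo) / (2 * _Z975))
    )


def tmrca(k: float, fit: WaitingTimeFit) -> TmrcaEstimate:
    """Divergence date for k synonymous substitutions from the ancestor."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return TmrcaEstimate(k=k, years=k * fit.mode, low=k * fit.q025, high=k * fit.q975)
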