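"""Between-scales interval significance: histograms and binomial tail tests.

The analysis pools note positions across many scales (balanced so no
society dominates), bins them, and asks per bin whether the observed count
k_i is compatible with a null model probability p_i via the binomial tail

    q_i = P(K >= k_i)   if k_i / n > p_i   (interval over-represented)
    q_i = P(K <= k_i)   otherwise          (interval under-represented)

with K ~ Binomial(n, p_i) and a Bonferroni-adjusted threshold over bins.
p_i comes either from integrating a fitted lognormal over the bin, or from
the mean bin proportion across many shuffled/resampled alternative corpora.

Bins are *centered* on integer multiples of the bin width so canonical
intervals (1200, 700, 200 cents) sit at bin centers rather than on edges.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Corpus
from .errors import DomainError
from .nulls import (
    Layout,
    LognormParams,
    fit_lognormal,
    resample_scales,
    shuffle_corpus,
    step_pool,
)

MODELS = ("lognorm", "shuffle", "resample")


@dataclass
class BetweenConfig:
    """Parameters of the between-scales significance analysis."""

    bin_width: float = 30.0
    value_range: tuple[float, float] = (0.0, 2700.0)
    max_per_society: int = 5
    n_resamples: int = 1000
    n_model_sets: int = 1000
    n_bootstrap: int = 1000
    alpha: float = 0.05


@dataclass
class SignificanceProfile:
    """Per-bin observed counts, model probabilities and tail p-values."""

    bin_centers: np.ndarray
    k: np.ndarray
    n: int
    p: np.ndarray
    q_tail: np.ndarray
    direction: np.ndarray  # "more" / "less" per bin
    alpha_bonferroni: float
    ci_low: np.ndarray
    ci_high: np.ndarray
    model: str = "lognorm"

    def significant(self, direction: str | None = None) -> np.ndarray:
        """Bin centers significant at the Bonferroni-adjusted threshold."""
        mask = self.q_tail < self.alpha_bonferroni
        if direction is not None:
            mask &= self.direction == direction
        return self.bin_centers[mask]

    def bin_of(self, value: float) -> int:
        """Index of the bin whose interval contains ``value``."""
        idx = int(np.round(value / (self.bin_centers[1] - self.bin_centers[0])))
        lo = int(np.round(self.bin_centers[0] / (self.bin_centers[1] - self.bin_centers[0])))
        return idx - lo

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "k": self.k,
                "n": self.n,
                "p": self.p,
                "q_tail": self.q_tail,
                "direction": self.direction,
                "significant_bonferroni": self.q_tail < self.alpha_bonferroni,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def balanced_subsample(
    corpus: Corpus, max_per_society: int, seed: int | np.random.Generator
) -> Corpus:
    """Uniform random subset with at most ``max_per_society`` scales per society.

    Societies with fewer records keep all of them.
    """
    if max_per_society < 1:
        raise DomainError("max_per_society must be >= 1")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for society in corpus.society_index:
        idx = corpus.society_index[society]
        if len(idx) <= max_per_society:
            keep.extend(idx)
        else:
            keep.extend(rng.choice(idx, size=max_per_society, replace=False))
    return corpus.subset(sorted(keep))


def bin_centers_for(bin_width: float, value_range: tuple[float, float]) -> np.ndarray:
    """Bin centers: integer multiples of ``bin_width`` inside ``value_range``."""
    lo, hi = value_range
    first = int(np.ceil(lo / bin_width))
    last = int(np.floor(hi / bin_width))
    return np.arange(first, last + 1) * bin_width


def interval_histogram(
    values: Sequence[float],
    bin_width: float,
    value_range: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with bins centered on multiples of ``bin_width``.

    Bin edges are half-open ``[center - w/2, center + w/2)``; counts sum to
    the number of values whose bin center falls inside ``value_range``.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    centers = bin_centers_for(bin_width, value_range)
    values = np.asarray(values, dtype=float)
    counts = np.zeros(centers.size, dtype=np.int64)
    if values.size:
        idx = np.floor(values / bin_width + 0.5).astype(np.int64)
        lo = int(np.round(centers[0] / bin_width))
        idx -= lo
        valid = (idx >= 0) & (idx < centers.size)
        counts = np.bincount(idx[valid], minlength=centers.size)
    return centers, counts


def lognorm_bin_probabilities(
    params: LognormParams, centers: np.ndarray, bin_width: float
) -> np.ndarray:
    """Integral of lnN(mu, sigma^2) over each bin ``[c - w/2, c + w/2)``."""
    if params.sigma == 0:
        raise DomainError("degenerate lognormal (sigma == 0)")
    lo = np.maximum(np.asarray(centers) - bin_width / 2.0, 0.0)
    hi = np.asarray(centers) + bin_width / 2.0

    def cdf(x):
        out = np.zeros_like(x, dtype=float)
        pos = x > 0
        out[pos] = stats.norm.cdf((np.log(x[pos]) - params.mu) / params.sigma)
        return out

    return cdf(hi) - cdf(lo)


def empirical_bin_probabilities(
    model: str,
    corpus: Corpus,
    centers: np.ndarray,
    bin_width: float,
    value_range: tuple[float, float],
    n_sets: int,
    seed: int | np.random.Generator,
    max_per_society: int | None = None,
) -> np.ndarray:
    """Mean per-bin note proportion across alternative corpora.

    Each alternative corpus is generated by the shuffle or resample model
    (optionally balanced by society like the observed data), histogrammed,
    and normalised by its own in-range note count.
    """
    if model not in ("shuffle", "resample"):
        raise DomainError(f"unknown empirical model {model!r}")
    if n_sets < 1:
        raise DomainError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    pool = step_pool(corpus) if model == "resample" else None
    layout = Layout.from_corpus(corpus)
    acc = np.zeros(centers.size)
    used = 0
    for _ in range(n_sets):
        if model == "shuffle":
            alt = shuffle_corpus(corpus, rng)
        else:
            alt = resample_scales(pool, layout, rng)
        if max_per_society is not None:
            alt = balanced_subsample(alt, max_per_society, rng)
        _, counts = interval_histogram(
            alt.all_notes(), bin_width, value_range
        )
        total = counts.sum()
        if total:
            acc += counts / total
            used += 1
    if used == 0:
        raise DomainError("no alternative corpus produced in-range notes")
    return acc / used


def binomial_tail_test(k: int, n: int, p: float) -> tuple[float, str]:
    """One-sided binomial tail probability and its direction.

    Upper tail P(K >= k) when the observed proportion exceeds p ("more"),
    else lower tail P(K <= k) ("less").
    """
    if not 0 <= k <= n:
        raise DomainError("need 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise DomainError("p must be a probability")
    if n > 0 and k / n > p:
        return float(stats.binom.sf(k - 1, n, p)), "more"
    return float(stats.binom.cdf(k, n, p)), "less"


def significance_profile(
    corpus: Corpus,
    model: str = "lognorm",
    config: BetweenConfig | None = None,
    seed: int | None = None,
) -> SignificanceProfile:
    """Full between-scales significance analysis against one null model.

    Procedure: draw ``n_resamples`` society-balanced subsamples, average
    their note histograms (rounded to integer counts); compute per-bin model
    probabilities (lognormal integral fitted to the pooled balanced notes,
    or mean proportions over shuffled/resampled corpora); run the binomial
    tail test per bin with a Bonferroni threshold alpha / n_bins; bootstrap
    95% percentile intervals of the observed bin proportions by resampling
    scales with replacement.
    """
    if model not in MODELS:
        raise DomainError(f"unknown model {model!r}")
    if len(corpus) == 0:
        raise DomainError("corpus is empty")
    cfg = config or BetweenConfig()
    ss = np.random.SeedSequence(seed)
    rng_sub, rng_model, rng_boot = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    centers = bin_centers_for(cfg.bin_width, cfg.value_range)
    acc = np.zeros(centers.size)
    pooled_notes: list[np.ndarray] = []
    for _ in range(cfg.n_resamples):
        sub = balanced_subsample(corpus, cfg.max_per_society, rng_sub)
        notes = sub.all_notes()
        pooled_notes.append(notes)
        _, counts = interval_histogram(notes, cfg.bin_width, cfg.value_range)
        acc += counts
    k = np.rint(acc / cfg.n_resamples).astype(np.int64)
    n = int(k.sum())

    if model == "lognorm":
        params = fit_lognormal(np.concatenate(pooled_notes))
        p = lognorm_bin_probabilities(params, centers, cfg.bin_width)
    else:
        p = empirical_bin_probabilities(
            model,
            corpus,
            centers,
            cfg.bin_width,
            cfg.value_range,
            cfg.n_model_sets,
            rng_model,
            max_per_society=cfg.max_per_society,
        )

    q = np.empty(centers.size)
    direction = np.empty(centers.size, dtype=object)
    for i in range(centers.size):
        q[i], direction[i] = binomial_tail_test(int(k[i]), n, float(p[i]))

    # bootstrap percentile CI of the observed bin proportions
    boot = np.empty((cfg.n_bootstrap, centers.size))
    indices = np.arange(len(corpus))
    for b in range(cfg.n_bootstrap):
        pick = rng_boot.choice(indices, size=len(corpus), replace=True)
        bc = Corpus(
            records=[
                corpus.records[i].with_notes(
                    corpus.records[i].notes, scale_id=f"b{b}_{j}"
                )
                for j, i in enumerate(pick)
            ]
        )
        sub = balanced_subsample(bc, cfg.max_per_society, rng_boot)
        _, counts = interval_histogram(
            sub.all_notes(), cfg.bin_width, cfg.value_range
        )
        total = counts.sum()
        boot[b] = counts / total if total else 0.0
    ci_low = np.percentile(boot, 2.5, axis=0)
    ci_high = np.percentile(boot, 97.5, axis=0)

    return SignificanceProfile(
        bin_centers=centers,
        k=k,
        n=n,
        p=p,
        q_tail=q,
        direction=direction.astype(str),
        alpha_bonferroni=cfg.alpha / centers.size,
        ci_low=ci_low,
        ci_high=ci_high,
        model=model,
    )
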