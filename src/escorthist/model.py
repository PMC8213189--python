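"""Fixed-shift maximum-likelihood estimation of an ensemble histogram.

The fixed-shift model assumes every image in an ensemble samples the same
underlying intensity distribution up to an image-specific additive shift of
its log-odds.  With the reference bin fixed at g = 0, an image's histogram
p_g enters through the logit transform

    rho_g = ln p_g - ln p_0            (over the support, p_g > 0)

and image i is allowed rho_g -> rho_g + b_i for an arbitrary constant b_i,
absorbing image-to-image staining-intensity variation.  Maximising the
ensemble likelihood over the common profile and the shifts yields the
closed-form estimate

    rho_hat_g = ln( d_g / (N_T - d_0) )    for g >= 1 with d_g > 0,

where d_g is the pooled count of intensity g over the ensemble and N_T the
pooled total pixel count — the pooled counts are the sufficient statistic.
By construction sum_g exp(rho_hat_g) = 1 over the estimated support.

A probability histogram is reconstructed by setting p_hat_0 = d_0 / N_T and
p_hat_g = (1 - p_hat_0) exp(rho_hat_g); this is the unique reconstruction
consistent with the estimate that sums to one, and it coincides with the
pooled relative frequencies d_g / N_T.

`FixedShiftModel` / `FixedShiftResults` wrap these operations in the usual
model-object idiom: build the model from per-image channel tallies, call
``fit()``, and read the estimate, its descriptors and ``summary()`` off the
results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .histogram import (
    N_BINS,
    Channel,
    ChannelCounts,
    CumulativeDistribution,
    ProbabilityHistogram,
    cumulative,
    summarize,
)

if TYPE_CHECKING:  # pragma: no cover
    from .compare import EscortParameters, GroupComparisonResult

__all__ = [
    "PooledCounts",
    "LogOddsVector",
    "pool_counts",
    "logit_transform",
    "mle_log_odds",
    "mle_histogram",
    "FixedShiftModel",
    "FixedShiftResults",
]


@dataclass(frozen=True)
class PooledCounts:
    """Ensemble-pooled intensity tallies — the model's sufficient statistic."""

    d: np.ndarray
    n_images: int
    channel: Channel = Channel.GRAY

    def __post_init__(self) -> None:
        d = np.asarray(self.d)
        if d.shape != (N_BINS,):
            raise ValueError(f"pooled counts must have shape (256,), got {d.shape}")
        if np.any(d < 0):
            raise ValueError("pooled counts must be non-negative")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        object.__setattr__(self, "d", d.astype(np.int64))

    @property
    def n_total(self) -> int:
        """N_T, the total pixel count across the ensemble."""
        return int(self.d.sum())


@dataclass(frozen=True)
class LogOddsVector:
    """Log-odds rho_g against the reference bin g = 0, on a stated support.

    ``bins`` holds the intensities g >= 1 at which rho is defined (the
    support excluding the reference bin); ``rho`` the matching values.
    """

    bins: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        bins = np.asarray(self.bins, dtype=np.int64)
        rho = np.asarray(self.rho, dtype=float)
        if bins.shape != rho.shape:
            raise ValueError("bins and rho must have matching shapes")
        if bins.size and (bins.min() < 1 or bins.max() > 255):
            raise ValueError("log-odds bins must lie in 1..255")
        if not np.all(np.isfinite(rho)):
            raise ValueError("log-odds must be finite on their support")
        object.__setattr__(self, "bins", bins)
        object.__setattr__(self, "rho", rho)

    def as_dict(self) -> dict[int, float]:
        return {int(g): float(r) for g, r in zip(self.bins, self.rho)}


def pool_counts(ensemble: Sequence[ChannelCounts]) -> PooledCounts:
    """Sum per-image tallies into pooled counts d_g with total N_T."""
    if len(ensemble) == 0:
        raise ValueError("cannot pool an empty ensemble")
    channels = {c.channel for c in ensemble}
    if len(channels) > 1:
        raise ValueError(f"cannot pool mixed channels: {sorted(c.value for c in channels)}")
    d = np.sum([c.counts for c in ensemble], axis=0)
    return PooledCounts(d=d, n_images=len(ensemble), channel=ensemble[0].channel)


def logit_transform(hist: ProbabilityHistogram) -> LogOddsVector:
    """rho_g = ln p_g - ln p_0 on the support, zero-mass bins omitted."""
    p = hist.probs
    if p[0] <= 0:
        raise ValueError("reference bin g=0 has zero probability; logit undefined")
    bins = np.flatnonzero(p[1:] > 0) + 1
    rho = np.log(p[bins]) - np.log(p[0])
    return LogOddsVector(bins=bins, rho=rho)


def mle_log_odds(pooled: PooledCounts) -> LogOddsVector:
    """Closed-form fixed-shift MLE rho_hat_g = ln(d_g / (N_T - d_0))."""
    d = pooled.d
    n_total = pooled.n_total
    denom = n_total - int(d[0])
    if denom <= 0:
        raise ValueError(
            "degenerate ensemble: every pixel has intensity 0 (N_T == d_0)"
        )
    bins = np.flatnonzero(d[1:] > 0) + 1
    rho = np.log(d[bins]) - np.log(denom)
    return LogOddsVector(bins=bins, rho=rho)


def mle_histogram(pooled: PooledCounts) -> ProbabilityHistogram:
    """Probability reconstruction of the MLE.

    p_hat_0 = d_0 / N_T and p_hat_g = (1 - p_hat_0) exp(rho_hat_g), which
    equals the pooled relative frequency d_g / N_T at every bin.
    """
    log_odds = mle_log_odds(pooled)
    n_total = pooled.n_total
    p0 = pooled.d[0] / n_total
    if pooled.d[0] == 0:
        warnings.warn(
            "reference bin g=0 absent from the ensemble; reconstruction "
            "proceeds with bin 0 outside the support",
            stacklevel=2,
        )
    probs = np.zeros(N_BINS)
    probs[0] = p0
    probs[log_odds.bins] = (1.0 - p0) * np.exp(log_odds.rho)
    return ProbabilityHistogram(probs=probs)


class FixedShiftModel:
    """Fixed-shift ensemble model over per-image channel tallies.

    Parameters
    ----------
    ensemble : sequence of ChannelCounts
        Per-image intensity tallies, all for the same channel.

    Examples
    --------
    >>> model = FixedShiftModel(counts_list)      # doctest: +SKIP
    >>> res = model.fit()                         # doctest: +SKIP
    >>> res.histogram.probs.sum()                 # doctest: +SKIP
    1.0
    """

    def __init__(self, ensemble: Sequence[ChannelCounts]):
        self.ensemble = list(ensemble)
        self.pooled = pool_counts(self.ensemble)

    @classmethod
    def from_images(
        cls, images, channel: Channel, weights=None
    ) -> "FixedShiftModel":
        """Build the model directly from decoded :class:`ImageArray` objects."""
        from .io import DEFAULT_GRAY_WEIGHTS, image_channel_counts

        w = DEFAULT_GRAY_WEIGHTS if weights is None else weights
        counts = [image_channel_counts(img, channel, weights=w) for img in images]
        return cls(counts)

    def fit(self) -> "FixedShiftResults":
        log_odds = mle_log_odds(self.pooled)
        hist = mle_histogram(self.pooled)
        return FixedShiftResults(self, log_odds, hist)


class FixedShiftResults:
    """Fitted fixed-shift estimate with its descriptors.

    Attributes
    ----------
    log_odds : LogOddsVector
        The MLE profile rho_hat.
    histogram : ProbabilityHistogram
        The reconstructed probability histogram (pooled relative frequencies).
    """

    def __init__(
        self,
        model: FixedShiftModel,
        log_odds: LogOddsVector,
        histogram: ProbabilityHistogram,
    ):
        self.model = model
        self.pooled = model.pooled
        self.log_odds = log_odds
        self.histogram = histogram

    @property
    def cdf(self) -> CumulativeDistribution:
        return cumulative(self.histogram)

    @property
    def n_images(self) -> int:
        return self.pooled.n_images

    @property
    def n_total(self) -> int:
        return self.pooled.n_total

    def summary(self) -> str:
        from .compare import shannon_entropy

        stats = summarize(self.histogram)
        lines = [
            "Fixed-shift MLE of ensemble intensity histogram",
            "=" * 48,
            f"channel:         {self.pooled.channel.value}",
            f"images pooled:   {self.n_images}",
            f"total pixels:    {self.n_total}",
            f"support size:    {len(self.histogram.support)}",
            f"mean intensity:  {stats['mean']:.3f}",
            f"median:          {stats['median']}",
            f"entropy (nats):  {shannon_entropy(self.histogram):.4f}",
        ]
        return "\n".join(lines)

    def compare(
        self,
        other: "FixedShiftResults",
        n_eff: str | float = "images",
        params: "EscortParameters | None" = None,
        alpha: float = 0.05,
    ) -> "GroupComparisonResult":
        """Full statistical comparison against another fitted ensemble.

        ``n_eff`` selects the effective sample sizes entering the KS
        p-value: ``"images"`` (ensemble sizes), ``"pixels"`` (pooled pixel
        counts), or an explicit numeric value used for both groups.
        """
        from .compare import compare_groups

        return compare_groups(self, other, n_eff=n_eff, params=params, alpha=alpha)

    def to_tsv(self, path: str | Path) -> None:
        """Write the estimate as TSV with columns g, d_g, rho_g, p_g."""
        rho_map = self.log_odds.as_dict()
        with open(path, "w") as fh:
            fh.write("g\td\trho\tp\n")
            for g in range(N_BINS):
                rho = rho_map.get(g)
                rho_s = f"{rho:.17g}" if rho is not None else "NA"
                fh.write(
                    f"{g}\t{self.pooled.d[g]}\t{rho_s}\t{self.histogram.probs[g]:.17g}\n"
                )
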