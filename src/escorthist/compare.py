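"""Statistical comparison of two ensemble histograms.

Three layers of comparison:

1. A two-sample Kolmogorov-Smirnov test on the estimated histograms,
   D = max_g |F_p(g) - F_q(g)|, with the p-value from the asymptotic
   Kolmogorov distribution at n = n1 n2 / (n1 + n2).  The effective
   sample sizes are a caller decision (image counts vs pooled pixel
   counts), never guessed.

2. The escort family P_g(beta) = p_g^beta / sum_{p_h != 0} p_h^beta,
   which scans a histogram: beta > 1 accentuates high-probability bins,
   beta < 1 and negative beta accentuate rare ones, beta = 0 is uniform
   on the support and beta = 1 the original histogram.  Escorts are
   computed in the log domain so large |beta| is stable.

3. Hellinger distance H and Shannon-entropy difference dS evaluated
   along a beta grid (`beta_scan`), with a qualitative classification of
   the H(beta) profile into monotonic growth / flat / non-monotonic —
   the three behaviours that tell which intensity bins drive the group
   difference.  A rising entropy of the treated arm is the histogram
   signature of cluster formation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import logsumexp
from scipy.stats import kstwobign

from .histogram import (
    N_BINS,
    CumulativeDistribution,
    Dominance,
    ProbabilityHistogram,
    cumulative,
    darker_than,
    summarize,
)

if TYPE_CHECKING:  # pragma: no cover
    from .model import FixedShiftResults

__all__ = [
    "EscortParameters",
    "KSResult",
    "BetaScanResult",
    "ProfileShape",
    "ProfileClass",
    "ks_compare",
    "escort",
    "hellinger",
    "shannon_entropy",
    "entropy_difference",
    "beta_scan",
    "classify_profile",
    "compare_groups",
    "GroupComparisonResult",
]


@dataclass(frozen=True)
class EscortParameters:
    """A strictly increasing beta grid; must contain 0 and 1."""

    beta_grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.beta_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("beta grid must be a 1-D array with >= 2 points")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("beta grid must be strictly increasing")
        if not (np.any(grid == 0.0) and np.any(grid == 1.0)):
            raise ValueError("beta grid must contain 0 and 1 exactly")
        object.__setattr__(self, "beta_grid", grid)

    @classmethod
    def default(
        cls, beta_min: float = -5.0, beta_max: float = 5.0, steps: int = 101
    ) -> "EscortParameters":
        """Evenly spaced grid on [beta_min, beta_max] plus exact 0 and 1."""
        grid = np.linspace(beta_min, beta_max, steps)
        grid = np.union1d(np.round(grid, 12), [0.0, 1.0])
        return cls(beta_grid=grid)


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    n_eff_1: float
    n_eff_2: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value <= alpha


class ProfileShape(str, enum.Enum):
    MONOTONIC_GROWTH = "monotonic_growth"
    FLAT = "flat"
    NON_MONOTONIC = "non_monotonic"


@dataclass(frozen=True)
class ProfileClass:
    """Qualitative shape of an H(beta) curve.

    ``argmax_beta`` is reported for non-monotonic profiles: the beta at
    which the curve peaks, i.e. the escort family member that best
    separates the two groups.
    """

    shape: ProfileShape
    argmax_beta: float | None = None


@dataclass(frozen=True)
class BetaScanResult:
    """H(beta) and dS(beta) along a beta grid for one (staining, channel)."""

    beta: np.ndarray
    hellinger: np.ndarray
    delta_entropy: np.ndarray
    labels: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("beta\thellinger\tdelta_entropy\n")
            for b, h, ds in zip(self.beta, self.hellinger, self.delta_entropy):
                fh.write(f"{b:.17g}\t{h:.17g}\t{ds:.17g}\n")


def ks_compare(
    p: ProbabilityHistogram,
    q: ProbabilityHistogram,
    n_eff_1: float,
    n_eff_2: float,
) -> KSResult:
    """Two-sample KS comparison of two intensity histograms.

    D is the maximum vertical gap between the two cumulative curves over
    all 256 bins; the p-value comes from the asymptotic two-sample
    Kolmogorov distribution at n = n1 n2 / (n1 + n2).
    """
    if n_eff_1 <= 0 or n_eff_2 <= 0:
        raise ValueError("effective sample sizes must be positive")
    fp = cumulative(p).values
    fq = cumulative(q).values
    statistic = float(np.max(np.abs(fp - fq)))
    n = n_eff_1 * n_eff_2 / (n_eff_1 + n_eff_2)
    p_value = float(kstwobign.sf(np.sqrt(n) * statistic))
    return KSResult(
        statistic=statistic,
        p_value=min(1.0, p_value),
        n_eff_1=float(n_eff_1),
        n_eff_2=float(n_eff_2),
    )


def escort(hist: ProbabilityHistogram, beta: float) -> ProbabilityHistogram:
    """Escort distribution P_g(beta) on the histogram's own support.

    Computed as exp(beta ln p_g - logsumexp(beta ln p_h)) so that large
    |beta| and negative beta remain stable.
    """
    support = hist.support
    if support.size == 0:
        raise ValueError("histogram has empty support")
    if beta == 1.0:  # identity member of the family, exact by construction
        return hist
    logp = np.log(hist.probs[support])
    scaled = beta * logp
    if not np.all(np.isfinite(scaled)):
        raise OverflowError(
            f"escort exponent overflow at beta={beta!r}: |beta * ln p| too large"
        )
    log_escort = scaled - logsumexp(scaled)
    probs = np.zeros(N_BINS)
    probs[support] = np.exp(log_escort)
    # guard renormalisation drift from the exponential
    probs[support] /= probs[support].sum()
    return ProbabilityHistogram(probs=probs)


def hellinger(
    p: ProbabilityHistogram, q: ProbabilityHistogram, form: str = "hellinger"
) -> float:
    """Hellinger distance H in [0, 1], with H^2 = 1/2 sum (sqrt p - sqrt q)^2.

    Evaluated over the union of supports (missing bins contribute their
    full mass).  ``form="squared_diff"`` instead returns
    sqrt(1/2 sum (p - q)^2), a non-Hellinger variant kept only for
    sensitivity checks.
    """
    if form == "hellinger":
        h2 = 0.5 * np.sum((np.sqrt(p.probs) - np.sqrt(q.probs)) ** 2)
    elif form == "squared_diff":
        h2 = 0.5 * np.sum((p.probs - q.probs) ** 2)
    else:
        raise ValueError(f"unknown form {form!r}")
    return float(np.sqrt(max(0.0, min(1.0, h2))))


def shannon_entropy(hist: ProbabilityHistogram) -> float:
    """S = -sum p ln p in nats, zero-mass bins contributing nothing."""
    p = hist.probs[hist.support]
    return float(-np.dot(p, np.log(p)))


def entropy_difference(
    cells: ProbabilityHistogram, control: ProbabilityHistogram, beta: float
) -> float:
    """dS(beta) = S(escort(cells, beta)) - S(escort(control, beta)).

    Positive values mean the treated ('cells') histogram carries more
    informational content — the signature of cluster formation.
    """
    return shannon_entropy(escort(cells, beta)) - shannon_entropy(escort(control, beta))


def beta_scan(
    cells: ProbabilityHistogram,
    control: ProbabilityHistogram,
    params: EscortParameters | None = None,
    labels: dict | None = None,
) -> BetaScanResult:
    """Evaluate H(beta) and dS(beta) along the beta grid.

    Escorts are formed on each histogram's own support; the Hellinger
    distance then runs over the union, so with unequal supports H(0)
    need not vanish.
    """
    if params is None:
        params = EscortParameters.default()
    h_vals = np.empty(params.beta_grid.size)
    ds_vals = np.empty(params.beta_grid.size)
    for i, b in enumerate(params.beta_grid):
        ec = escort(cells, b)
        ek = escort(control, b)
        h_vals[i] = hellinger(ec, ek)
        ds_vals[i] = shannon_entropy(ec) - shannon_entropy(ek)
    return BetaScanResult(
        beta=params.beta_grid.copy(),
        hellinger=h_vals,
        delta_entropy=ds_vals,
        labels=dict(labels or {}),
    )


def classify_profile(
    beta: np.ndarray,
    values: np.ndarray,
    tol_flat: float = 0.05,
    tol_mono: float = 1e-6,
) -> ProfileClass:
    """Classify an H(beta) curve as flat, monotonic growth, or non-monotonic.

    Flat: relative range (max - min) below ``tol_flat`` of the maximum.
    Monotonic growth: successive differences all >= -tol_mono.
    Otherwise non-monotonic, with the beta of the maximum reported.
    """
    beta = np.asarray(beta, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("profile classification needs at least 3 grid points")
    vmax, vmin = float(values.max()), float(values.min())
    eps = 1e-300
    if (vmax - vmin) < tol_flat * max(vmax, eps):
        return ProfileClass(shape=ProfileShape.FLAT)
    if np.all(np.diff(values) >= -tol_mono):
        return ProfileClass(shape=ProfileShape.MONOTONIC_GROWTH)
    return ProfileClass(
        shape=ProfileShape.NON_MONOTONIC, argmax_beta=float(beta[np.argmax(values)])
    )


class GroupComparisonResult:
    """Full comparison of a treated ('cells') vs control fitted ensemble."""

    def __init__(
        self,
        ks: KSResult,
        scan: BetaScanResult,
        profile: ProfileClass,
        darkness: Dominance,
        cells_stats: dict,
        control_stats: dict,
        alpha: float = 0.05,
    ):
        self.ks = ks
        self.scan = scan
        self.profile = profile
        self.darkness = darkness
        self.cells_stats = cells_stats
        self.control_stats = control_stats
        self.alpha = alpha

    @property
    def delta_entropy_at_1(self) -> float:
        idx = int(np.flatnonzero(self.scan.beta == 1.0)[0])
        return float(self.scan.delta_entropy[idx])

    def to_dict(self) -> dict:
        return {
            "ks": {
                "statistic": self.ks.statistic,
                "p_value": self.ks.p_value,
                "n_eff_1": self.ks.n_eff_1,
                "n_eff_2": self.ks.n_eff_2,
                "significant": self.ks.significant(self.alpha),
                "alpha": self.alpha,
            },
            "profile": {
                "shape": self.profile.shape.value,
                "argmax_beta": self.profile.argmax_beta,
            },
            "darkness": self.darkness.value,
            "delta_entropy_at_beta_1": self.delta_entropy_at_1,
            "cells": self.cells_stats,
            "control": self.control_stats,
            "labels": self.scan.labels,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Group comparison (treated vs control)",
            "=" * 48,
            f"KS statistic:      {self.ks.statistic:.6f}",
            f"KS p-value:        {self.ks.p_value:.6g}"
            f"  ({'significant' if self.ks.significant(self.alpha) else 'not significant'}"
            f" at alpha={self.alpha})",
            f"n_eff:             {self.ks.n_eff_1:g}, {self.ks.n_eff_2:g}",
            f"H(beta) profile:   {self.profile.shape.value}"
            + (
                f" (argmax beta = {self.profile.argmax_beta:g})"
                if self.profile.argmax_beta is not None
                else ""
            ),
            f"darkness verdict:  {self.darkness.value}",
            f"dS at beta=1:      {self.delta_entropy_at_1:+.6f}",
            f"treated mean/med:  {d['cells']['mean']:.2f} / {d['cells']['median']}",
            f"control mean/med:  {d['control']['mean']:.2f} / {d['control']['median']}",
        ]
        return "\n".join(lines)


def compare_groups(
    cells: "FixedShiftResults",
    control: "FixedShiftResults",
    n_eff: str | float = "images",
    params: EscortParameters | None = None,
    alpha: float = 0.05,
    labels: dict | None = None,
) -> GroupComparisonResult:
    """Compare two fitted fixed-shift ensembles end to end.

    Runs the KS test (with the requested effective-sample-size policy),
    the beta scan, the profile classification and the darkness ordering.
    """
    if n_eff == "images":
        n1, n2 = cells.n_images, control.n_images
    elif n_eff == "pixels":
        n1, n2 = cells.n_total, control.n_total
    else:
        n1 = n2 = float(n_eff)
    ks = ks_compare(cells.histogram, control.histogram, n1, n2)
    scan = beta_scan(cells.histogram, control.histogram, params=params, labels=labels)
    profile = classify_profile(scan.beta, scan.hellinger)
    darkness = darker_than(cells.cdf, control.cdf)
    return GroupComparisonResult(
        ks=ks,
        scan=scan,
        profile=profile,
        darkness=darkness,
        cells_stats=summarize(cells.histogram),
        control_stats=summarize(control.histogram),
        alpha=alpha,
    )
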