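"""Droplet-level quantification for two-channel digital PCR.

A droplet digital PCR well partitions a DNA sample into ~20,000
water-in-oil droplets, each an independent end-point PCR read out on two
fluorescence channels (FAM / HEX).  Template molecules load into droplets
as independent Poisson processes, so the mean occupancy per droplet is

    lambda = -ln(n_negative / n_total)

where a droplet is "negative" on a channel when its amplitude stays at
the no-amplification baseline.  This module classifies droplets into the
four threshold quadrants, estimates lambda per channel with a score-based
confidence interval, and detects the intermediate "aberrant" cluster that
arises when a wild-type probe cross-hybridizes to an untargeted mutant
amplicon (the signature used for indirect rare-variant detection).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger("umdpcr")

#: Nominal droplet volume in nanolitres (QX100-class instruments).
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Fallback amplitude cutoff when a channel shows a single cluster.
DEFAULT_FIXED_CUTOFF = 3000.0


class SaturatedWellError(ValueError):
    """No negative droplets on a channel: lambda is unbounded."""


@dataclass(frozen=True)
class DropletWell:
    """Raw per-droplet amplitudes of one assay well.

    Parameters
    ----------
    well_id, assay_id
        Free-form labels (plate position and assay name).
    ch1, ch2
        Per-droplet fluorescence amplitudes, arbitrary units.  Channel 1
        carries the target/mutant probe (FAM), channel 2 the
        reference/wild-type probe (HEX).
    """

    well_id: str
    assay_id: str
    ch1: np.ndarray
    ch2: np.ndarray

    def __post_init__(self) -> None:
        ch1 = np.asarray(self.ch1, dtype=float)
        ch2 = np.asarray(self.ch2, dtype=float)
        object.__setattr__(self, "ch1", ch1)
        object.__setattr__(self, "ch2", ch2)
        if ch1.ndim != 1 or ch1.shape != ch2.shape:
            raise ValueError("ch1 and ch2 must be 1-D arrays of equal length")
        if ch1.size < 1:
            raise ValueError("a well must contain at least one droplet")
        if not (np.isfinite(ch1).all() and np.isfinite(ch2).all()):
            raise ValueError("droplet amplitudes must be finite")

    @property
    def n_droplets(self) -> int:
        return int(self.ch1.size)

    def amplitudes(self, channel: int) -> np.ndarray:
        if channel == 1:
            return self.ch1
        if channel == 2:
            return self.ch2
        raise ValueError(f"channel must be 1 or 2, got {channel}")


@dataclass(frozen=True)
class ChannelThresholds:
    """Per-channel amplitude cutoffs separating negative from positive."""

    channel1_cutoff: float
    channel2_cutoff: float
    method: str = "data-driven"  # "data-driven" | "fixed"

    def cutoff(self, channel: int) -> float:
        return self.channel1_cutoff if channel == 1 else self.channel2_cutoff


@dataclass(frozen=True)
class DropletCounts:
    """Quadrant occupancy of a classified well."""

    n_total: int
    n_double_negative: int
    n_ch1_only: int
    n_ch2_only: int
    n_double_positive: int

    def __post_init__(self) -> None:
        parts = (
            self.n_double_negative,
            self.n_ch1_only,
            self.n_ch2_only,
            self.n_double_positive,
        )
        if any(p < 0 for p in parts) or sum(parts) != self.n_total:
            raise ValueError("quadrant counts must be non-negative and sum to n_total")

    def n_positive(self, channel: int) -> int:
        """Droplets positive on `channel`, regardless of the other channel."""
        if channel == 1:
            return self.n_ch1_only + self.n_double_positive
        return self.n_ch2_only + self.n_double_positive

    def n_negative(self, channel: int) -> int:
        return self.n_total - self.n_positive(channel)


@dataclass(frozen=True)
class Concentration:
    """Poisson concentration estimate for one channel.

    ``lam`` is mean template copies per droplet; the confidence interval
    comes from the Wilson score interval on the negative-droplet fraction
    mapped through -ln.  ``saturated`` wells (no negatives) carry NaN.
    """

    lam: float
    ci_low: float
    ci_high: float
    copies_per_microliter: float
    estimated_template_copies: float
    n_droplets: int
    n_positive: int
    saturated: bool = False
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not self.saturated:
            if not (0.0 <= self.ci_low <= self.lam <= self.ci_high):
                raise ValueError("require 0 <= ci_low <= lambda <= ci_high")
            if (self.lam == 0.0) != (self.n_positive == 0):
                raise ValueError("lambda must be 0 exactly when no droplet is positive")


@dataclass(frozen=True)
class AberrantClusterReport:
    """Intermediate-amplitude cluster on the wild-type channel.

    ``occupancy_fraction`` is relative to the whole well so it can be
    compared across assays with the mutant-positive fraction of a
    variant-targeting assay on the same sample.
    """

    detected: bool
    center_amplitude: float = float("nan")
    occupancy_fraction: float = 0.0
    n_droplets: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_fraction <= 1.0:
            raise ValueError("occupancy_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# 1-D clustering helpers
# ---------------------------------------------------------------------------

def _kmeans1d(x: np.ndarray, k: int, n_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D Lloyd's k-means.

    Centers initialise evenly spaced over the amplitude range (quantile
    init collapses when one cluster holds most droplets, e.g. a small
    aberrant cluster next to a dominant negative cluster).  Empty
    clusters keep their center.  Returns (sorted centers, labels into
    sorted order).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    centers = lo + (np.arange(k) + 0.5) / k * (hi - lo)
    for _ in range(n_iter):
        labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(k):
            sel = labels == j
            if sel.any():
                new[j] = x[sel].mean()
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    order = np.argsort(centers)
    centers = centers[order]
    labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    return centers, labels


def _cluster_spread(x: np.ndarray, labels: np.ndarray, j: int) -> float:
    sel = labels == j
    if sel.sum() < 2:
        return 0.0
    return float(np.std(x[sel], ddof=1))


# ---------------------------------------------------------------------------
# Thresholds and classification
# ---------------------------------------------------------------------------

def fit_thresholds(
    well: DropletWell,
    fixed_cutoff: float = DEFAULT_FIXED_CUTOFF,
    min_droplets: int = 100,
    min_separation_sigma: float = 3.0,
) -> ChannelThresholds:
    """Place a per-channel cutoff between the negative and positive clusters.

    Each channel is clustered with 2-means; the cutoff is the midpoint of
    the two cluster centers.  When the centers are closer than
    ``min_separation_sigma`` pooled within-cluster standard deviations
    (single-cluster channel, e.g. lambda = 0) the configured fixed cutoff
    is used instead and a warning is logged.
    """
    if well.n_droplets < min_droplets:
        logger.warning(
            "well %s: %d droplets < %d required for data-driven thresholds; "
            "using fixed cutoff %.1f",
            well.well_id, well.n_droplets, min_droplets, fixed_cutoff,
        )
        return ChannelThresholds(fixed_cutoff, fixed_cutoff, method="fixed")

    cutoffs: list[float] = []
    methods: list[str] = []
    for channel in (1, 2):
        x = well.amplitudes(channel)
        if np.ptp(x) == 0.0:
            logger.warning(
                "well %s ch%d: all amplitudes identical; fixed-cutoff fallback",
                well.well_id, channel,
            )
            cutoffs.append(fixed_cutoff)
            methods.append("fixed")
            continue
        centers, labels = _kmeans1d(x, 2)
        s = math.sqrt(
            0.5 * (_cluster_spread(x, labels, 0) ** 2 + _cluster_spread(x, labels, 1) ** 2)
        )
        if centers[1] - centers[0] < min_separation_sigma * s or s == 0.0 and centers[1] == centers[0]:
            # Inseparable clusters: single population on this channel.
            fallback = max(fixed_cutoff, float(x.max()) + 1.0) if centers[1] < fixed_cutoff else fixed_cutoff
            logger.warning(
                "well %s ch%d: clusters inseparable (gap %.1f < %.1f sigma); "
                "fixed-cutoff fallback at %.1f",
                well.well_id, channel, centers[1] - centers[0], min_separation_sigma, fallback,
            )
            cutoffs.append(fallback)
            methods.append("fixed")
        else:
            cutoffs.append(float(centers.mean()))
            methods.append("data-driven")
    method = "data-driven" if all(m == "data-driven" for m in methods) else "fixed"
    return ChannelThresholds(cutoffs[0], cutoffs[1], method=method)


def classify_droplets(well: DropletWell, thresholds: ChannelThresholds) -> DropletCounts:
    """Assign every droplet to one threshold quadrant.

    Positivity is strict (amplitude > cutoff); a droplet exactly at the
    cutoff counts as negative.
    """
    pos1 = well.ch1 > thresholds.channel1_cutoff
    pos2 = well.ch2 > thresholds.channel2_cutoff
    return DropletCounts(
        n_total=well.n_droplets,
        n_double_negative=int((~pos1 & ~pos2).sum()),
        n_ch1_only=int((pos1 & ~pos2).sum()),
        n_ch2_only=int((~pos1 & pos2).sum()),
        n_double_positive=int((pos1 & pos2).sum()),
    )


# ---------------------------------------------------------------------------
# Poisson estimation
# ---------------------------------------------------------------------------

def estimate_concentration(
    n_negative: int,
    n_total: int,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    confidence: float = 0.95,
) -> Concentration:
    """Estimate copies/droplet from the negative-droplet count.

    lambda-hat = -ln(n_negative / n_total) is the maximum-likelihood
    estimator under Poisson loading.  The CI transforms the Wilson score
    interval for the negative fraction through -ln (monotone decreasing,
    so the bounds swap).  An all-positive well is returned flagged
    ``saturated`` with NaN concentration rather than +inf.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_negative <= n_total:
        raise ValueError("n_negative must be in [0, n_total]")
    if droplet_volume_nl <= 0:
        raise ValueError("droplet_volume_nl must be positive")

    if n_negative == 0:
        logger.warning("saturated well: every droplet positive; lambda unbounded")
        return Concentration(
            lam=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            copies_per_microliter=float("nan"), estimated_template_copies=float("nan"),
            n_droplets=n_total, n_positive=n_total, saturated=True,
            confidence=confidence,
        )

    lam = -math.log(n_negative / n_total)
    alpha = 1.0 - confidence
    p_lo, p_hi = proportion_confint(n_negative, n_total, alpha=alpha, method="wilson")
    ci_high = -math.log(p_lo) if p_lo > 0 else float("inf")
    ci_low = max(0.0, -math.log(min(p_hi, 1.0)) if p_hi > 0 else 0.0)
    if n_negative == n_total:
        lam, ci_low = 0.0, 0.0
    volume_ul = droplet_volume_nl * 1e-3
    return Concentration(
        lam=lam,
        ci_low=ci_low,
        ci_high=ci_high,
        copies_per_microliter=lam / volume_ul,
        estimated_template_copies=lam * n_total,
        n_droplets=n_total,
        n_positive=n_total - n_negative,
        saturated=False,
        confidence=confidence,
    )


def concentration_from_counts(
    counts: DropletCounts,
    channel: int,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    confidence: float = 0.95,
) -> Concentration:
    """Channel-wise concentration from quadrant counts.

    A droplet counts as negative on a channel whenever its amplitude on
    that channel is below the cutoff, regardless of the other channel.
    """
    return estimate_concentration(
        counts.n_negative(channel), counts.n_total,
        droplet_volume_nl=droplet_volume_nl, confidence=confidence,
    )


# ---------------------------------------------------------------------------
# Aberrant-cluster detection
# ---------------------------------------------------------------------------

def detect_aberrant_cluster(
    well: DropletWell,
    thresholds: ChannelThresholds,
    mutant_channel: int = 1,
    min_fraction: float = 0.01,
    min_droplets: int = 20,
    separation_sigma: float = 4.0,
) -> AberrantClusterReport:
    """Look for an intermediate cluster on the wild-type channel.

    Among droplets negative on the mutant channel, the wild-type-channel
    amplitudes are clustered into three components.  The middle component
    is reported as aberrant when its center is separated from both the
    negative and the positive center by at least ``separation_sigma``
    pooled within-cluster standard deviations and it holds at least
    ``min_fraction`` of the well (and ``min_droplets`` droplets).  Such a
    cluster is the cross-hybridization signature of a mutant amplicon not
    targeted by the assay's mutant probe.
    """
    wt_channel = 2 if mutant_channel == 1 else 1
    neg_sel = well.amplitudes(mutant_channel) <= thresholds.cutoff(mutant_channel)
    x = well.amplitudes(wt_channel)[neg_sel]
    min_n = max(min_droplets, int(math.ceil(min_fraction * well.n_droplets)))
    if x.size < max(3 * min_n, 3):
        return AberrantClusterReport(detected=False)
    if np.ptp(x) == 0.0:
        return AberrantClusterReport(detected=False)

    centers, labels = _kmeans1d(x, 3)
    n_mid = int((labels == 1).sum())
    if n_mid < min_n:
        return AberrantClusterReport(detected=False)

    s0 = _cluster_spread(x, labels, 0)
    s1 = _cluster_spread(x, labels, 1)
    s2 = _cluster_spread(x, labels, 2)
    gap_lo = centers[1] - centers[0]
    gap_hi = centers[2] - centers[1]
    pooled_lo = math.sqrt(0.5 * (s0**2 + s1**2))
    pooled_hi = math.sqrt(0.5 * (s1**2 + s2**2))
    well_separated = (
        pooled_lo > 0 and pooled_hi > 0
        and gap_lo >= separation_sigma * pooled_lo
        and gap_hi >= separation_sigma * pooled_hi
    )
    if not well_separated:
        return AberrantClusterReport(detected=False)
    return AberrantClusterReport(
        detected=True,
        center_amplitude=float(centers[1]),
        occupancy_fraction=n_mid / well.n_droplets,
        n_droplets=n_mid,
    )


# ---------------------------------------------------------------------------
# Convenience: full quantification of one well
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellQuantification:
    """Both channel concentrations plus the aberrant-cluster scan."""

    well_id: str
    assay_id: str
    thresholds: ChannelThresholds
    counts: DropletCounts
    channel1: Concentration
    channel2: Concentration
    aberrant: AberrantClusterReport


def quantify_well(
    well: DropletWell,
    thresholds: ChannelThresholds | None = None,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    confidence: float = 0.95,
    mutant_channel: int = 1,
) -> WellQuantification:
    """Threshold, classify, estimate and scan a well in one call."""
    if thresholds is None:
        thresholds = fit_thresholds(well)
    counts = classify_droplets(well, thresholds)
    return WellQuantification(
        well_id=well.well_id,
        assay_id=well.assay_id,
        thresholds=thresholds,
        counts=counts,
        channel1=concentration_from_counts(counts, 1, droplet_volume_nl, confidence),
        channel2=concentration_from_counts(counts, 2, droplet_volume_nl, confidence),
        aberrant=detect_aberrant_cluster(well, thresholds, mutant_channel=mutant_channel),
    )
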