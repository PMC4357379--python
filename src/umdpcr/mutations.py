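"""GNAQ/GNA11 hotspot mutation calling from duplex assay quantifications.

Uveal melanoma is initiated by mutually exclusive hotspot mutations in
GNAQ or GNA11 (codon 209 in exon 5, codon 183 in exon 4).  Each duplex
assay pairs a mutation-specific probe (channel 1) with a wild-type probe
(channel 2).  A tumour is called:

* **direct** when a mutant probe lights up above the positivity floor;
* **indirect** when no mutant probe fires but an aberrant
  (cross-hybridization) cluster betrays an untargeted rare variant —
  such samples are flagged for confirmatory sequencing;
* **none** (wild-type) otherwise.

Under the model that every tumour cell is diploid at the driver locus
and carries one mutant and one wild-type allele, the mutant allele
fraction f gives the tumour cell fraction p = 2f, and a sample whose f
interval excludes 1/2 from below contains admixed non-tumour (or
wild-type tumour) cells — a *heterogeneous* sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .quant import AberrantClusterReport, Concentration

logger = logging.getLogger("umdpcr")

UNKNOWN_RARE_VARIANT = "unknown rare variant"


@dataclass(frozen=True)
class MutationAssayResult:
    """Quantification of one duplex mutation assay on one sample."""

    assay: str                   # e.g. "GNAQ_Q209P"
    gene: str                    # "GNAQ" | "GNA11" | ...
    variant: str                 # e.g. "Q209P"
    mutant: Concentration
    wildtype: Concentration
    aberrant: AberrantClusterReport


@dataclass(frozen=True)
class MutationCall:
    """Per-sample mutation call combining a panel of assays."""

    gene: str
    variant: str
    mode: str                    # direct | indirect | none
    mutant_fraction: float
    f_ci: tuple[float, float]
    heterogeneity: str           # homogeneous | heterogeneous | not_applicable
    tumour_fraction: float
    sequencing_recommended: bool = False
    anomalous: bool = False


def mutant_fraction(
    mutant_copies: float,
    wildtype_copies: float,
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Mutant allele fraction f = mut / (mut + wt) with a score interval.

    Copies may be fractional (lambda-derived template estimates); they
    are treated as effective binomial counts for the Wilson score
    interval, which stays well-behaved at extreme fractions.
    """
    if mutant_copies < 0 or wildtype_copies < 0:
        raise ValueError("copy estimates must be non-negative")
    total = mutant_copies + wildtype_copies
    if total <= 0:
        raise ValueError("no template: mutant + wildtype copies must be positive")
    f = mutant_copies / total
    lo, hi = proportion_confint(mutant_copies, total, alpha=1 - confidence, method="wilson")
    return f, (float(lo), float(hi))


def classify_heterogeneity(f: float, f_ci: tuple[float, float]) -> str:
    """Homogeneous unless the interval for f lies entirely below 1/2.

    A homogeneous tumour sample has balanced mutant and wild-type
    alleles (f = 1/2); an excess of wild-type alleles that cannot be
    explained by counting noise marks an admixed, heterogeneous sample.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    return "heterogeneous" if f_ci[1] < 0.5 else "homogeneous"


def estimate_tumour_fraction(f: float) -> float:
    """Tumour cell fraction p = 2f, capped at 1 (one mutant allele/cell)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    return min(2.0 * f, 1.0)


def _is_direct_positive(result: MutationAssayResult, min_mutant_droplets: int) -> bool:
    mut = result.mutant
    if mut.saturated:
        return True
    return mut.ci_low > 0.0 and mut.n_positive >= min_mutant_droplets


def call_mutation_panel(
    results: list[MutationAssayResult],
    min_mutant_droplets: int = 5,
    confidence: float = 0.95,
) -> MutationCall:
    """Combine a panel of duplex assays into one mutation call.

    Direct calls require the mutant channel's lambda lower bound above 0
    and at least ``min_mutant_droplets`` mutant-positive droplets
    (single-droplet artifacts never call a mutation).  Ties between
    direct positives resolve to the largest mutant fraction; direct
    positives in *both* genes are biologically implausible (the hotspot
    mutations are mutually exclusive) and mark the call anomalous rather
    than being silently resolved.
    """
    if not results:
        raise ValueError("need at least one assay result")

    direct = [r for r in results if _is_direct_positive(r, min_mutant_droplets)]
    if direct:
        scored = []
        for r in direct:
            f, ci = mutant_fraction(
                r.mutant.estimated_template_copies,
                r.wildtype.estimated_template_copies,
                confidence=confidence,
            )
            scored.append((f, ci, r))
        scored.sort(key=lambda t: t[0], reverse=True)
        f, ci, best = scored[0]
        anomalous = len({r.gene for r in direct}) > 1
        if anomalous:
            logger.warning(
                "anomalous panel: direct positives in multiple genes (%s)",
                ", ".join(sorted({r.gene for r in direct})),
            )
        return MutationCall(
            gene=best.gene,
            variant=best.variant,
            mode="direct",
            mutant_fraction=f,
            f_ci=ci,
            heterogeneity=classify_heterogeneity(f, ci),
            tumour_fraction=estimate_tumour_fraction(f),
            sequencing_recommended=anomalous,
            anomalous=anomalous,
        )

    aberrant = [r for r in results if r.aberrant is not None and r.aberrant.detected]
    if aberrant:
        # Largest aberrant occupancy carries the call; convert the
        # occupancy through the Poisson model to an allele fraction.
        best = max(aberrant, key=lambda r: r.aberrant.occupancy_fraction)
        occ = best.aberrant.occupancy_fraction
        lam_mut = -math.log(max(1.0 - occ, 1e-12))
        mut_copies = lam_mut * best.wildtype.n_droplets
        wt_copies = best.wildtype.estimated_template_copies
        f, ci = mutant_fraction(mut_copies, wt_copies, confidence=confidence)
        logger.warning(
            "indirect mutation call in %s via aberrant cluster (occupancy %.3f); "
            "confirmatory sequencing recommended", best.gene, occ,
        )
        return MutationCall(
            gene=best.gene,
            variant=UNKNOWN_RARE_VARIANT,
            mode="indirect",
            mutant_fraction=f,
            f_ci=ci,
            heterogeneity=classify_heterogeneity(f, ci),
            tumour_fraction=estimate_tumour_fraction(f),
            sequencing_recommended=True,
        )

    return MutationCall(
        gene="", variant="", mode="none",
        mutant_fraction=0.0, f_ci=(0.0, 0.0),
        heterogeneity="not_applicable", tumour_fraction=0.0,
    )
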