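"""Copy-number calling and chromosome-8 mechanism inference.

Copy numbers come from duplex digital PCR: a target locus (PPARG on 3p,
PTK2 on 8q, TUSC3 on 8p) against a reference locus (TERT on chromosome
5), normalized as cn = 2 * lambda_target / lambda_reference.  Classes
follow fixed dosage thresholds (loss < 1.9, normal 1.9–2.1, gain up to
3.1, amplification above), and the balance between 8q and 8p separates
whole-chromosome trisomy 8 from isochromosome 8q formation.  When the
TERT reference region is itself aberrant in a tumour, dPCR values cannot
be normalized properly and the SNP-array value substitutes (the
platform-fallback rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .quant import Concentration

logger = logging.getLogger("umdpcr")


class ReferenceFailure(ValueError):
    """Reference channel unusable (zero or saturated lambda)."""


@dataclass(frozen=True)
class CnThresholds:
    """Dosage class boundaries, in copy-number units.

    normal includes both endpoints [normal_low, normal_high]; gain is
    (normal_high, amplification_above]; amplification is open above.
    """

    loss_below: float = 1.9
    normal_low: float = 1.9
    normal_high: float = 2.1
    amplification_above: float = 3.1

    def __post_init__(self) -> None:
        if not (self.loss_below <= self.normal_low <= self.normal_high
                < self.amplification_above):
            raise ValueError("thresholds must be ordered: loss <= normal_low <= "
                             "normal_high < amplification_above")


@dataclass(frozen=True)
class CopyNumberCall:
    """One locus call: normalized value, dosage class, provenance."""

    locus: str
    cn: float
    cn_se: float
    cn_class: str
    reference: str = "TERT"
    reference_valid: bool = True
    platform: str = "dPCR"


@dataclass(frozen=True)
class TumourRecord:
    """Per-tumour cross-platform copy-number readout.

    Values are one-decimal copy numbers as reported by the platforms;
    karyotype codes are 0 = disomy, 1 = monosomy for chromosome 3 and
    0 = disomy, 1 = gain, 2 = isochromosome for chromosome 8 (None when
    karyotyping failed).  ``reference_flagged`` marks tumours whose
    chromosome-5 (TERT) region is aberrant, invalidating dPCR
    normalization for that sample.
    """

    tumour_id: str
    snp_chr3: float | None
    dpcr_chr3: float | None
    karyotype_chr3: int | None
    snp_8q: float | None
    dpcr_8q: float | None
    snp_8p: float | None
    dpcr_8p: float | None
    karyotype_chr8: int | None
    reference_flagged: bool = False


@dataclass(frozen=True)
class Chr8Mechanism:
    """Inferred structural route to the observed 8q dosage."""

    mechanism: str  # no_aberration | trisomy_8 | isochromosome_8q |
                    # trisomy_plus_isochromosome | undetermined


@dataclass(frozen=True)
class TumourProfile:
    """Classified molecular profile of one tumour."""

    tumour_id: str
    chr3_status: str            # disomy | monosomy
    cn_chr3: float
    cn_8q: float
    cn_8p: float | None
    cn8q_class: str
    cn8p_class: str | None
    mechanism: Chr8Mechanism
    combined_group: str
    platform: str               # dPCR | SNP
    classifiable: bool = True


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def copy_number(
    lambda_target: Concentration,
    lambda_reference: Concentration,
) -> tuple[float, float]:
    """Reference-normalized copy number 2 * lambda_t / lambda_r.

    The standard error propagates by the delta method from the two
    lambda confidence intervals (se taken as CI half-width / z).  It is
    reported for transparency; class assignment uses the point value.
    """
    if lambda_reference.saturated or lambda_target.saturated:
        raise ReferenceFailure("saturated channel: cannot normalize")
    if lambda_reference.lam <= 0:
        raise ReferenceFailure("reference lambda is zero: no normalization possible")
    cn = 2.0 * lambda_target.lam / lambda_reference.lam
    z = 1.959963984540054
    se_t = (lambda_target.ci_high - lambda_target.ci_low) / (2 * z)
    se_r = (lambda_reference.ci_high - lambda_reference.ci_low) / (2 * z)
    rel_t = se_t / lambda_target.lam if lambda_target.lam > 0 else 0.0
    rel_r = se_r / lambda_reference.lam
    cn_se = cn * math.sqrt(rel_t**2 + rel_r**2)
    return cn, cn_se


def classify_cn(cn: float, thresholds: CnThresholds = CnThresholds()) -> str:
    """Map a copy-number value to its dosage class."""
    if cn < 0 or not math.isfinite(cn):
        raise ValueError("cn must be finite and non-negative")
    if cn < thresholds.loss_below:
        return "loss"
    if cn <= thresholds.normal_high:
        return "normal"
    if cn <= thresholds.amplification_above:
        return "gain"
    return "amplification"


@dataclass(frozen=True)
class ReferenceConsensus:
    """Outcome of multi-reference validation."""

    consensus: float
    flagged: tuple[bool, ...]
    sample_flagged: bool


def validate_reference(
    reference_lambdas: list[float],
    tolerance: float = 0.15,
) -> ReferenceConsensus:
    """Cross-check candidate reference loci against each other.

    A reference from a stable genomic region should agree with the other
    candidates; any candidate whose ratio to the median deviates by more
    than ``tolerance`` is flagged aberrant and excluded.  The consensus
    is the mean of the survivors; with fewer than two survivors the whole
    sample is flagged as having no usable reference.
    """
    lams = np.asarray(reference_lambdas, dtype=float)
    if lams.size < 2:
        raise ValueError("need at least two candidate references")
    if np.any(lams < 0):
        raise ValueError("reference lambdas must be non-negative")
    if np.all(lams == 0):
        raise ValueError("all candidate references are zero")
    med = float(np.median(lams))
    flagged = tuple(bool(med == 0 or abs(l / med - 1.0) > tolerance) for l in lams)
    survivors = lams[~np.array(flagged)]
    if survivors.size < 2:
        logger.warning("reference validation: fewer than two concordant references; "
                       "sample flagged")
        consensus = float(survivors.mean()) if survivors.size else float("nan")
        return ReferenceConsensus(consensus, flagged, sample_flagged=True)
    return ReferenceConsensus(float(survivors.mean()), flagged, sample_flagged=False)


def infer_chr8_mechanism(
    cn8q_class: str,
    cn8p: float | None,
    thresholds: CnThresholds = CnThresholds(),
) -> Chr8Mechanism:
    """Infer the structural mechanism behind an 8q dosage class.

    A balanced increase of 8p alongside an 8q gain indicates trisomy 8;
    8q excess over a normal 8p indicates isochromosome 8q; amplification
    with 8p gained on top indicates trisomy plus isochromosome.
    """
    if cn8q_class in ("normal", "loss"):
        return Chr8Mechanism("no_aberration")
    if cn8p is None or (isinstance(cn8p, float) and math.isnan(cn8p)):
        return Chr8Mechanism("undetermined")
    p_gained = cn8p > thresholds.normal_high
    if cn8q_class == "gain":
        return Chr8Mechanism("trisomy_8" if p_gained else "isochromosome_8q")
    if cn8q_class == "amplification":
        return Chr8Mechanism("trisomy_plus_isochromosome" if p_gained
                             else "isochromosome_8q")
    raise ValueError(f"unknown 8q class {cn8q_class!r}")


def _pick(record: TumourRecord, locus: str) -> tuple[float | None, str]:
    """Apply the platform-fallback rule for one locus."""
    dpcr = getattr(record, f"dpcr_{locus}")
    snp = getattr(record, f"snp_{locus}")
    if record.reference_flagged:
        return snp, "SNP"
    return dpcr, "dPCR"


def classify_tumour(
    record: TumourRecord,
    thresholds: CnThresholds = CnThresholds(),
) -> TumourProfile:
    """Classify one tumour record into its molecular profile."""
    cn3, platform = _pick(record, "chr3")
    cn8q, _ = _pick(record, "8q")
    cn8p, _ = _pick(record, "8p")
    if record.reference_flagged:
        logger.warning("tumour %s: TERT reference flagged; substituting SNP values",
                       record.tumour_id)
    if cn3 is None or cn8q is None:
        logger.warning("tumour %s: missing %s values; unclassifiable",
                       record.tumour_id, platform)
        return TumourProfile(
            tumour_id=record.tumour_id, chr3_status="unknown",
            cn_chr3=float("nan"), cn_8q=float("nan"), cn_8p=None,
            cn8q_class="unknown", cn8p_class=None,
            mechanism=Chr8Mechanism("undetermined"),
            combined_group="unclassifiable", platform=platform,
            classifiable=False,
        )
    chr3_status = "monosomy" if cn3 < thresholds.loss_below else "disomy"
    cn8q_class = classify_cn(cn8q, thresholds)
    cn8p_class = classify_cn(cn8p, thresholds) if cn8p is not None else None
    mechanism = infer_chr8_mechanism(cn8q_class, cn8p, thresholds)
    return TumourProfile(
        tumour_id=record.tumour_id,
        chr3_status=chr3_status,
        cn_chr3=cn3, cn_8q=cn8q, cn_8p=cn8p,
        cn8q_class=cn8q_class, cn8p_class=cn8p_class,
        mechanism=mechanism,
        combined_group=f"{chr3_status}3+8q-{cn8q_class}",
        platform=platform,
    )


def classify_cohort(
    records: list[TumourRecord],
    thresholds: CnThresholds = CnThresholds(),
) -> list[TumourProfile]:
    """Classify every tumour in a cohort (dPCR primary, SNP fallback)."""
    ids = [r.tumour_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("tumour ids must be unique")
    return [classify_tumour(r, thresholds) for r in records]
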