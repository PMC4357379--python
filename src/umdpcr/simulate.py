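"""Droplet-level and cohort-level simulators with known ground truth.

The wet-lab side of the workflow — droplet generation, end-point PCR and
the two-colour droplet reader — is replaced here by a generative model:

* :func:`simulate_well` emulates one ~20,000-droplet emulsion.  Template
  molecules load into droplets as independent Poisson processes at rate
  lambda = copies / n_droplets per species; a droplet's channel amplitude
  is drawn from a negative or positive Gaussian cluster according to its
  occupancy, with double occupancy saturating at the positive amplitude.
  A mutant allele not targeted by the assay's probe appears on the
  wild-type channel at an intermediate amplitude scaled by the probe
  cross-reactivity — the "aberrant" cluster used for indirect detection.

* :func:`simulate_cohort` emulates a tumour cohort: per-tumour integer
  copy numbers drawn from a joint (chromosome 3) x (8q dosage) class mix,
  per-platform noisy purity-weighted readouts, and exponential survival
  times calibrated so that each 8q class hits its configured five-year
  survival.

Both return the truth alongside the observable data, so estimators can be
scored against what actually happened in the simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .quant import DropletWell, DEFAULT_DROPLET_VOLUME_NL

#: Mass of one haploid human genome, picograms.
HAPLOID_GENOME_PG = 3.3

#: Haploid genome equivalents per nanogram of human DNA (~303 /ng).
HAPLOID_COPIES_PER_NG = 1000.0 / HAPLOID_GENOME_PG

#: Five-year survival per 8q dosage class used to calibrate the cohort
#: simulator (good / intermediate / bad prognosis).
FIVE_YEAR_SURVIVAL = {"normal": 0.93, "gain": 0.67, "amplification": 0.29}

#: Joint class mix (chr3 status, 8q class) -> proportion, matching the
#: observed distribution in the 66-tumour reference cohort.
DEFAULT_CLASS_MIX = {
    ("disomy", "normal"): 11 / 66,
    ("disomy", "gain"): 8 / 66,
    ("disomy", "amplification"): 4 / 66,
    ("monosomy", "normal"): 3 / 66,
    ("monosomy", "gain"): 16 / 66,
    ("monosomy", "amplification"): 24 / 66,
}

#: Among 8q-gain tumours, the fraction whose mechanism is whole-chromosome
#: trisomy 8 (balanced 8p gain); the rest are isochromosome 8q.
TRISOMY_FRACTION_OF_GAIN = 8 / 24
#: Among 8q-amplified tumours, the fraction with trisomy 8 on top of
#: isochromosome 8q (8p gained as well).
COMBINED_FRACTION_OF_AMP = 6 / 28

CLUSTER_LABELS = ("double_negative", "ch1_positive", "ch2_positive",
                  "double_positive", "aberrant")


@dataclass(frozen=True)
class AmplitudeModel:
    """Gaussian amplitude clusters per channel (arbitrary units)."""

    neg_mean: float = 1000.0
    neg_sd: float = 100.0
    pos_mean: float = 5000.0
    pos_sd: float = 300.0

    def __post_init__(self) -> None:
        if self.neg_mean <= 0 or self.pos_mean <= 0:
            raise ValueError("amplitude means must be positive")
        if self.neg_sd < 0 or self.pos_sd < 0:
            raise ValueError("amplitude standard deviations must be non-negative")
        if self.pos_mean <= self.neg_mean:
            raise ValueError("positive cluster must sit above the negative cluster")

    def aberrant_mean(self, cross_reactivity: float) -> float:
        return self.neg_mean + cross_reactivity * (self.pos_mean - self.neg_mean)


@dataclass(frozen=True)
class WellSimConfig:
    """Configuration of one simulated duplex well.

    Template input is given either as explicit molecule counts
    (``ch1_copies`` / ``ch2_copies`` / ``untargeted_mutant_copies``) or
    derived from DNA mass, tumour fraction and a copy-number profile via
    the :meth:`mutation_assay` / :meth:`cnv_assay` constructors.
    ``untargeted_mutant_copies`` are mutant molecules the channel-1 probe
    does not recognise; they surface only through the wild-type probe's
    cross-reactivity on channel 2.
    """

    n_droplets: int = 20000
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    ch1_copies: float = 0.0
    ch2_copies: float = 0.0
    untargeted_mutant_copies: float = 0.0
    cross_reactivity: float = 0.3
    amplitude: AmplitudeModel = field(default_factory=AmplitudeModel)
    seed: int = 0
    well_id: str = "A01"
    assay_id: str = "assay"

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if min(self.ch1_copies, self.ch2_copies, self.untargeted_mutant_copies) < 0:
            raise ValueError("template copies must be non-negative")
        if not 0.0 <= self.cross_reactivity <= 1.0:
            raise ValueError("cross_reactivity must be in [0, 1]")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be positive")

    # -- constructors from biological parameters --------------------------

    @classmethod
    def mutation_assay(
        cls,
        template_mass_ng: float,
        tumour_fraction: float,
        targets_mutant: bool = True,
        mutant_present: bool = True,
        **kwargs,
    ) -> "WellSimConfig":
        """Duplex mutant/wild-type assay on a tumour/normal DNA mixture.

        Every tumour cell is assumed diploid with one mutant and one
        wild-type allele of the driver gene, so at tumour cell fraction p
        the mutant allele fraction is p/2.  When the simulated assay does
        not target the mutant (``targets_mutant=False``), mutant
        molecules are routed to the untargeted pool and can only show up
        as an aberrant cluster.
        """
        if template_mass_ng < 0:
            raise ValueError("template_mass_ng must be non-negative")
        if not 0.0 <= tumour_fraction <= 1.0:
            raise ValueError("tumour_fraction must be in [0, 1]")
        genomes = template_mass_ng * HAPLOID_COPIES_PER_NG  # haploid equivalents
        mut = genomes * tumour_fraction / 2.0 if mutant_present else 0.0
        wt = genomes - mut
        if targets_mutant:
            return cls(ch1_copies=mut, ch2_copies=wt, untargeted_mutant_copies=0.0, **kwargs)
        return cls(ch1_copies=0.0, ch2_copies=wt, untargeted_mutant_copies=mut, **kwargs)

    @classmethod
    def cnv_assay(
        cls,
        template_mass_ng: float,
        tumour_fraction: float,
        target_cn: float,
        reference_cn: float = 2.0,
        **kwargs,
    ) -> "WellSimConfig":
        """Duplex target/reference copy-number assay.

        Channel 1 carries the target locus, channel 2 the reference
        locus; normal (non-tumour) cells contribute two copies of each.
        """
        if template_mass_ng < 0:
            raise ValueError("template_mass_ng must be non-negative")
        if not 0.0 <= tumour_fraction <= 1.0:
            raise ValueError("tumour_fraction must be in [0, 1]")
        if target_cn < 0 or reference_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        genomes = template_mass_ng * HAPLOID_COPIES_PER_NG
        p = tumour_fraction
        mean_target = p * target_cn + (1 - p) * 2.0
        mean_ref = p * reference_cn + (1 - p) * 2.0
        return cls(
            ch1_copies=genomes * mean_target / 2.0,
            ch2_copies=genomes * mean_ref / 2.0,
            untargeted_mutant_copies=0.0,
            **kwargs,
        )


@dataclass(frozen=True)
class WellTruth:
    """Ground truth of one simulated well."""

    lambda_ch1: float
    lambda_ch2: float
    lambda_untargeted: float
    occupancy_ch1: np.ndarray
    occupancy_ch2: np.ndarray
    occupancy_untargeted: np.ndarray
    cluster_labels: np.ndarray  # values from CLUSTER_LABELS

    @property
    def n_droplets(self) -> int:
        return int(self.cluster_labels.size)

    def fraction(self, label: str) -> float:
        if label not in CLUSTER_LABELS:
            raise ValueError(f"unknown cluster label {label!r}")
        return float((self.cluster_labels == label).mean())


def simulate_well(config: WellSimConfig) -> tuple[DropletWell, WellTruth]:
    """Draw one well from the generative droplet model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_droplets
    lam1 = config.ch1_copies / n
    lam2 = config.ch2_copies / n
    lamu = config.untargeted_mutant_copies / n

    k1 = rng.poisson(lam1, n)
    k2 = rng.poisson(lam2, n)
    ku = rng.poisson(lamu, n)

    am = config.amplitude
    pos1 = k1 > 0
    pos2 = k2 > 0
    aberr = (~pos2) & (ku > 0)  # cross-reactive signal only without true WT template

    ch1 = rng.normal(am.neg_mean, am.neg_sd, n)
    ch1[pos1] = rng.normal(am.pos_mean, am.pos_sd, pos1.sum())
    ch2 = rng.normal(am.neg_mean, am.neg_sd, n)
    ch2[pos2] = rng.normal(am.pos_mean, am.pos_sd, pos2.sum())
    ch2[aberr] = rng.normal(am.aberrant_mean(config.cross_reactivity), am.neg_sd, aberr.sum())

    labels = np.full(n, "double_negative", dtype=object)
    labels[pos1 & ~pos2] = "ch1_positive"
    labels[~pos1 & pos2] = "ch2_positive"
    labels[pos1 & pos2] = "double_positive"
    labels[~pos1 & aberr] = "aberrant"
    labels[pos1 & aberr] = "ch1_positive"

    well = DropletWell(well_id=config.well_id, assay_id=config.assay_id, ch1=ch1, ch2=ch2)
    truth = WellTruth(
        lambda_ch1=lam1, lambda_ch2=lam2, lambda_untargeted=lamu,
        occupancy_ch1=k1, occupancy_ch2=k2, occupancy_untargeted=ku,
        cluster_labels=labels.astype(str),
    )
    return well, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of a simulated tumour cohort.

    ``class_mix`` gives the joint distribution over (chromosome-3 status,
    8q dosage class); per-platform readouts are purity-weighted mixtures
    of tumour and normal copy number with Gaussian noise, reported to one
    decimal as instrument software does.  Survival times are exponential
    with per-8q-class hazard h = -ln(S5)/60 per month so the population
    five-year survival matches ``five_year_survival``.
    """

    n_tumours: int = 66
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    purity_range: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 0.1
    five_year_survival: dict = field(default_factory=lambda: dict(FIVE_YEAR_SURVIVAL))
    followup_horizon_months: float = 157.0
    censoring_rate: float = 0.004  # per month, light random loss to follow-up
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumours <= 0:
            raise ValueError("n_tumours must be positive")
        if not self.class_mix:
            raise ValueError("class_mix must not be empty")
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_mix proportions must sum to 1, got {total}")
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("purity_range must satisfy 0 <= lo <= hi <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for cls_, s5 in self.five_year_survival.items():
            if not 0.0 < s5 <= 1.0:
                raise ValueError(f"five_year_survival[{cls_!r}] must be in (0, 1]")
        if self.followup_horizon_months <= 0:
            raise ValueError("followup_horizon_months must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")


@dataclass(frozen=True)
class SimTumourTruth:
    """True state of one simulated tumour."""

    tumour_id: str
    chr3_status: str            # disomy | monosomy
    cn8q_class: str             # normal | gain | amplification
    mechanism: str              # no_aberration | trisomy_8 | isochromosome_8q | trisomy_plus_isochromosome
    cn_chr3: int
    cn_8q: int
    cn_8p: int
    purity: float


def _true_copy_numbers(rng: np.random.Generator, chr3_status: str, cn8q_class: str) -> tuple[int, int, int, str]:
    cn3 = 1 if chr3_status == "monosomy" else 2
    if cn8q_class == "normal":
        return cn3, 2, 2, "no_aberration"
    if cn8q_class == "gain":
        if rng.random() < TRISOMY_FRACTION_OF_GAIN:
            return cn3, 3, 3, "trisomy_8"
        return cn3, 3, 2, "isochromosome_8q"
    # amplification: >1 extra 8q copy, from isochromosome stacking
    cn8q = int(rng.integers(4, 7))
    if rng.random() < COMBINED_FRACTION_OF_AMP:
        return cn3, cn8q, 3, "trisomy_plus_isochromosome"
    return cn3, cn8q, 2, "isochromosome_8q"


def _observed(rng: np.random.Generator, cn: int, purity: float, noise_sd: float) -> float:
    value = purity * cn + (1.0 - purity) * 2.0 + rng.normal(0.0, noise_sd)
    return round(max(value, 0.0), 1)


def simulate_cohort(config: CohortSimConfig):
    """Draw a cohort of tumour records, survival records and truth.

    Returns ``(tumour_records, survival_records, truths)`` where the
    record types are the analysis-facing containers from
    :mod:`umdpcr.cnv` and :mod:`umdpcr.cohort`.
    """
    from .cnv import TumourRecord
    from .cohort import SurvivalRecord

    rng = np.random.default_rng(config.seed)
    classes = list(config.class_mix.keys())
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    draw = rng.choice(len(classes), size=config.n_tumours, p=probs)

    records, survival, truths = [], [], []
    for i, ci in enumerate(draw):
        chr3_status, cn8q_class = classes[ci]
        cn3, cn8q, cn8p, mechanism = _true_copy_numbers(rng, chr3_status, cn8q_class)
        lo, hi = config.purity_range
        purity = float(rng.uniform(lo, hi)) if hi > lo else lo
        tid = f"SIM-{i:04d}"
        truths.append(SimTumourTruth(
            tumour_id=tid, chr3_status=chr3_status, cn8q_class=cn8q_class,
            mechanism=mechanism, cn_chr3=cn3, cn_8q=cn8q, cn_8p=cn8p, purity=purity,
        ))
        records.append(TumourRecord(
            tumour_id=tid,
            snp_chr3=_observed(rng, cn3, purity, config.noise_sd),
            dpcr_chr3=_observed(rng, cn3, purity, config.noise_sd),
            karyotype_chr3=None,
            snp_8q=_observed(rng, cn8q, purity, config.noise_sd),
            dpcr_8q=_observed(rng, cn8q, purity, config.noise_sd),
            snp_8p=_observed(rng, cn8p, purity, config.noise_sd),
            dpcr_8p=_observed(rng, cn8p, purity, config.noise_sd),
            karyotype_chr8=None,
            reference_flagged=False,
        ))
        s5 = config.five_year_survival[cn8q_class]
        hazard = -math.log(s5) / 60.0
        t_event = rng.exponential(1.0 / hazard) if hazard > 0 else float("inf")
        t_cens = config.followup_horizon_months
        if config.censoring_rate > 0:
            t_cens = min(t_cens, rng.exponential(1.0 / config.censoring_rate))
        event = t_event <= t_cens
        months = max(min(t_event, t_cens), 1e-6)
        survival.append(SurvivalRecord(
            tumour_id=tid, months=float(months), event=bool(event),
            group=cn8q_class,
        ))
    return records, survival, truths
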