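"""File formats, packaged fixtures, configuration and the pipeline driver.

Formats
-------
* Droplet wells: CSV with header ``Ch1Amplitude,Ch2Amplitude``, one
  droplet per row (the dialect droplet-reader software exports).
* Cohort tables: CSV in the packaged reference-cohort schema
  (``tumour_id, snp_chr3, dpcr_chr3, karyotype_chr3, snp_8q, dpcr_8q,
  snp_8p, dpcr_8p, karyotype_chr8, reference_flagged``).
* Survival: CSV ``id,months,event``; results: TSV; reports and truth
  sidecars: JSON; configuration: YAML.

Two fixtures ship with the package and are integrity-checked on load: a
66-tumour uveal melanoma cohort with copy-number values from SNP array
and dPCR plus karyotype codes, and the corresponding hotspot-mutation
count summary.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .quant import (DEFAULT_DROPLET_VOLUME_NL, DropletWell, WellQuantification,
                    quantify_well)
from .cnv import CnThresholds, TumourRecord, classify_cohort
from .cohort import (SurvivalRecord, cooccurrence, platform_correlation,
                     survival_report)
from .mutations import MutationAssayResult, call_mutation_panel
from .simulate import (CohortSimConfig, FIVE_YEAR_SURVIVAL, WellSimConfig,
                       simulate_cohort, simulate_well)

logger = logging.getLogger("umdpcr")

_DATA_PACKAGE = "umdpcr.data"
COHORT_FIXTURE = "um_cohort_66.csv"
MUTATION_FIXTURE = "mutation_counts.csv"
_FIXTURE_SHA256 = {
    COHORT_FIXTURE: "8b1bfe3fc4f188d2107ecf1fb92812ff7af98cbec139b40e266affc5c9c3df57",
    MUTATION_FIXTURE: "db0bc4d8c518d4a91adace10e1c49e3e87a492be4055e7ed60c225126dec20f1",
}

#: Five-year survival per 8q class used to calibrate simulations
#: (re-exported from the simulator for report consumers).
FIVE_YEAR_SURVIVAL_CALIBRATION = dict(FIVE_YEAR_SURVIVAL)


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# Droplet CSV
# ---------------------------------------------------------------------------

DROPLET_HEADER = ["Ch1Amplitude", "Ch2Amplitude"]


def write_droplet_csv(well: DropletWell, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DROPLET_HEADER)
        for a, b in zip(well.ch1, well.ch2):
            writer.writerow([repr(float(a)), repr(float(b))])


def read_droplet_csv(path, well_id: str | None = None,
                     assay_id: str = "unknown") -> DropletWell:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"empty file: missing header {','.join(DROPLET_HEADER)}",
                             path, 1) from None
        if [h.strip() for h in header] != DROPLET_HEADER:
            raise ParseError(
                f"bad header {header!r}; expected {','.join(DROPLET_HEADER)}", path, 1)
        ch1, ch2 = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(f"expected 2 columns, got {len(row)}", path, lineno)
            try:
                ch1.append(float(row[0]))
                ch2.append(float(row[1]))
            except ValueError:
                raise ParseError(f"non-numeric amplitude {row!r}", path, lineno) from None
    if not ch1:
        raise ParseError("no droplet rows", path, 2)
    return DropletWell(well_id=well_id or path.stem, assay_id=assay_id,
                       ch1=np.array(ch1), ch2=np.array(ch2))


# ---------------------------------------------------------------------------
# Cohort / survival CSV
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["tumour_id", "snp_chr3", "dpcr_chr3", "karyotype_chr3",
                  "snp_8q", "dpcr_8q", "snp_8p", "dpcr_8p", "karyotype_chr8",
                  "reference_flagged"]


def _opt_float(s: str) -> float | None:
    s = s.strip()
    return float(s) if s else None


def _opt_int(s: str) -> int | None:
    s = s.strip()
    return int(float(s)) if s else None


def read_cohort_csv(path) -> list[TumourRecord]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != COHORT_COLUMNS:
            raise ParseError(f"bad cohort header {reader.fieldnames!r}", path, 1)
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(TumourRecord(
                    tumour_id=row["tumour_id"].strip(),
                    snp_chr3=_opt_float(row["snp_chr3"]),
                    dpcr_chr3=_opt_float(row["dpcr_chr3"]),
                    karyotype_chr3=_opt_int(row["karyotype_chr3"]),
                    snp_8q=_opt_float(row["snp_8q"]),
                    dpcr_8q=_opt_float(row["dpcr_8q"]),
                    snp_8p=_opt_float(row["snp_8p"]),
                    dpcr_8p=_opt_float(row["dpcr_8p"]),
                    karyotype_chr8=_opt_int(row["karyotype_chr8"]),
                    reference_flagged=bool(int(row["reference_flagged"])),
                ))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"malformed cohort row: {exc}", path, lineno) from None
    return records


def write_cohort_csv(records: list[TumourRecord], path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow([
                r.tumour_id,
                "" if r.snp_chr3 is None else r.snp_chr3,
                "" if r.dpcr_chr3 is None else r.dpcr_chr3,
                "" if r.karyotype_chr3 is None else r.karyotype_chr3,
                "" if r.snp_8q is None else r.snp_8q,
                "" if r.dpcr_8q is None else r.dpcr_8q,
                "" if r.snp_8p is None else r.snp_8p,
                "" if r.dpcr_8p is None else r.dpcr_8p,
                "" if r.karyotype_chr8 is None else r.karyotype_chr8,
                int(r.reference_flagged),
            ])


def read_survival_csv(path) -> list[SurvivalRecord]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "months", "event"}
        if not required.issubset(set(reader.fieldnames or [])):
            raise ParseError(f"survival header must contain {sorted(required)}", path, 1)
        out = []
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(SurvivalRecord(
                    tumour_id=row["id"].strip(),
                    months=float(row["months"]),
                    event=bool(int(row["event"])),
                    group=row.get("group", "").strip(),
                ))
            except ValueError as exc:
                raise ParseError(f"malformed survival row: {exc}", path, lineno) from None
    return out


def write_survival_csv(records: list[SurvivalRecord], path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "months", "event", "group"])
        for r in records:
            writer.writerow([r.tumour_id, repr(r.months), int(r.event), r.group])


def write_quant_tsv(quants: list[WellQuantification], path) -> None:
    """Per-well, per-channel quantification table."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["well_id", "assay_id", "channel", "lambda", "ci_low",
                         "ci_high", "copies_per_ul", "saturated",
                         "aberrant_detected", "aberrant_fraction"])
        for q in quants:
            for channel, conc in ((1, q.channel1), (2, q.channel2)):
                writer.writerow([
                    q.well_id, q.assay_id, channel,
                    f"{conc.lam:.6g}", f"{conc.ci_low:.6g}", f"{conc.ci_high:.6g}",
                    f"{conc.copies_per_microliter:.6g}", int(conc.saturated),
                    int(q.aberrant.detected), f"{q.aberrant.occupancy_fraction:.6g}",
                ])


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_path(name: str) -> Path:
    ref = resources.files(_DATA_PACKAGE).joinpath(name)
    with resources.as_file(ref) as p:
        data = p.read_bytes()
        digest = hashlib.sha256(data).hexdigest()
        if digest != _FIXTURE_SHA256[name]:
            raise RuntimeError(
                f"fixture {name} checksum mismatch ({digest}); refusing to load")
        return Path(p)


def load_cohort_fixture() -> list[TumourRecord]:
    """The packaged 66-tumour cohort with checksum verification.

    The two tumours whose chromosome-5 (TERT) region is aberrant —
    03-087 and 06-046 — carry ``reference_flagged=True``.
    """
    records = read_cohort_csv(_fixture_path(COHORT_FIXTURE))
    if len(records) != 66:
        raise RuntimeError(f"cohort fixture must have 66 records, found {len(records)}")
    flagged = {r.tumour_id for r in records if r.reference_flagged}
    if flagged != {"03-087", "06-046"}:
        raise RuntimeError(f"unexpected reference-flagged tumours: {sorted(flagged)}")
    return records


def load_mutation_counts() -> pd.DataFrame:
    """Packaged hotspot-mutation count summary (66 tumours)."""
    df = pd.read_csv(_fixture_path(MUTATION_FIXTURE))
    if int(df["n_tumours"].sum()) != 66:
        raise RuntimeError("mutation counts must sum to the 66-tumour cohort")
    return df


def mutation_summary(counts: pd.DataFrame | None = None) -> dict:
    """Mutation detection fractions from the count summary.

    Returns percentages of tumours with an exon-5 hotspot mutation and
    with any GNAQ/GNA11 mutation (exon 4 included).
    """
    df = counts if counts is not None else load_mutation_counts()
    total = int(df["n_tumours"].sum())
    mutated = df[df["gene"] != "wildtype"]
    exon5 = int(mutated.loc[mutated["exon"] == 5, "n_tumours"].sum())
    overall = int(mutated["n_tumours"].sum())
    return {
        "n_tumours": total,
        "n_exon5_mutant": exon5,
        "n_mutant": overall,
        "exon5_fraction_pct": 100.0 * exon5 / total,
        "overall_fraction_pct": 100.0 * overall / total,
    }


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Validated knobs for a full pipeline run."""

    loss_below: float = 1.9
    normal_low: float = 1.9
    normal_high: float = 2.1
    amplification_above: float = 3.1
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    confidence: float = 0.95
    aberrant_min_fraction: float = 0.01
    aberrant_min_droplets: int = 20
    aberrant_separation_sigma: float = 4.0
    min_mutant_droplets: int = 5
    reference_tolerance: float = 0.15
    n_simulated_samples: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.cn_thresholds()  # ordering check
        if not 0.5 <= self.confidence < 1.0:
            raise ValueError("confidence must be in [0.5, 1)")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be positive")
        if not 0.0 < self.aberrant_min_fraction < 1.0:
            raise ValueError("aberrant_min_fraction must be in (0, 1)")
        if self.aberrant_min_droplets < 1 or self.min_mutant_droplets < 1:
            raise ValueError("droplet minimums must be >= 1")
        if not 0.0 < self.reference_tolerance < 1.0:
            raise ValueError("reference_tolerance must be in (0, 1)")
        if self.n_simulated_samples < 1:
            raise ValueError("n_simulated_samples must be >= 1")

    def cn_thresholds(self) -> CnThresholds:
        return CnThresholds(self.loss_below, self.normal_low,
                            self.normal_high, self.amplification_above)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParseError("config must be a YAML mapping", path)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}", path)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def _sample_calls(config: PipelineConfig, seed: int) -> list[dict]:
    """Simulate mutation duplex wells per sample and call the panel."""
    panel = [("GNAQ", "Q209P"), ("GNAQ", "Q209L"), ("GNA11", "Q209L")]
    rng = np.random.default_rng(seed)
    calls = []
    for i in range(config.n_simulated_samples):
        # Alternate true variants across the panel, plus one wild-type.
        truth_variant = panel[i % len(panel)] if i % 4 != 3 else None
        tumour_fraction = float(rng.uniform(0.4, 1.0))
        results = []
        for j, (gene, variant) in enumerate(panel):
            targets = truth_variant == (gene, variant)
            mutant_present = truth_variant is not None and truth_variant[0] == gene
            cfg = WellSimConfig.mutation_assay(
                template_mass_ng=10.0,
                tumour_fraction=tumour_fraction,
                targets_mutant=targets,
                mutant_present=mutant_present,
                seed=int(rng.integers(0, 2**31 - 1)),
                well_id=f"S{i:02d}W{j}",
                assay_id=f"{gene}_{variant}",
            )
            well, _ = simulate_well(cfg)
            q = quantify_well(well, droplet_volume_nl=config.droplet_volume_nl,
                              confidence=config.confidence)
            results.append(MutationAssayResult(
                assay=q.assay_id, gene=gene, variant=variant,
                mutant=q.channel1, wildtype=q.channel2, aberrant=q.aberrant,
            ))
        call = call_mutation_panel(results,
                                   min_mutant_droplets=config.min_mutant_droplets,
                                   confidence=config.confidence)
        calls.append({
            "sample": f"S{i:02d}",
            "true_variant": "_".join(truth_variant) if truth_variant else "wildtype",
            "true_tumour_fraction": round(tumour_fraction, 4),
            "gene": call.gene, "variant": call.variant, "mode": call.mode,
            "f": round(call.mutant_fraction, 4),
            "heterogeneity": call.heterogeneity,
            "tumour_fraction": round(call.tumour_fraction, 4),
            "sequencing_recommended": call.sequencing_recommended,
        })
    return calls


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Run simulate -> quantify -> call -> cohort stages and write a report.

    Everything derives from ``seed`` (default: the config's seed), so a
    repeated run writes byte-identical outputs.  Returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    thresholds = config.cn_thresholds()

    # Stage 1: reference cohort classification and statistics.
    records = load_cohort_fixture()
    profiles = classify_cohort(records, thresholds)
    table = cooccurrence(profiles)
    corr3 = platform_correlation(records, "snp", "dpcr", "chr3")
    corr8q = platform_correlation(records, "snp", "dpcr", "8q")

    # Stage 2: simulated per-sample mutation calling.
    calls = _sample_calls(config, seed)

    # Stage 3: simulated survival stratified by 8q dosage class.
    sim_cfg = CohortSimConfig(n_tumours=300, seed=seed + 1)
    _, survival, _ = simulate_cohort(sim_cfg)
    surv = survival_report(survival)

    report = {
        "config": asdict(config),
        "seed": seed,
        "cohort": {
            "n": table.n_total,
            "monosomy3": table.margin_chr3("monosomy"),
            "8q_normal": table.margin_8q("normal"),
            "8q_gain": table.margin_8q("gain"),
            "8q_amplification": table.margin_8q("amplification"),
            "8q_aberrant": table.margin_8q("gain") + table.margin_8q("amplification"),
            "monosomy3_with_8q_aberration": table.monosomy3_with_8q_aberration,
            "monosomy3_with_normal_chr8": table.monosomy3_with_normal_chr8,
            "disomy3_with_8q_aberration": table.disomy3_with_8q_aberration,
            "mechanism_counts": {
                m: sum(1 for p in profiles if p.mechanism.mechanism == m)
                for m in ("no_aberration", "trisomy_8", "isochromosome_8q",
                          "trisomy_plus_isochromosome")
            },
        },
        "correlations": {
            "chr3_snp_vs_dpcr": {"r": round(corr3.r, 4), "p": corr3.p_value,
                                 "n": corr3.n},
            "8q_snp_vs_dpcr": {"r": round(corr8q.r, 4), "p": corr8q.p_value,
                               "n": corr8q.n},
        },
        "mutation_summary": {k: (round(v, 2) if isinstance(v, float) else v)
                             for k, v in mutation_summary().items()},
        "simulated_mutation_calls": calls,
        "simulated_survival": {
            "five_year_survival_by_8q": {
                g: round(surv.survival_at(g, 60.0), 4) for g in surv.curves
            },
            "logrank_statistic": round(surv.logrank_statistic, 4),
            "logrank_p": surv.logrank_p,
            "hazard_ratios": {k: [round(x, 4) for x in v]
                              for k, v in surv.hazard_ratios.items()},
        },
    }

    profile_rows = pd.DataFrame([{
        "tumour_id": p.tumour_id, "chr3_status": p.chr3_status,
        "cn_chr3": p.cn_chr3, "cn_8q": p.cn_8q, "cn_8p": p.cn_8p,
        "cn8q_class": p.cn8q_class, "mechanism": p.mechanism.mechanism,
        "combined_group": p.combined_group, "platform": p.platform,
    } for p in profiles])
    profile_rows.to_csv(out / "profiles.tsv", sep="\t", index=False)
    with (out / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline report written to %s", out / "report.json")
    return report
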