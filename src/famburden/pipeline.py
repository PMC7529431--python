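"""End-to-end orchestration of the family and cohort analyses.

Two entry points: :func:`run_family_analysis` (prioritization cascade +
pedigree kinship verification) and :func:`run_cohort_analysis` (carrier
enrichment / burden testing).  Both read the standard file formats,
emit machine-readable JSON (with a schema version) plus tabular TSV
reports, and are fully deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import variant_io
from .burden import BurdenConfig, BurdenResult, CohortDataset, run_burden
from .exceptions import ConfigurationError, UndefinedKinshipError
from .family_filter import CascadeResult, FilterConfig, run_cascade
from .relatedness import relatedness_matrix

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

__all__ = [
    "RunConfig",
    "run_family_analysis",
    "run_cohort_analysis",
    "load_run_config",
]


@dataclass
class RunConfig:
    """Paths, filter/burden settings and seed for a pipeline run."""

    mode: str = "both"  # family | cohort | both
    family_vcf: str | None = None
    family_ped: str | None = None
    family_annotations: str | None = None
    cohort_vcf: str | None = None
    cohort_ped: str | None = None
    cohort_annotations: str | None = None
    cohort_covariates: str | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    burden_config: BurdenConfig = field(default_factory=BurdenConfig)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("family", "cohort", "both"):
            raise ConfigurationError(f"bad mode {self.mode!r}")


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    filter_cfg = FilterConfig(**raw.pop("filter", {}))
    burden_raw = raw.pop("burden", {})
    for key in ("weights_beta", "rho_grid", "covariate_names"):
        if key in burden_raw:
            burden_raw[key] = tuple(burden_raw[key])
    burden_cfg = BurdenConfig(**burden_raw)
    return RunConfig(filter_config=filter_cfg, burden_config=burden_cfg, **raw)


def _require(path: str | None, name: str) -> str:
    if path is None:
        raise ConfigurationError(f"missing required input: {name}")
    if not Path(path).exists():
        raise ConfigurationError(f"{name} path does not exist: {path}")
    return path


def _kinship_report(genotypes, samples) -> tuple[list[dict], list[str]]:
    """All-pairs kinship plus declared-parent-offspring contradictions."""
    estimates = relatedness_matrix(genotypes)
    rows = [
        {
            "sample_i": e.sample_i,
            "sample_j": e.sample_j,
            "n_informative": e.n_informative,
            "phi": e.phi,
            "degree": e.degree,
        }
        for e in estimates
    ]
    by_pair = {tuple(sorted((e.sample_i, e.sample_j))): e for e in estimates}
    genotyped = set(genotypes.samples)
    contradictions = []
    for s in samples:
        for parent in (s.father_id, s.mother_id):
            if parent and parent in genotyped and s.sample_id in genotyped:
                est = by_pair[tuple(sorted((s.sample_id, parent)))]
                if est.degree not in ("first", "duplicate_or_MZ"):
                    contradictions.append(
                        f"declared parent-offspring pair ({parent}, {s.sample_id}) "
                        f"classified {est.degree} (phi={est.phi:.4f})"
                    )
    return rows, contradictions


def run_family_analysis(
    config: RunConfig, dataset: dict | None = None
) -> dict:
    """Cascade + kinship verification; returns the family report dict.

    ``dataset`` may supply in-memory objects (keys ``variants``,
    ``genotypes``, ``samples``, ``annotations``) instead of file paths.
    The report's ``kinship_contradictions`` list is non-empty when a
    declared parent-offspring pair is not genotypically first-degree.
    """
    if dataset is None:
        variants, genotypes = variant_io.read_vcf(_require(config.family_vcf, "family VCF"))
        samples = variant_io.read_ped(_require(config.family_ped, "family PED"))
        ann_records = variant_io.read_annotations(
            _require(config.family_annotations, "family annotations")
        )
        annotations = {tuple(r.variant_key): r for r in ann_records}
    else:
        variants = dataset["variants"]
        genotypes = dataset["genotypes"]
        samples = dataset["samples"]
        annotations = dataset["annotations"]
    if not variants:
        raise ConfigurationError("family analysis: empty variant list")

    logger.info("[family] cascade over %d variants, %d samples", len(variants), len(samples))
    cascade: CascadeResult = run_cascade(
        variants, annotations, genotypes, samples, config.filter_config
    )
    for name, frag, count, _ in cascade.steps:
        logger.info("[family] step %-18s %-28s %6d survivors", name, frag, count)

    try:
        kinship_rows, contradictions = _kinship_report(genotypes, samples)
    except UndefinedKinshipError as exc:
        kinship_rows, contradictions = [], [str(exc)]

    report = {
        "schema_version": SCHEMA_VERSION,
        "analysis": "family",
        "n_input_variants": cascade.n_input,
        "steps": cascade.to_table(),
        "candidates": [":".join(map(str, k)) for k in cascade.candidates],
        "kinship": kinship_rows,
        "kinship_contradictions": contradictions,
    }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "family_report.json", "wt", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    with open(out / "family_steps.tsv", "wt", encoding="utf-8") as fh:
        fh.write("step_name\tthreshold\tsurviving_count\n")
        for row in cascade.to_table():
            fh.write(f"{row['step_name']}\t{row['threshold']}\t{row['surviving_count']}\n")
    with open(out / "kinship.tsv", "wt", encoding="utf-8") as fh:
        fh.write("sample_i\tsample_j\tn_informative\tphi\tdegree\n")
        for r in kinship_rows:
            fh.write(
                f"{r['sample_i']}\t{r['sample_j']}\t{r['n_informative']}\t"
                f"{r['phi']:.6f}\t{r['degree']}\n"
            )
    return report


def run_cohort_analysis(config: RunConfig, dataset: dict | None = None) -> dict:
    """Burden analysis; returns the cohort report dict (JSON-serializable)."""
    if dataset is None:
        variants, genotypes = variant_io.read_vcf(_require(config.cohort_vcf, "cohort VCF"))
        samples = variant_io.read_ped(_require(config.cohort_ped, "cohort PED"))
        ann_records = variant_io.read_annotations(
            _require(config.cohort_annotations, "cohort annotations")
        )
        annotations = {tuple(r.variant_key): r for r in ann_records}
        covariates = variant_io.read_covariates(
            _require(config.cohort_covariates, "cohort covariates")
        )
        ds = CohortDataset(variants, annotations, genotypes, samples, covariates)
    else:
        ds = CohortDataset(
            dataset["variants"],
            dataset["annotations"],
            dataset["genotypes"],
            dataset["samples"],
            dataset["covariates"],
        )
    if not ds.variants:
        raise ConfigurationError("cohort analysis: empty variant list")

    burden_config = config.burden_config
    if burden_config.seed != config.seed:
        burden_config = BurdenConfig(**{**burden_config.__dict__, "seed": config.seed})
    result: BurdenResult = run_burden(ds, burden_config)
    t = result.carrier_table
    logger.info(
        "[cohort] carriers %d/%d cases vs %d/%d controls; fisher_p=%.3g skato_p=%.3g",
        t.case_carriers, t.n_cases, t.control_carriers, t.n_controls,
        result.fisher_p, result.skato_p,
    )
    report = {
        "schema_version": SCHEMA_VERSION,
        "analysis": "cohort",
        "seed": config.seed,
        **result.to_dict(),
    }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "burden.json", "wt", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    with open(out / "burden_summary.tsv", "wt", encoding="utf-8") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"case_carriers\t{t.case_carriers}/{t.n_cases}\n")
        fh.write(f"control_carriers\t{t.control_carriers}/{t.n_controls}\n")
        fh.write(f"fisher_p\t{result.fisher_p:.6g}\n")
        fh.write(f"skat_p\t{result.skat_p:.6g}\n")
        fh.write(f"skato_p\t{result.skato_p:.6g}\n")
        fh.write(f"skato_rho_hat\t{result.skato_rho_hat:g}\n")
        fh.write(f"bootstrap_min\t{result.bootstrap_summary.minimum}\n")
        fh.write(f"bootstrap_max\t{result.bootstrap_summary.maximum}\n")
        fh.write(f"bootstrap_mean\t{result.bootstrap_summary.mean:.2f}\n")
        syn = result.synonymous_control_p
        fh.write(f"synonymous_control_p\t{'NA' if syn is None else format(syn, '.6g')}\n")
    return report
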