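"""End-to-end genotyping workflows with config, manifests and logging.

Three workflows mirror the genotyping modes: ``kmer`` (emission-only,
unphased panels), ``hmm`` (Li-Stephens against a phased panel) and
``two_pass`` (k-mer pass builds a phased panel, HMM pass re-genotypes
against it).  Every run writes the resolved configuration and a staged
log to the output directory so results are reproducible from the
manifest alone.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__, vcfio
from .errors import ConfigurationError, ConsistencyError, PopccdgError, ValidationError
from .genotype import HMMParams, genotype_partition
from .kmer_index import PopulationIndex, load_index
from .panel import VariantPanel, extract_unique_kmers, load_panel
from .refine import (
    RefinerConfig,
    aggregate_partitions,
    impute_missing,
    median_confidence_filter,
    phase_cohort,
    two_pass,
)

WORKFLOWS = ("kmer", "hmm", "two_pass")


@dataclass
class RunConfig:
    workflow: str
    index_paths: list = field(default_factory=list)
    panel_path: str | None = None
    reference_path: str | None = None
    output_dir: str = "popccdg_run"
    seed: int = 0
    k: int = 31
    flank: int | None = None
    kmer_cap: int = 300
    error_rate: float = 0.01
    rho: float = 1e-6
    refiner_backend: str = "internal"
    refiner_iterations: int = 3
    refiner_command: str | None = None
    panel_haplotypes: int = 32

    def __post_init__(self):
        if self.workflow not in WORKFLOWS:
            raise ConfigurationError(
                f"workflow must be one of {WORKFLOWS}, got {self.workflow!r}"
            )

    def refiner(self) -> RefinerConfig:
        return RefinerConfig(
            backend=self.refiner_backend,
            iterations=self.refiner_iterations,
            seed=self.seed,
            command_template=self.refiner_command,
            rho=self.rho,
        )


def validate_inputs(
    cfg: RunConfig,
    indexes: list[PopulationIndex] | None = None,
    panel: VariantPanel | None = None,
) -> dict:
    """Machine-readable pre-flight report; failures never raise here."""
    failures = []
    if indexes is None:
        indexes = []
        for p in cfg.index_paths:
            try:
                indexes.append(load_index(p))
            except PopccdgError as e:
                failures.append({"check": "index_readable", "detail": str(e)})
    ks = sorted({idx.k for idx in indexes})
    if len(ks) > 1:
        failures.append(
            {"check": "index_k_congruent", "detail": f"mixed k values: {ks}"}
        )
    versions = sorted({idx.format_version for idx in indexes})
    if len(versions) > 1:
        failures.append(
            {
                "check": "index_version_congruent",
                "detail": f"mixed format versions: {versions}",
            }
        )
    ids = [sid for idx in indexes for sid in idx.sample_ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        failures.append(
            {
                "check": "sample_ids_unique",
                "detail": f"duplicated across partitions: {dupes}",
            }
        )
    if panel is None and cfg.panel_path and cfg.reference_path:
        try:
            panel = load_panel(cfg.panel_path, cfg.reference_path, k=cfg.k)
        except PopccdgError as e:
            failures.append(
                {"check": "panel_reference_consistent", "detail": str(e)}
            )
    if panel is not None:
        if cfg.workflow == "hmm" and not panel.phased:
            failures.append(
                {
                    "check": "panel_phased",
                    "detail": "hmm workflow requires a phased panel",
                }
            )
        if indexes and panel.k != indexes[0].k:
            failures.append(
                {
                    "check": "panel_index_k",
                    "detail": f"panel k={panel.k} vs index k={indexes[0].k}",
                }
            )
    return {"failures": failures, "n_indexes": len(indexes)}


def run_workflow(
    cfg: RunConfig,
    indexes: list[PopulationIndex] | None = None,
    panel: VariantPanel | None = None,
    reference=None,
):
    """Run a full genotyping workflow and write VCF + reports.

    Inputs may be pre-loaded objects (library use) or paths from the
    config (CLI use).  Returns the final phased CohortGenotypes.
    """
    log: list[dict] = []
    if indexes is None:
        indexes = [load_index(p) for p in cfg.index_paths]
    if panel is None:
        if cfg.panel_path is None or cfg.reference_path is None:
            raise ConfigurationError("panel and reference paths required")
        panel = load_panel(cfg.panel_path, cfg.reference_path, k=cfg.k, flank=cfg.flank)
        log.append({"stage": "load_panel", "loci": panel.n_loci})
    if cfg.workflow == "hmm" and not panel.phased:
        raise ConfigurationError("hmm workflow requires a phased panel")
    report = validate_inputs(cfg, indexes=indexes, panel=panel)
    if report["failures"]:
        raise ValidationError(f"input validation failed: {report['failures']}")
    if panel.allele_kmers is None:
        if reference is None:
            reference = cfg.reference_path
        if reference is None:
            raise ConfigurationError("reference required for k-mer extraction")
        panel = extract_unique_kmers(panel, reference, cap=cfg.kmer_cap)
        log.append(
            {
                "stage": "extract_unique_kmers",
                "uninformative": int(panel.uninformative_mask().sum()),
            }
        )

    refiner = cfg.refiner()
    hmm = HMMParams(rho=cfg.rho)
    if cfg.workflow == "two_pass":
        cohort = two_pass(
            panel,
            indexes,
            config=refiner,
            hmm=hmm,
            panel_haplotypes=cfg.panel_haplotypes,
            log=log,
        )
    else:
        parts = [
            genotype_partition(
                panel, idx, mode=cfg.workflow, hmm=hmm,
                error_rate=cfg.error_rate,
            )
            for idx in indexes
        ]
        log.append(
            {"stage": "genotype", "mode": cfg.workflow, "partitions": len(parts)}
        )
        cohort = aggregate_partitions(parts)
        log.append({"stage": "aggregate", "samples": cohort.n_samples})
        cohort, filt = median_confidence_filter(cohort)
        log.append({"stage": "filter", "filtered": int(filt.filtered.sum())})
        cohort = impute_missing(cohort, panel, refiner)
        log.append({"stage": "impute"})
        phase_cohort(cohort, panel, refiner)
        log.append({"stage": "phase"})

    os.makedirs(cfg.output_dir, exist_ok=True)
    out_vcf = os.path.join(cfg.output_dir, "genotypes.vcf")
    vcfio.write_cohort_vcf(
        cohort,
        out_vcf,
        phased=True,
        extra_meta={"popccdg_seed": cfg.seed, "popccdg_version": __version__},
    )
    manifest = {
        "tool": "popccdg",
        "version": __version__,
        "config": asdict(cfg),
        "stages": log,
        "n_loci": cohort.n_loci,
        "n_samples": cohort.n_samples,
    }
    with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return cohort, manifest
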