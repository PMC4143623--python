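"""End-to-end orchestration: split -> phase set 1 -> crossovers/segments ->
nonfounder matrix -> phase set 2 -> project/complement -> impute ->
(optional) mask + evaluate.  Also the in-memory engine behind the CLI."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import IQSReport, MaskRecord, evaluate_imputation, mask_cells
from .ibd import NonfounderMatrix, trace_inheritance
from .imputation import (ImputedMatrix, ImputeSource, impute_diploid,
                         imputation_yield, infer_complement, phase_set2,
                         project_to_founders)
from .matrices import MISSING, GenotypeMatrix, PhaseMatrix
from .pedigree import Pedigree, read_families, split_on_missing
from .recombination import collect_local_segments
from .simulator import SimResult
from .trio_phasing import phase_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    ped_path: str
    set1_path: str
    set2_path: str
    out_prefix: str
    conflict_policy: str = "abstain"
    mask_scheme: str | None = None      # None, "uniform_rate", "per_marker_uniform"
    mask_rate: float = 0.5
    seed: int = 0
    targets: list[str] | None = None
    unrelated_ids: list[str] | None = None


@dataclass
class PipelineResult:
    """Artifacts of one in-memory pipeline run over all (sub-)pedigrees."""

    imputed: ImputedMatrix
    nfms: list[NonfounderMatrix]
    segments: list
    events: list
    subpedigrees: list[Pedigree]
    counts: dict = field(default_factory=dict)


def impute_pedigrees(
    peds: list[Pedigree],
    set1: GenotypeMatrix,
    set2: GenotypeMatrix,
    policy: str = "abstain",
    targets: list[str] | None = None,
) -> PipelineResult:
    """Run phasing, IBD tracing and imputation for every family, splitting
    each at members lacking set 1 data, and merge the imputed columns."""
    set1_ids = set(set1.samples)
    all_targets: list[str] = []
    columns: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    nfms, all_segments, all_events, subpeds = [], [], [], []
    counts = {"trios_phased": 0, "crossovers": 0, "segments": 0,
              "cells_imputed": 0, "founder_conflicts": 0}
    for ped in peds:
        for sub in split_on_missing(ped, set1_ids):
            subpeds.append(sub)
            gm1 = set1.subset_samples(sub.ids)
            pm1, recs = phase_all(gm1, sub, require_complete=True)
            counts["trios_phased"] += len(recs)
            segments, events = collect_local_segments(sub, gm1, pm1)
            counts["crossovers"] += len(events)
            counts["segments"] += len(segments)
            nfm = trace_inheritance(sub, segments, gm1)
            present2 = [s for s in sub.ids if set2.has_sample(s)]
            gm2 = set2.subset_samples(present2)
            pm2 = phase_set2(gm2, sub)
            table = project_to_founders(pm2, nfm, gm2, sub)
            infer_complement(gm2, sub, nfm, table, policy)
            counts["founder_conflicts"] += table.n_conflicted
            sub_targets = sub.ids if targets is None else [
                t for t in targets if t in sub
            ]
            imp = impute_diploid(table, nfm, gm2, sub, sub_targets, policy)
            for j, sid in enumerate(imp.samples):
                columns[sid] = (imp.dosages[:, j], imp.source[:, j],
                                imp.haplotypes[:, j])
            nfms.append(nfm)
            all_segments.extend(segments)
            all_events.extend(events)
            all_targets.extend(imp.samples)
    all_targets = sorted(set(all_targets))
    n_m = set2.n_markers
    dosages = np.full((n_m, len(all_targets)), MISSING, np.int8)
    source = np.full((n_m, len(all_targets)),
                     ImputeSource.NOT_IMPUTABLE, np.uint8)
    haps = np.full((n_m, len(all_targets), 2), MISSING, np.int8)
    for j, sid in enumerate(all_targets):
        dosages[:, j], source[:, j], haps[:, j] = columns[sid]
    merged = ImputedMatrix(set2.markers, all_targets, dosages, source, haps)
    counts["cells_imputed"] = int((source == ImputeSource.IMPUTED).sum())
    return PipelineResult(merged, nfms, all_segments, all_events, subpeds, counts)


def dedup_overlap(set1: GenotypeMatrix, set2: GenotypeMatrix) -> GenotypeMatrix:
    """Drop set 1 markers whose (chrom, pos) also appears in set 2."""
    key2 = set(zip(set2.markers["chrom"], set2.markers["pos"]))
    keep = [
        r for r in range(set1.n_markers)
        if (set1.markers["chrom"].iloc[r], set1.markers["pos"].iloc[r]) not in key2
    ]
    if len(keep) < set1.n_markers:
        logger.info("deduplicated %d set1 markers overlapping set2",
                    set1.n_markers - len(keep))
        return GenotypeMatrix(
            set1.markers.iloc[keep].reset_index(drop=True), set1.samples,
            set1.dosages[keep],
        )
    return set1


def run_masking_experiment(
    sim: SimResult,
    scheme: str = "uniform_rate",
    rate: float = 0.5,
    seed: int = 0,
    policy: str = "abstain",
) -> tuple[ImputedMatrix, IQSReport, MaskRecord, PipelineResult]:
    """Mask set 2 cells, impute them back, and score the result.

    MAF is computed over the pedigree founders (the unrelated set);
    availability over the masked input.
    """
    masked, record = mask_cells(sim.set2, scheme=scheme, rate=rate, seed=seed)
    result = impute_pedigrees([sim.ped], sim.set1, masked, policy=policy)
    unrelated = sim.ped.founders
    report = evaluate_imputation(result.imputed, sim.set2, record, masked, unrelated)
    return result.imputed, report, record, result


def run_pipeline(cfg: RunConfig) -> dict:
    """File-to-file pipeline used by the ``run`` CLI subcommand."""
    from .recombination import crossovers_to_bed, crossovers_to_tsv, segments_to_tsv
    from .vcfio import read_vcf, write_imputed_vcf

    out = Path(cfg.out_prefix)
    out.parent.mkdir(parents=True, exist_ok=True)
    peds = read_families(cfg.ped_path)
    set1, _ = read_vcf(cfg.set1_path)
    set2, _ = read_vcf(cfg.set2_path)
    set1 = dedup_overlap(set1, set2)

    record = None
    truth_set2 = set2
    if cfg.mask_scheme:
        set2, record = mask_cells(set2, scheme=cfg.mask_scheme,
                                  rate=cfg.mask_rate, seed=cfg.seed)
        record.to_tsv(f"{cfg.out_prefix}.mask.tsv", set2.markers)

    result = impute_pedigrees(peds, set1, set2, policy=cfg.conflict_policy,
                              targets=cfg.targets)
    write_imputed_vcf(f"{cfg.out_prefix}.imputed.vcf", result.imputed, seed=cfg.seed)
    segments_to_tsv(result.segments, f"{cfg.out_prefix}.segments.tsv")
    crossovers_to_tsv(result.events, f"{cfg.out_prefix}.crossovers.tsv")
    crossovers_to_bed(result.events, f"{cfg.out_prefix}.crossovers.bed")
    for k, nfm in enumerate(result.nfms):
        nfm.to_tsv(f"{cfg.out_prefix}.nonfounder.{k}.tsv")
    y = imputation_yield(result.imputed, set2)
    y["per_individual"].to_csv(f"{cfg.out_prefix}.yield.tsv", sep="\t", index=False)

    summary = dict(result.counts)
    summary["seed"] = cfg.seed
    summary["return_on_investment_pct"] = y["return_on_investment_pct"]
    if record is not None:
        unrelated = cfg.unrelated_ids or sorted(
            {f for p in result.subpedigrees for f in p.founders}
        )
        report = evaluate_imputation(result.imputed, truth_set2, record,
                                     set2, unrelated)
        report.per_marker.to_csv(f"{cfg.out_prefix}.iqs_per_marker.tsv",
                                 sep="\t", index=False)
        report.by_maf.to_csv(f"{cfg.out_prefix}.iqs_by_maf.tsv",
                             sep="\t", index=False)
        report.by_availability.to_csv(f"{cfg.out_prefix}.iqs_by_availability.tsv",
                                      sep="\t", index=False)
        summary["mean_iqs"] = report.mean_iqs
        summary["n_reported_markers"] = report.n_reported
    with open(f"{cfg.out_prefix}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    for k, v in summary.items():
        logger.info("%s: %s", k, v)
    return summary
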