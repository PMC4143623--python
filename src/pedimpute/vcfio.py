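"""VCF reading/writing (pysam-backed, diallelic SNPs only).

Reading loads diploid GT fields into a :class:`GenotypeMatrix`; phased
("|"-separated) calls also populate a :class:`PhaseMatrix`.  Multi-allelic
and non-SNP records are skipped with a logged count.  Writing emits VCF 4.2
with "a|b" for phased cells, "a/b" otherwise and "./." for missing; imputed
matrices carry a per-genotype ``SRC`` FORMAT tag (OBS/IMP/NI/CON) and the
header records the tool version and the run seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pysam

from . import __version__
from .imputation import ImputedMatrix, ImputeSource
from .matrices import (MISSING, GenotypeMatrix, PhaseMatrix, PhaseStatus,
                       make_markers)

logger = logging.getLogger(__name__)

_SRC_CODE = {ImputeSource.OBSERVED: "OBS", ImputeSource.IMPUTED: "IMP",
             ImputeSource.NOT_IMPUTABLE: "NI", ImputeSource.CONFLICTED: "CON"}


class VCFParseError(ValueError):
    pass


def read_vcf(path) -> tuple[GenotypeMatrix, PhaseMatrix | None]:
    """Load diallelic SNP records; returns the dosage matrix and, when any
    call is phased, a phase matrix (unphased cells ambiguous)."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    chroms, poss, ids, refs, alts = [], [], [], [], []
    rows_d, rows_p = [], []
    n_skipped = 0
    any_phased = False
    for rec in vf:
        alleles = rec.alleles
        if (
            alleles is None or len(alleles) != 2
            or len(alleles[0]) != 1 or len(alleles[1]) != 1
        ):
            n_skipped += 1
            continue
        d = np.full(len(samples), MISSING, np.int8)
        p = np.full((len(samples), 2), MISSING, np.int8)
        for j, s in enumerate(samples):
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                continue
            d[j] = gt[0] + gt[1]
            if call.phased:
                any_phased = True
                p[j, 0], p[j, 1] = gt
            elif gt[0] == gt[1]:
                p[j, 0] = p[j, 1] = gt[0]
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        refs.append(alleles[0])
        alts.append(alleles[1])
        rows_d.append(d)
        rows_p.append(p)
    vf.close()
    if n_skipped:
        logger.info("skipped %d multi-allelic/non-SNP records in %s", n_skipped, path)
    markers = make_markers(np.array(chroms, object), poss, ids, refs, alts)
    dos = (np.stack(rows_d) if rows_d
           else np.empty((0, len(samples)), np.int8))
    gm = GenotypeMatrix(markers, samples, dos)
    if not any_phased:
        return gm, None
    alleles_arr = (np.stack(rows_p) if rows_p
                   else np.empty((0, len(samples), 2), np.int8))
    status = np.full(dos.shape, PhaseStatus.AMBIGUOUS, np.uint8)
    status[(alleles_arr != MISSING).all(axis=2)] = PhaseStatus.PHASED
    status[dos == MISSING] = PhaseStatus.UNPHASED_MISSING
    return gm, PhaseMatrix(markers, samples, alleles_arr, status)


def _header(gm, seed, with_src=False) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line("##fileformat=VCFv4.2")
    h.add_line(f"##source=pedimpute-{__version__}")
    if seed is not None:
        h.add_line(f"##pedimpute_seed={seed}")
    maxpos = {}
    for chrom, pos in zip(gm.markers["chrom"], gm.markers["pos"]):
        maxpos[chrom] = max(maxpos.get(chrom, 0), int(pos))
    for chrom, mp in maxpos.items():
        h.contigs.add(str(chrom), length=mp + 1000)
    h.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_src:
        h.add_line(
            '##FORMAT=<ID=SRC,Number=1,Type=String,'
            'Description="Genotype source: OBS observed, IMP imputed, '
            'NI not imputable, CON conflicted">'
        )
    for s in gm.samples if not isinstance(gm, ImputedMatrix) else gm.samples:
        h.add_sample(s)
    return h


def write_vcf(path, gm: GenotypeMatrix, phase: PhaseMatrix | None = None,
              seed: int | None = None) -> None:
    """Write a genotype matrix; cells with known phase are written "a|b"."""
    h = _header(gm, seed)
    with pysam.VariantFile(str(path), "w", header=h) as out:
        mk = gm.markers
        for r in range(gm.n_markers):
            rec = out.new_record(
                contig=str(mk["chrom"].iloc[r]), start=int(mk["pos"].iloc[r]) - 1,
                stop=int(mk["pos"].iloc[r]),
                alleles=(mk["ref"].iloc[r], mk["alt"].iloc[r]),
                id=str(mk["id"].iloc[r]),
            )
            for j, s in enumerate(gm.samples):
                d = int(gm.dosages[r, j])
                if d == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                    continue
                if phase is not None and (phase.alleles[r, j] != MISSING).all():
                    a, b = int(phase.alleles[r, j, 0]), int(phase.alleles[r, j, 1])
                    rec.samples[s]["GT"] = (a, b)
                    rec.samples[s].phased = True
                elif d in (0, 2):
                    rec.samples[s]["GT"] = (d // 2, d // 2)
                    rec.samples[s].phased = True
                else:
                    rec.samples[s]["GT"] = (0, 1)
                    rec.samples[s].phased = False
            out.write(rec)


def write_imputed_vcf(path, imp: ImputedMatrix, seed: int | None = None) -> None:
    """Write an imputed matrix with the SRC provenance tag; imputed cells are
    phased paternal|maternal, unimputable cells are './.'."""
    h = _header(imp, seed, with_src=True)
    with pysam.VariantFile(str(path), "w", header=h) as out:
        mk = imp.markers
        for r in range(len(mk)):
            rec = out.new_record(
                contig=str(mk["chrom"].iloc[r]), start=int(mk["pos"].iloc[r]) - 1,
                stop=int(mk["pos"].iloc[r]),
                alleles=(mk["ref"].iloc[r], mk["alt"].iloc[r]),
                id=str(mk["id"].iloc[r]),
            )
            for j, s in enumerate(imp.samples):
                src = ImputeSource(imp.source[r, j])
                d = int(imp.dosages[r, j])
                if d == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                elif src == ImputeSource.IMPUTED:
                    rec.samples[s]["GT"] = (int(imp.haplotypes[r, j, 0]),
                                            int(imp.haplotypes[r, j, 1]))
                    rec.samples[s].phased = True
                elif d in (0, 2):
                    rec.samples[s]["GT"] = (d // 2, d // 2)
                    rec.samples[s].phased = True
                else:
                    rec.samples[s]["GT"] = (0, 1)
                rec.samples[s]["SRC"] = _SRC_CODE[src]
            out.write(rec)
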