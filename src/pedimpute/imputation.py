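"""Diploid genotype imputation through the nonfounder matrix.

Observed dense (set 2) haploid genotypes — trio-phased alleles and split
homozygotes — are projected onto the founder chromosomes their IBD segments
trace to.  A sequenced founder's second homolog is inferred by complement
from its diploid genotype when the first is resolved.  Diploid genotypes are
then imputed for every individual by summing the two haploid genotypes on
the founder chromosomes its two slots descend from.  Disagreeing projections
make a founder allele *conflicted*; the default policy abstains from imputing
through conflicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .ibd import NonfounderMatrix
from .matrices import MISSING, GenotypeMatrix, PhaseMatrix
from .pedigree import Pedigree
from .trio_phasing import phase_all

logger = logging.getLogger(__name__)

#: resolved-allele sentinel values
UNKNOWN = -1
CONFLICT = -2


class ImputeSource(IntEnum):
    OBSERVED = 0
    IMPUTED = 1
    NOT_IMPUTABLE = 2
    CONFLICTED = 3


@dataclass
class FounderAlleleTable:
    """Haploid allele observations projected onto founder chromosomes.

    Rows are founder chromosomes (``nfm.origins`` order), columns set 2
    markers.  ``n0``/``n1`` count independent observations of allele 0/1;
    ``complemented`` marks entries added by founder complement inference;
    ``forced_conflict`` marks entries proven inconsistent.
    """

    origins: list[tuple[str, int]]
    n_markers: int
    n0: np.ndarray = field(default=None)
    n1: np.ndarray = field(default=None)
    complemented: np.ndarray = field(default=None)
    forced_conflict: np.ndarray = field(default=None)

    def __post_init__(self):
        shape = (len(self.origins), self.n_markers)
        if self.n0 is None:
            self.n0 = np.zeros(shape, np.int32)
        if self.n1 is None:
            self.n1 = np.zeros(shape, np.int32)
        if self.complemented is None:
            self.complemented = np.zeros(shape, bool)
        if self.forced_conflict is None:
            self.forced_conflict = np.zeros(shape, bool)

    def resolve(self, policy: str = "abstain") -> np.ndarray:
        """Per-entry allele: 0/1, ``UNKNOWN`` or ``CONFLICT``.

        ``abstain``: any disagreement between observations is a conflict.
        ``majority``: the majority allele wins, exact ties conflict.
        """
        out = np.full((len(self.origins), self.n_markers), UNKNOWN, np.int8)
        if policy == "abstain":
            out[(self.n0 > 0) & (self.n1 == 0)] = 0
            out[(self.n1 > 0) & (self.n0 == 0)] = 1
            out[(self.n0 > 0) & (self.n1 > 0)] = CONFLICT
        elif policy == "majority":
            out[self.n0 > self.n1] = 0
            out[self.n1 > self.n0] = 1
            out[(self.n0 == self.n1) & (self.n0 > 0)] = CONFLICT
        else:
            raise ValueError(f"unknown conflict policy {policy!r}")
        out[self.forced_conflict] = CONFLICT
        return out

    @property
    def n_conflicted(self) -> int:
        return int((self.resolve("abstain") == CONFLICT).sum())


@dataclass
class ImputedMatrix:
    """Completed set 2 matrix: observed + imputed dosages with provenance."""

    markers: pd.DataFrame
    samples: list[str]
    dosages: np.ndarray               # (n_markers, n_samples) int8
    source: np.ndarray                # ImputeSource codes
    haplotypes: np.ndarray            # (n_markers, n_samples, 2), -1 unknown

    def sample_idx(self, s: str) -> int:
        return self.samples.index(s)


def phase_set2(set2: GenotypeMatrix, ped: Pedigree) -> PhaseMatrix:
    """Phase dense genotypes: trio phasing where all three members carry
    set 2 data, homozygote splitting everywhere else."""
    dropped = [s for s in set2.samples if s not in ped]
    if dropped:
        logger.warning("%d set-2 samples not in pedigree ignored", len(dropped))
    pm, _ = phase_all(set2, ped)
    return pm


def _origin_code_matrix(
    nfm: NonfounderMatrix, set2: GenotypeMatrix, samples: list[str]
) -> np.ndarray:
    """Origin code per (marker, sample, slot); -1 where untraceable."""
    codes = np.full((set2.n_markers, len(samples), 2), -1, np.int32)
    for chrom in set2.chroms:
        rows = set2.chrom_rows(chrom)
        pos = set2.markers["pos"].to_numpy()[rows]
        for j, sid in enumerate(samples):
            for slot in (0, 1):
                codes[rows, j, slot] = nfm.origin_codes_at(sid, slot, chrom, pos)
    return codes


def project_to_founders(
    phased2: PhaseMatrix,
    nfm: NonfounderMatrix,
    set2: GenotypeMatrix,
    ped: Pedigree,
) -> FounderAlleleTable:
    """Assign every known haploid set 2 allele to the founder chromosome its
    covering IBD segment traces to; agreeing observations merge, disagreeing
    ones will resolve as conflicts."""
    table = FounderAlleleTable(nfm.origins, set2.n_markers)
    carriers = [s for s in set2.samples if s in ped]
    codes = _origin_code_matrix(nfm, set2, carriers)
    for j, sid in enumerate(carriers):
        si = phased2.sample_idx(sid)
        for slot in (0, 1):
            a = phased2.alleles[:, si, slot]
            c = codes[:, j, slot]
            ok = (a != MISSING) & (c >= 0)
            np.add.at(table.n0, (c[ok & (a == 0)], np.flatnonzero(ok & (a == 0))), 1)
            np.add.at(table.n1, (c[ok & (a == 1)], np.flatnonzero(ok & (a == 1))), 1)
    return table


def infer_complement(
    set2: GenotypeMatrix,
    ped: Pedigree,
    nfm: NonfounderMatrix,
    table: FounderAlleleTable,
    policy: str = "abstain",
) -> FounderAlleleTable:
    """Founder complement inference, iterated to a fixed point.

    For a sequenced founder with exactly one homolog resolved at a marker,
    the paired homolog's allele is the diploid dosage minus the known allele;
    an out-of-range complement proves an inconsistency and conflicts both
    homologs.
    """
    code = {o: i for i, o in enumerate(nfm.origins)}
    founders = [
        f for f in ped.founders
        if set2.has_sample(f) and (f, 0) in code and (f, 1) in code
    ]
    changed = True
    while changed:
        changed = False
        resolved = table.resolve(policy)
        for f in founders:
            ca, cb = code[(f, 0)], code[(f, 1)]
            dos = set2.dosages[:, set2.sample_idx(f)].astype(np.int16)
            for known, other in ((ca, cb), (cb, ca)):
                have = (resolved[known] >= 0) & (resolved[other] == UNKNOWN) & (dos != MISSING)
                if not have.any():
                    continue
                comp = dos[have] - resolved[known][have]
                midx = np.flatnonzero(have)
                good = (comp == 0) | (comp == 1)
                gi = midx[good]
                table.n0[other, gi[comp[good] == 0]] += 1
                table.n1[other, gi[comp[good] == 1]] += 1
                table.complemented[other, gi] = True
                bad = midx[~good]
                if len(bad):
                    table.forced_conflict[known, bad] = True
                    table.forced_conflict[other, bad] = True
                changed = True
    return table


def impute_diploid(
    table: FounderAlleleTable,
    nfm: NonfounderMatrix,
    set2: GenotypeMatrix,
    ped: Pedigree,
    targets: list[str] | None = None,
    policy: str = "abstain",
) -> ImputedMatrix:
    """Impute diploid genotypes for every target by summing the two haploid
    genotypes on the founder chromosomes its slots descend from.

    Observed genotypes are preserved verbatim; a cell is ``NOT_IMPUTABLE``
    when either slot's origin is unknown (e.g. a crossover uncertainty gap)
    or its founder allele is unresolved, and ``CONFLICTED`` when a needed
    founder allele is conflicted.
    """
    if targets is None:
        targets = ped.ids
    targets = sorted(targets)
    resolved = table.resolve(policy)
    codes = _origin_code_matrix(nfm, set2, targets)
    n_m = set2.n_markers
    dosages = np.full((n_m, len(targets)), MISSING, np.int8)
    source = np.full((n_m, len(targets)), ImputeSource.NOT_IMPUTABLE, np.uint8)
    haps = np.full((n_m, len(targets), 2), MISSING, np.int8)

    for j, sid in enumerate(targets):
        c0, c1 = codes[:, j, 0], codes[:, j, 1]
        a0 = np.where(c0 >= 0, resolved[np.clip(c0, 0, None), np.arange(n_m)], UNKNOWN)
        a1 = np.where(c1 >= 0, resolved[np.clip(c1, 0, None), np.arange(n_m)], UNKNOWN)
        both = (a0 >= 0) & (a1 >= 0)
        conf = (a0 == CONFLICT) | (a1 == CONFLICT)
        observed = np.zeros(n_m, bool)
        if set2.has_sample(sid):
            obs = set2.dosages[:, set2.sample_idx(sid)]
            observed = obs != MISSING
            dosages[observed, j] = obs[observed]
            source[observed, j] = ImputeSource.OBSERVED
        imp = both & ~observed
        dosages[imp, j] = (a0[imp] + a1[imp]).astype(np.int8)
        source[imp, j] = ImputeSource.IMPUTED
        haps[imp, j, 0] = a0[imp]
        haps[imp, j, 1] = a1[imp]
        source[conf & ~observed & ~imp, j] = ImputeSource.CONFLICTED
    return ImputedMatrix(set2.markers, targets, dosages, source, haps)


def imputation_yield(imp: ImputedMatrix, set2: GenotypeMatrix) -> dict:
    """Counts of imputed homozygous/heterozygous genotypes per individual and
    the overall return on investment (imputed / observed input cells, %)."""
    rows = []
    total_imputed = 0
    for j, sid in enumerate(imp.samples):
        m = imp.source[:, j] == ImputeSource.IMPUTED
        hom = int((m & ((imp.dosages[:, j] == 0) | (imp.dosages[:, j] == 2))).sum())
        het = int((m & (imp.dosages[:, j] == 1)).sum())
        total_imputed += hom + het
        rows.append({"individual": sid, "imputed_hom": hom, "imputed_het": het,
                     "imputed_total": hom + het})
    observed_cells = int((set2.dosages != MISSING).sum())
    roi = 100.0 * total_imputed / observed_cells if observed_cells else float("nan")
    return {
        "per_individual": pd.DataFrame(rows),
        "total_imputed": total_imputed,
        "observed_input_cells": observed_cells,
        "return_on_investment_pct": roi,
    }
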