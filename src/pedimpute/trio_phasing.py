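"""Mendelian trio phasing for diallelic markers.

Each trio/marker triple of dosages is resolved by enumerating the allele
pairs (paternal transmitted, maternal transmitted) compatible with the three
diploid genotypes: homozygotes split into two identical haploid alleles, a
unique compatible pair forces the child's phase and both transmissions, the
triple-heterozygote stays ambiguous, and incompatible triples are flagged as
Mendelian errors (recorded, never filtered).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrices import MISSING, GenotypeMatrix, PhaseMatrix, PhaseStatus
from .pedigree import Pedigree, Trio

logger = logging.getLogger(__name__)

#: transmissible alleles per parental dosage (missing parent may transmit either)
_TRANSMISSIBLE = {0: (0,), 1: (0, 1), 2: (1,), MISSING: (0, 1)}


@dataclass(frozen=True)
class TrioPhaseResult:
    """Resolution of one trio at one marker."""

    child_paternal: int       # {0,1} or MISSING
    child_maternal: int
    child_status: PhaseStatus
    father_transmitted: int   # {0,1} or MISSING
    mother_transmitted: int
    mendelian_error: bool


@dataclass(frozen=True)
class TransmissionRecord:
    """Transmitted alleles of one trio at one marker."""

    trio: Trio
    marker: int
    father_transmitted: int
    mother_transmitted: int
    mendelian_error: bool


@dataclass
class TrioTransmissions:
    """Vectorized transmission records for one trio across all markers."""

    trio: Trio
    father_transmitted: np.ndarray  # (n_markers,) int8
    mother_transmitted: np.ndarray
    mendelian_error: np.ndarray     # (n_markers,) bool

    def record(self, marker: int) -> TransmissionRecord:
        return TransmissionRecord(
            self.trio,
            marker,
            int(self.father_transmitted[marker]),
            int(self.mother_transmitted[marker]),
            bool(self.mendelian_error[marker]),
        )

    def __iter__(self):
        for m in range(len(self.father_transmitted)):
            yield self.record(m)


def phase_trio_marker(f: int, m: int, c: int) -> TrioPhaseResult:
    """Resolve a single (father, mother, child) dosage triple.

    Parameters are alternate-allele dosages in ``{0, 1, 2}`` or ``-1`` for
    missing.  Deterministic; errors are encoded in the status, not raised.
    """
    if c == MISSING:
        return TrioPhaseResult(MISSING, MISSING, PhaseStatus.UNPHASED_MISSING,
                               MISSING, MISSING, False)
    pairs = [
        (a, b)
        for a in _TRANSMISSIBLE[f]
        for b in _TRANSMISSIBLE[m]
        if a + b == c
    ]
    if not pairs:
        return TrioPhaseResult(MISSING, MISSING, PhaseStatus.MENDELIAN_ERROR,
                               MISSING, MISSING, True)
    fa = pairs[0][0] if all(p[0] == pairs[0][0] for p in pairs) else MISSING
    mo = pairs[0][1] if all(p[1] == pairs[0][1] for p in pairs) else MISSING
    if fa != MISSING and mo != MISSING:
        return TrioPhaseResult(fa, mo, PhaseStatus.PHASED, fa, mo, False)
    if c in (0, 2):  # homozygote: phase known even if a transmission is not
        return TrioPhaseResult(c // 2, c // 2, PhaseStatus.PHASED, fa, mo, False)
    return TrioPhaseResult(MISSING, MISSING, PhaseStatus.AMBIGUOUS, fa, mo, False)


def _build_tables():
    """Precompute phase_trio_marker over all 4^3 dosage triples for
    vectorized lookup (index = dosage + 1, missing first)."""
    shape = (4, 4, 4)
    cpat = np.full(shape, MISSING, np.int8)
    cmat = np.full(shape, MISSING, np.int8)
    stat = np.zeros(shape, np.uint8)
    ftr = np.full(shape, MISSING, np.int8)
    mtr = np.full(shape, MISSING, np.int8)
    merr = np.zeros(shape, bool)
    for f in (-1, 0, 1, 2):
        for m in (-1, 0, 1, 2):
            for c in (-1, 0, 1, 2):
                r = phase_trio_marker(f, m, c)
                i = (f + 1, m + 1, c + 1)
                cpat[i], cmat[i] = r.child_paternal, r.child_maternal
                stat[i] = r.child_status
                ftr[i], mtr[i] = r.father_transmitted, r.mother_transmitted
                merr[i] = r.mendelian_error
    return cpat, cmat, stat, ftr, mtr, merr


_CPAT, _CMAT, _STAT, _FTR, _MTR, _MERR = _build_tables()


def phase_all(
    gm: GenotypeMatrix,
    ped: Pedigree,
    *,
    require_complete: bool = False,
) -> tuple[PhaseMatrix, list[TrioTransmissions]]:
    """Phase every individual over all trios and markers.

    Homozygotes are split everywhere; each trio's children get forced phases;
    trios are processed in topological (ancestors-first) order and the sweep
    repeats until no locus changes.  Trios with a member absent from ``gm``
    are skipped (set 2 usage) unless ``require_complete`` is set, in which
    case their absence is an error (set 1 contract).

    Returns the phase matrix and one :class:`TrioTransmissions` per processed
    trio.
    """
    pm = PhaseMatrix.from_genotypes(gm)
    topo_rank = {iid: k for k, iid in enumerate(ped.topological_order())}
    trios = []
    for t in ped.trios:
        if all(gm.has_sample(x.id) for x in (t.father, t.mother, t.child)):
            trios.append(t)
        elif require_complete:
            raise ValueError(
                f"trio member missing from genotype matrix: "
                f"{t.father.id}/{t.mother.id}/{t.child.id}"
            )
    trios.sort(key=lambda t: (topo_rank[t.child.id], t.child.id))

    records: list[TrioTransmissions] = []
    first = True
    changed = True
    while changed:
        changed = False
        for t in trios:
            fi = gm.sample_idx(t.father.id)
            mi = gm.sample_idx(t.mother.id)
            ci = gm.sample_idx(t.child.id)
            idx = (gm.dosages[:, fi] + 1, gm.dosages[:, mi] + 1, gm.dosages[:, ci] + 1)
            cpat, cmat, stat = _CPAT[idx], _CMAT[idx], _STAT[idx]
            if first:
                records.append(
                    TrioTransmissions(t, _FTR[idx], _MTR[idx], _MERR[idx])
                )
            newly = (cpat != MISSING) & (pm.alleles[:, ci, 0] == MISSING)
            if newly.any():
                pm.alleles[newly, ci, 0] = cpat[newly]
                pm.alleles[newly, ci, 1] = cmat[newly]
                changed = True
            upgraded = (stat == PhaseStatus.PHASED) & (
                pm.status[:, ci] == PhaseStatus.AMBIGUOUS
            )
            if upgraded.any():
                pm.status[upgraded, ci] = PhaseStatus.PHASED
                changed = True
            err = stat == PhaseStatus.MENDELIAN_ERROR
            flip = err & (pm.status[:, ci] != PhaseStatus.MENDELIAN_ERROR)
            if flip.any():
                pm.status[flip, ci] = PhaseStatus.MENDELIAN_ERROR
                changed = True
        first = False
    n_err = int(sum(r.mendelian_error.sum() for r in records))
    if n_err:
        logger.info("trio phasing flagged %d Mendelian-error trio-loci", n_err)
    return pm, records
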