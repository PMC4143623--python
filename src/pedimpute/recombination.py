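"""Crossover detection and local IBD segments, one strategy per chromosome
subtype.

Chromosomes produced by two or more meioses inside the pedigree belong to
children whose transmitting parent is itself a phased trio-offspring: at every
marker where that parent is heterozygous and phased, the child's inherited
allele identifies the parental homolog (grandpaternal vs grandmaternal), and a
switch between consecutive informative markers is a crossover.

Chromosomes produced by a single meiosis are carried by founder offspring.
There the founder's phase is unknown, so offspring are dichotomized at each
founder-heterozygous marker into the two groups matching the founder's two
haploid alleles, and the minimum number of recombination events explaining
group changes between adjacent informative markers is taken (greedy
left-to-right orientation scan).  The resulting single consistent
representation of the founder's phase is its *proxy* phase (homologs A/B).

Uncertainty regions — between the flanking informative markers of a detected
crossover, and beyond the outermost informative markers of a meiosis — are
excluded from segments: no origin is ever asserted where a crossover could
hide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrices import MISSING, GenotypeMatrix, PhaseMatrix, PhaseStatus
from .pedigree import Pedigree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrossoverEvent:
    """A crossover localized to the open interval between two informative
    markers (indices local to the chromosome, bp attached)."""

    parent: str
    child: str
    chrom: str
    left_idx: int   # last informative marker before the event
    right_idx: int  # first informative marker after
    left_bp: int
    right_bp: int
    arbitrarily_assigned: bool = False


@dataclass(frozen=True)
class LocalSegment:
    """A maximal run of markers whose parental-homolog origin is constant.

    ``path`` is the 2- or 3-generation inheritance path ending at the
    carrier; ``parent_slot`` is the homolog of the direct parent
    (``path[-2]``) the segment descends from — slot 0/1 for a non-founder
    parent (paternal/maternal), proxy homolog A=0/B=1 for a founder parent.
    Intervals are half-open in chromosome-local marker index space, with bp
    bounds ``[pos(first marker), pos(last marker) + 1)``.
    """

    carrier: str
    slot: int
    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    path: tuple[str, ...]
    parent_slot: int

    def interval(self) -> tuple[int, int]:
        """Half-open bp interval."""
        return (self.start_bp, self.end_bp)


#: open-ended bp bound for chromosome-spanning segments
FULL_SPAN_BP = 2**62


@dataclass
class DichotomyTable:
    """Offspring dichotomization of a founder's informative markers.

    ``alleles[k, j]`` is the allele offspring ``offspring[j]`` inherited from
    the founder at informative marker ``marker_idx[k]`` (chromosome-local
    index), or -1 when that offspring is uninformative there.  After
    :func:`min_recomb_phase_founder` runs, ``orientation[k]`` holds the
    allele assigned to proxy homolog A and ``groups[k, j]`` the homolog
    (0=A, 1=B) carried by each offspring, -1 where uninformative.
    """

    founder: str
    chrom: str
    marker_idx: np.ndarray
    offspring: list[str]
    alleles: np.ndarray
    orientation: np.ndarray | None = None
    groups: np.ndarray | None = None


# ----------------------------------------------------------------------
# multi-meiosis strategy
# ----------------------------------------------------------------------

def _runs_to_segments(carrier, slot, chrom, inf_idx, labels, pos, path_for):
    """Split informative markers into runs of constant label; one segment per
    run, events between runs.  ``path_for(label)`` builds the segment path."""
    segments, events = [], []
    if len(inf_idx) == 0:
        return segments, events
    run_start = 0
    for k in range(1, len(inf_idx) + 1):
        if k == len(inf_idx) or labels[k] != labels[k - 1]:
            i0, i1 = int(inf_idx[run_start]), int(inf_idx[k - 1])
            lab = int(labels[run_start])
            segments.append(
                LocalSegment(
                    carrier, slot, chrom,
                    start_idx=i0, end_idx=i1 + 1,
                    start_bp=int(pos[i0]), end_bp=int(pos[i1]) + 1,
                    path=path_for(lab), parent_slot=lab,
                )
            )
            run_start = k
    return segments, events


def infer_crossovers_multi_meiosis(
    ped: Pedigree,
    gm: GenotypeMatrix,
    pm: PhaseMatrix,
    parent: str,
    child: str,
    chrom: str,
) -> tuple[list[CrossoverEvent], list[LocalSegment]]:
    """Crossovers in the ``parent -> child`` meiosis when the parent is a
    phased trio-offspring (grandparental origin of its homologs known).

    Informative markers: parent heterozygous, parent phase known, child's
    allele inherited from the parent known, and neither flagged as a
    Mendelian error.  Segments carry 3-generation paths
    (grandparent -> parent -> child).
    """
    rows = gm.chrom_rows(chrom)
    pos = gm.markers["pos"].to_numpy()[rows]
    pi, ci = gm.sample_idx(parent), gm.sample_idx(child)
    slot = 0 if ped.members[child].father_id == parent else 1
    ppat = pm.alleles[rows, pi, 0]
    pmat = pm.alleles[rows, pi, 1]
    call = pm.alleles[rows, ci, slot]
    ok = (
        (gm.dosages[rows, pi] == 1)
        & (ppat != MISSING)
        & (pmat != MISSING)
        & (ppat != pmat)
        & (call != MISSING)
        & (pm.status[rows, pi] != PhaseStatus.MENDELIAN_ERROR)
        & (pm.status[rows, ci] != PhaseStatus.MENDELIAN_ERROR)
    )
    inf = np.flatnonzero(ok)
    if len(inf) == 0:
        logger.warning(
            "no informative markers for meiosis %s -> %s on %s; "
            "no origin assigned", parent, child, chrom
        )
        return [], []
    homolog = (call[inf] != ppat[inf]).astype(np.int8)  # 0 = parent's paternal

    pind = ped.members[parent]

    def path_for(h):
        g = pind.father_id if h == 0 else pind.mother_id
        return (g, parent, child)

    segments, _ = _runs_to_segments(child, slot, chrom, inf, homolog, pos, path_for)
    events = []
    for k in np.flatnonzero(np.diff(homolog) != 0):
        li, ri = int(inf[k]), int(inf[k + 1])
        events.append(
            CrossoverEvent(parent, child, chrom, li, ri, int(pos[li]), int(pos[ri]))
        )
    return events, segments


# ----------------------------------------------------------------------
# founder-offspring strategy
# ----------------------------------------------------------------------

def dichotomize_offspring(
    ped: Pedigree,
    gm: GenotypeMatrix,
    pm: PhaseMatrix,
    founder: str,
    chrom: str,
) -> DichotomyTable:
    """Partition a founder's offspring at each informative marker by which
    founder allele they inherited.

    A marker is informative when the founder is heterozygous (and not a
    Mendelian-error locus) and at least one offspring's allele inherited from
    the founder is phased; uninformative offspring are omitted at that marker.
    """
    rows = gm.chrom_rows(chrom)
    fi = gm.sample_idx(founder)
    kids = ped.children_of(founder)
    het = (gm.dosages[rows, fi] == 1) & (
        pm.status[rows, fi] != PhaseStatus.MENDELIAN_ERROR
    )
    cols = []
    for kid in kids:
        ki = gm.sample_idx(kid)
        slot = 0 if ped.members[kid].father_id == founder else 1
        a = pm.alleles[rows, ki, slot].copy()
        a[~het] = MISSING
        a[pm.status[rows, ki] == PhaseStatus.MENDELIAN_ERROR] = MISSING
        cols.append(a)
    alleles = np.stack(cols, axis=1) if cols else np.empty((len(rows), 0), np.int8)
    informative = (alleles != MISSING).any(axis=1)
    idx = np.flatnonzero(informative)
    return DichotomyTable(founder, chrom, idx, kids, alleles[idx])


def _min_recomb_orientations(alleles: np.ndarray, sort_rank: np.ndarray):
    """Exact minimum-recombination orientation sequence by dynamic
    programming.

    ``alleles`` is the ``(n_markers, n_offspring)`` dichotomy table (-1
    where uninformative).  The hidden state is the vector of current
    offspring groups; at each marker, choosing the orientation (which
    founder allele sits on proxy homolog A) updates the groups of the
    offspring informative there, at a cost of one event per group flip
    relative to that offspring's previous informative marker.  Among minimal
    explanations, ties prefer (lexicographically) more events on earlier
    offspring in ``sort_rank`` order — which reduces, for two offspring, to
    assigning an ambiguous event to the lexicographically smaller one.

    Returns (orientation per marker, flipped offspring per marker,
    local_tie per marker, total cost).
    """
    n_m, n_off = alleles.shape
    init = (MISSING,) * n_off

    def pref(flipvec):
        # smaller key preferred: maximize flip counts on earlier offspring
        return tuple(-flipvec[j] for j in np.argsort(sort_rank))

    states: dict[tuple, tuple] = {init: (0, (0,) * n_off)}
    back: list[dict] = []
    for k in range(n_m):
        a = alleles[k]
        here = [j for j in range(n_off) if a[j] != MISSING]
        new: dict[tuple, tuple] = {}
        bk: dict[tuple, tuple] = {}
        for st in sorted(states):
            cost, fv = states[st]
            for x in (0, 1):
                g = list(st)
                flipped = []
                for j in here:
                    gj = 0 if a[j] == x else 1
                    if st[j] != MISSING and gj != st[j]:
                        flipped.append(j)
                    g[j] = gj
                nst = tuple(g)
                nfv = list(fv)
                for j in flipped:
                    nfv[j] += 1
                cand = (cost + len(flipped), tuple(nfv))
                key = (cand[0], pref(cand[1]))
                if nst not in new or key < (new[nst][0], pref(new[nst][1])):
                    new[nst] = cand
                    bk[nst] = (st, x, tuple(flipped))
        states = new
        back.append(bk)

    best = min(states, key=lambda s: (states[s][0], pref(states[s][1]), s))
    total = states[best][0]
    xs = np.zeros(n_m, np.int8)
    flips: list[tuple[int, ...]] = [()] * n_m
    st = best
    for k in range(n_m - 1, -1, -1):
        prev, x, fl = back[k][st]
        xs[k], flips[k] = x, fl
        st = prev
    # local ambiguity: equal flip counts under either orientation
    ties = []
    prev_group = np.full(n_off, MISSING, np.int8)
    for k in range(n_m):
        a = alleles[k]
        seen = (a != MISSING) & (prev_group != MISSING)
        f0 = int(((a[seen] != 0).astype(np.int8) != prev_group[seen]).sum())
        f1 = int(((a[seen] != 1).astype(np.int8) != prev_group[seen]).sum())
        ties.append(seen.any() and f0 == f1 and len(flips[k]) > 0)
        here = a != MISSING
        prev_group[here] = (a[here] != xs[k]).astype(np.int8)
    return xs, flips, ties, total


def min_recomb_phase_founder(
    ped: Pedigree,
    gm: GenotypeMatrix,
    pm: PhaseMatrix,
    table: DichotomyTable,
) -> tuple[list[CrossoverEvent], list[LocalSegment]]:
    """Minimum-recombination phasing of a founder from its dichotomy table.

    The founder-allele orientation at each informative marker (which allele
    sits on proxy homolog A) is chosen so that the *total* number of
    offspring group flips — one crossover event each — is minimal (exact
    dynamic program over offspring-group states).  Events whose offspring
    assignment is locally ambiguous (equal flip counts under either
    orientation, e.g. any event in a two-offspring family) are resolved
    toward the lexicographically smallest offspring and flagged
    ``arbitrarily_assigned``.

    Only *anchored* markers — informative for at least two offspring — can
    localize a crossover: where a single offspring is informative the
    founder's phase is constrained by that offspring alone, so its group
    there is gauge-free and asserting a boundary would be arbitrary.
    Crossovers are therefore placed between consecutive anchored markers,
    segments span anchored runs (single-informative markers strictly inside
    a run are covered), and the proxy phase at an interior single-informative
    marker follows the covering run's group.

    Writes the founder's proxy phase into ``pm`` (slot 0 = homolog A) and
    fills ``table.orientation`` / ``table.groups``.
    """
    rows = gm.chrom_rows(chrom := table.chrom)
    pos = gm.markers["pos"].to_numpy()[rows]
    fi = gm.sample_idx(table.founder)
    n_m, n_off = table.alleles.shape
    sort_rank = np.argsort(np.argsort(np.asarray(table.offspring, dtype=object)))
    anchored = (table.alleles != MISSING).sum(axis=1) >= 2
    aidx = np.flatnonzero(anchored)
    orientation = np.full(n_m, MISSING, np.int8)
    groups = np.full((n_m, n_off), MISSING, np.int8)
    events: list[CrossoverEvent] = []
    if len(aidx) == 0:
        logger.warning(
            "founder %s/%s: no markers informative for >=2 offspring; "
            "no segments attributable", table.founder, chrom,
        )
        table.orientation = orientation
        table.groups = groups
        return events, []
    xs, flips, ties, _ = _min_recomb_orientations(table.alleles[aidx], sort_rank)

    prev_marker = np.full(n_off, -1, np.int64)
    for k, row in enumerate(aidx):
        a = table.alleles[row]
        here = a != MISSING
        orientation[row] = xs[k]
        groups[row, here] = (a[here] != xs[k]).astype(np.int8)
        for j in flips[k]:
            li = int(prev_marker[j])
            ri = int(table.marker_idx[row])
            events.append(
                CrossoverEvent(
                    table.founder, table.offspring[j], chrom,
                    li, ri, int(pos[li]), int(pos[ri]),
                    arbitrarily_assigned=bool(ties[k]),
                )
            )
        prev_marker[here] = table.marker_idx[row]

    # attribute single-informative markers lying inside an anchored run
    for row in np.flatnonzero(~anchored):
        (j,) = np.flatnonzero(table.alleles[row] != MISSING)
        own = aidx[table.alleles[aidx, j] != MISSING]
        left = own[own < row]
        right = own[own > row]
        if len(left) and len(right):
            gl, gr = groups[left[-1], j], groups[right[0], j]
            if gl == gr:
                groups[row, j] = gl
                a = int(table.alleles[row, j])
                orientation[row] = a if gl == 0 else 1 - a

    # proxy phase rows for the founder: A carries orientation, B the complement
    known = orientation != MISSING
    midx = rows[table.marker_idx[known]]
    pm.alleles[midx, fi, 0] = orientation[known]
    pm.alleles[midx, fi, 1] = 1 - orientation[known]
    pm.status[midx, fi] = PhaseStatus.PHASED

    # per-offspring segments: runs of constant group over own informative markers
    segments: list[LocalSegment] = []
    for j, kid in enumerate(table.offspring):
        slot = 0 if ped.members[kid].father_id == table.founder else 1
        own = np.flatnonzero(groups[:, j] != MISSING)
        inf = table.marker_idx[own]
        labels = groups[own, j]
        segs, _ = _runs_to_segments(
            kid, slot, chrom, inf, labels, pos,
            path_for=lambda lab: (table.founder, kid),
        )
        segments.extend(segs)
    return events, segments


def proxy_phase_single_offspring(
    ped: Pedigree,
    gm: GenotypeMatrix,
    pm: PhaseMatrix,
    founder: str,
    chrom: str,
) -> list[LocalSegment]:
    """Proxy phase for a founder with exactly one offspring.

    Homolog A is *defined* as the haplotype transmitted to the offspring
    (possibly a recombinant of the founder's true homologs — genotype flow is
    unaffected), homolog B as its complement given the founder's diploid
    dosage.  The offspring's whole slot is one chromosome-spanning segment on
    homolog A and no crossover events are emitted.
    """
    (kid,) = ped.children_of(founder)
    rows = gm.chrom_rows(chrom)
    fi, ki = gm.sample_idx(founder), gm.sample_idx(kid)
    slot = 0 if ped.members[kid].father_id == founder else 1
    a = pm.alleles[rows, ki, slot]
    dos = gm.dosages[rows, fi]
    known = (a != MISSING) & (pm.status[rows, ki] != PhaseStatus.MENDELIAN_ERROR)
    comp = dos - a
    ok = known & (dos != MISSING) & ((comp == 0) | (comp == 1))
    midx = rows[ok]
    pm.alleles[midx, fi, 0] = a[ok]
    pm.alleles[midx, fi, 1] = comp[ok].astype(np.int8)
    pm.status[midx, fi] = PhaseStatus.PHASED
    n_bad = int((known & (dos != MISSING) & ~((comp == 0) | (comp == 1))).sum())
    if n_bad:
        logger.info(
            "proxy phase %s/%s: %d loci inconsistent with founder dosage",
            founder, chrom, n_bad,
        )
    return [
        LocalSegment(
            kid, slot, chrom,
            start_idx=0, end_idx=len(rows),
            start_bp=0, end_bp=FULL_SPAN_BP,
            path=(founder, kid), parent_slot=0,
        )
    ]


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

def collect_local_segments(
    ped: Pedigree,
    gm: GenotypeMatrix,
    pm: PhaseMatrix,
) -> tuple[list[LocalSegment], list[CrossoverEvent]]:
    """Run the appropriate strategy for every meiosis in the pedigree.

    Founder parents get the dichotomization / minimum-recombination (or
    single-offspring proxy) strategy; non-founder parents the multi-meiosis
    informative-marker strategy.  Also fills founder proxy phases in ``pm``.
    """
    segments: list[LocalSegment] = []
    events: list[CrossoverEvent] = []
    for chrom in gm.chroms:
        for founder in ped.founders:
            kids = ped.children_of(founder)
            if not kids:
                continue
            if len(kids) == 1:
                segments.extend(
                    proxy_phase_single_offspring(ped, gm, pm, founder, chrom)
                )
            else:
                table = dichotomize_offspring(ped, gm, pm, founder, chrom)
                if len(table.marker_idx) == 0:
                    logger.warning(
                        "founder %s has no informative markers on %s", founder, chrom
                    )
                    continue
                ev, segs = min_recomb_phase_founder(ped, gm, pm, table)
                events.extend(ev)
                segments.extend(segs)
        for parent in ped.nonfounders:
            for child in ped.children_of(parent):
                ev, segs = infer_crossovers_multi_meiosis(
                    ped, gm, pm, parent, child, chrom
                )
                events.extend(ev)
                segments.extend(segs)
    return segments, events


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------

def segments_to_tsv(segments, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "chrom": s.chrom, "start_bp": s.start_bp, "end_bp": s.end_bp,
                "start_idx": s.start_idx, "end_idx": s.end_idx,
                "carrier": s.carrier, "slot": s.slot,
                "path": ",".join(s.path), "parent_slot": s.parent_slot,
            }
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)


def crossovers_to_tsv(events, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "chrom": e.chrom, "start_bp": e.left_bp, "end_bp": e.right_bp,
                "start_idx": e.left_idx, "end_idx": e.right_idx,
                "parent": e.parent, "child": e.child,
                "arbitrarily_assigned": e.arbitrarily_assigned,
            }
            for e in events
        ]
    ).to_csv(path, sep="\t", index=False)


def crossovers_to_bed(events, path) -> None:
    """Crossover uncertainty intervals as BED (0-based half-open bp)."""
    with open(path, "w") as fh:
        for e in events:
            name = f"{e.parent}>{e.child}"
            fh.write(f"{e.chrom}\t{e.left_bp - 1}\t{e.right_bp}\t{name}\n")
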