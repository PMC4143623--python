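"""Pedigree data model: parsing, validation, trios, founders, splitting.

A pedigree is a set of individuals with father/mother links.  Founders are
members with no parents inside the pedigree; their chromosomes are the
"founding chromosomes" every identical-by-descent segment ultimately traces
back to.  Individuals with exactly one in-pedigree parent have both links
severed and are treated as founders: the trio machinery needs both parents,
and the method gives no half-trio rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

logger = logging.getLogger(__name__)


class PedigreeError(ValueError):
    """Base class for pedigree parse/validation errors."""


class DuplicateIndividualError(PedigreeError):
    pass


class OwnAncestorError(PedigreeError):
    """An individual appears in its own ancestor chain."""


class UnknownParentError(PedigreeError):
    """A parent id is referenced but absent and not coded missing ('0')."""


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = 0  # 1 male, 2 female, 0 unknown
    family: str = "1"


@dataclass(frozen=True)
class Trio:
    father: Individual
    mother: Individual
    child: Individual


@dataclass(frozen=True)
class ChromosomeClass:
    """Meiosis-count classification of one haplotype slot.

    ``meiosis_count`` is the number of meioses within the pedigree separating
    the slot from the nearest founding chromosome: 0 for founder slots, 1 for
    slots inherited from a founder parent ("single meiosis"), >= 2 otherwise.
    """

    individual: str
    slot: int  # 0 paternal, 1 maternal
    meiosis_count: int


class Pedigree:
    """A validated single-family pedigree.

    Parent links referencing non-members, or present for only one parent,
    are severed in pairs at construction; such children become founders.
    """

    def __init__(self, individuals, family: str | None = None):
        members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in members:
                raise DuplicateIndividualError(f"duplicate individual id {ind.id!r}")
            members[ind.id] = ind
        # sever incomplete parent pairs (both-or-nothing rule)
        for iid, ind in list(members.items()):
            fa, mo = ind.father_id, ind.mother_id
            if fa not in members or mo not in members or fa is None or mo is None:
                if (fa is not None and fa in members) or (mo is not None and mo in members):
                    logger.warning(
                        "individual %s has a single in-pedigree parent; "
                        "severing both links and treating as founder", iid
                    )
                members[iid] = replace(ind, father_id=None, mother_id=None)
        self.members = members
        self.family = family if family is not None else next(
            (i.family for i in members.values()), "1"
        )
        self._check_acyclic()
        self._children: dict[str, list[str]] = {i: [] for i in members}
        for ind in members.values():
            if ind.father_id is not None:
                self._children[ind.father_id].append(ind.id)
                self._children[ind.mother_id].append(ind.id)
        for v in self._children.values():
            v.sort()

    # -- validation ------------------------------------------------------
    def _check_acyclic(self):
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(iid: str):
            stack = [(iid, iter(self._parents_of(iid)))]
            state[iid] = 0
            while stack:
                cur, it = stack[-1]
                nxt = next(it, None)
                if nxt is None:
                    state[cur] = 1
                    stack.pop()
                    continue
                if state.get(nxt) == 0:
                    raise OwnAncestorError(f"individual {nxt!r} is its own ancestor")
                if nxt not in state:
                    state[nxt] = 0
                    stack.append((nxt, iter(self._parents_of(nxt))))

        for iid in self.members:
            if iid not in state:
                visit(iid)

    def _parents_of(self, iid: str) -> list[str]:
        ind = self.members[iid]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None]

    # -- structure accessors ---------------------------------------------
    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __len__(self) -> int:
        return len(self.members)

    @property
    def ids(self) -> list[str]:
        return sorted(self.members)

    def is_founder(self, iid: str) -> bool:
        ind = self.members[iid]
        return ind.father_id is None and ind.mother_id is None

    @property
    def founders(self) -> list[str]:
        return sorted(i for i in self.members if self.is_founder(i))

    @property
    def nonfounders(self) -> list[str]:
        return sorted(i for i in self.members if not self.is_founder(i))

    def children_of(self, iid: str) -> list[str]:
        return list(self._children[iid])

    def parent_of_slot(self, iid: str, slot: int) -> str | None:
        """The transmitting parent of an individual's slot (0=paternal)."""
        ind = self.members[iid]
        return ind.father_id if slot == 0 else ind.mother_id

    @property
    def trios(self) -> list[Trio]:
        return find_trios(self)

    def topological_order(self) -> list[str]:
        """Members ordered so that parents precede children (ties by id)."""
        depth: dict[str, int] = {}

        def d(iid: str) -> int:
            if iid not in depth:
                ps = self._parents_of(iid)
                depth[iid] = 0 if not ps else 1 + max(d(p) for p in ps)
            return depth[iid]

        return sorted(self.members, key=lambda i: (d(i), i))


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def find_trios(ped: Pedigree) -> list[Trio]:
    """One trio per child with both parents in the pedigree, sorted by child id."""
    out = []
    for iid in ped.ids:
        ind = ped.members[iid]
        if ind.father_id is not None and ind.mother_id is not None:
            out.append(Trio(ped.members[ind.father_id], ped.members[ind.mother_id], ind))
    return out


def classify_chromosomes(ped: Pedigree) -> list[ChromosomeClass]:
    """Classify every haplotype slot by its within-pedigree meiosis count.

    A slot inherited from a founder parent is the product of a single meiosis
    (count 1); a slot inherited from a non-founder parent has count
    ``1 + min`` over the parent's own slot counts, i.e. the edge distance to
    the nearest founding chromosome.
    """
    depth: dict[str, int] = {}

    def d(iid: str) -> int:
        # min #meioses from iid's genome back to a founding chromosome
        if iid not in depth:
            if ped.is_founder(iid):
                depth[iid] = 0
            else:
                ind = ped.members[iid]
                depth[iid] = 1 + min(d(ind.father_id), d(ind.mother_id))
        return depth[iid]

    out = []
    for iid in ped.ids:
        if ped.is_founder(iid):
            out.append(ChromosomeClass(iid, 0, 0))
            out.append(ChromosomeClass(iid, 1, 0))
        else:
            ind = ped.members[iid]
            out.append(ChromosomeClass(iid, 0, 1 + d(ind.father_id)))
            out.append(ChromosomeClass(iid, 1, 1 + d(ind.mother_id)))
    return out


def split_on_missing(ped: Pedigree, genotyped_ids) -> list[Pedigree]:
    """Break a pedigree at individuals lacking framework (set 1) data.

    Returns the maximal connected sub-pedigrees of genotyped individuals.
    Connectivity is through trio edges: a child is linked to its parents only
    when the child and *both* parents are genotyped; otherwise the links are
    severed in pairs and the child founds its sub-pedigree.  Sub-pedigrees are
    ordered by their smallest member id.
    """
    genotyped_ids = set(genotyped_ids)
    extra = genotyped_ids - set(ped.members)
    if extra:
        logger.warning("%d genotyped ids not in pedigree %s ignored", len(extra), ped.family)
    keep = genotyped_ids & set(ped.members)
    if not keep:
        logger.warning("no genotyped individuals in pedigree %s", ped.family)
        return []

    # adjacency through complete genotyped trios
    adj: dict[str, set[str]] = {i: set() for i in keep}
    for iid in keep:
        ind = ped.members[iid]
        fa, mo = ind.father_id, ind.mother_id
        if fa in keep and mo in keep:
            adj[iid] |= {fa, mo}
            adj[fa].add(iid)
            adj[mo].add(iid)
            adj[fa].add(mo)
            adj[mo].add(fa)

    seen: set[str] = set()
    comps: list[list[str]] = []
    for iid in sorted(keep):
        if iid in seen:
            continue
        comp, stack = [], [iid]
        seen.add(iid)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        comps.append(sorted(comp))

    out = []
    for comp in comps:
        cset = set(comp)
        inds = []
        for iid in comp:
            ind = ped.members[iid]
            if ind.father_id in cset and ind.mother_id in cset:
                inds.append(ind)
            else:
                inds.append(replace(ind, father_id=None, mother_id=None))
        out.append(Pedigree(inds, family=ped.family))
    return out


# ----------------------------------------------------------------------
# PED/FAM I/O
# ----------------------------------------------------------------------

def _parse_ped_lines(lines) -> dict[str, list[Individual]]:
    families: dict[str, list[Individual]] = {}
    ids_by_family: dict[str, set[str]] = {}
    for ln, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 5:
            raise PedigreeError(f"line {ln}: expected >=5 whitespace-delimited columns")
        fam, iid, fa, mo, sex = fields[:5]
        try:
            sex_i = int(sex)
        except ValueError:
            sex_i = 0
        if sex_i not in (0, 1, 2):
            sex_i = 0
        ind = Individual(
            id=iid,
            father_id=None if fa == "0" else fa,
            mother_id=None if mo == "0" else mo,
            sex=sex_i,
            family=fam,
        )
        if iid in ids_by_family.setdefault(fam, set()):
            raise DuplicateIndividualError(f"line {ln}: duplicate individual id {iid!r}")
        ids_by_family[fam].add(iid)
        families.setdefault(fam, []).append(ind)
    # referenced parents must be present or coded missing
    for fam, inds in families.items():
        present = ids_by_family[fam]
        for ind in inds:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in present:
                    raise UnknownParentError(
                        f"family {fam}: parent {pid!r} of {ind.id!r} not in file"
                    )
    return families


def read_families(path) -> list[Pedigree]:
    """Read a whitespace-delimited PED/FAM file into one Pedigree per family."""
    with open(path) as fh:
        families = _parse_ped_lines(fh)
    return [Pedigree(inds, family=fam) for fam, inds in sorted(families.items())]


def read_pedigree(path) -> Pedigree:
    """Read a single-family PED/FAM file into a validated Pedigree."""
    peds = read_families(path)
    if len(peds) != 1:
        raise PedigreeError(
            f"{path} contains {len(peds)} families; use read_families()"
        )
    return peds[0]


def write_ped(ped: Pedigree, path) -> None:
    """Write a pedigree in the 6-column PED dialect (phenotype = 0)."""
    path = Path(path)
    with open(path, "w") as fh:
        for iid in ped.ids:
            ind = ped.members[iid]
            fh.write(
                f"{ped.family}\t{iid}\t{ind.father_id or 0}\t{ind.mother_id or 0}"
                f"\t{ind.sex}\t0\n"
            )
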