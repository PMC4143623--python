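"""Recursive tracing of local IBD segments to founder chromosomes.

The *nonfounder matrix* is the central queryable structure: every segment of
every phased chromosome in the pedigree, expressed as an interval with a full
path of inheritance starting at a specific founder homolog.  It is built by a
depth-first traversal from each founding chromosome: at each meiosis the
intervals known to descend along the current path are intersected with the
child's local segments attributed to the transmitting parent's current
homolog, and surviving intervals extend the path one generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import GenotypeMatrix
from .pedigree import Pedigree
from .recombination import FULL_SPAN_BP, LocalSegment

logger = logging.getLogger(__name__)

#: (founder id, homolog index) — homolog 0 = proxy A, 1 = proxy B
FounderChromosomeId = tuple[str, int]


def intersect_intervals(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int] | None:
    """Half-open interval intersection; ``None`` when empty."""
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if lo < hi else None


@dataclass(frozen=True)
class IBDSegment:
    """A chromosome interval traced to an exact founder chromosome."""

    carrier: str
    slot: int
    chrom: str
    start_bp: int
    end_bp: int
    path: tuple[str, ...]          # founder ... carrier
    origin: FounderChromosomeId

    def interval(self) -> tuple[int, int]:
        return (self.start_bp, self.end_bp)


class NonfounderMatrix:
    """Queryable collection of :class:`IBDSegment`.

    Indexes segments by ``(carrier, slot, chrom)``; overlapping same-origin
    segments (possible with inbreeding loops) are merged for querying, and
    any residual overlap of *different* origins is treated as unknown.
    """

    def __init__(self, segments: list[IBDSegment]):
        self.segments = list(segments)
        origins = sorted({s.origin for s in segments})
        self.origins: list[FounderChromosomeId] = origins
        self._origin_code = {o: i for i, o in enumerate(origins)}
        self._index: dict[tuple[str, int, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        buckets: dict[tuple[str, int, str], dict[int, list[tuple[int, int]]]] = {}
        for s in segments:
            key = (s.carrier, s.slot, s.chrom)
            buckets.setdefault(key, {}).setdefault(
                self._origin_code[s.origin], []
            ).append(s.interval())
        for key, per_origin in buckets.items():
            ivals: list[tuple[int, int, int]] = []
            for code, lst in per_origin.items():
                for lo, hi in _merge_intervals(lst):
                    ivals.append((lo, hi, code))
            ivals.sort()
            # drop regions covered by >1 distinct origin (inconsistent data)
            clean: list[tuple[int, int, int]] = []
            for lo, hi, code in ivals:
                if clean and lo < clean[-1][1]:
                    logger.warning(
                        "overlapping segments with different origins for %s; "
                        "overlap treated as unknown", key,
                    )
                    prev = clean.pop()
                    if prev[0] < lo:
                        clean.append((prev[0], lo, prev[2]))
                    if prev[1] < hi:
                        clean.append((prev[1], hi, code))
                else:
                    clean.append((lo, hi, code))
            starts = np.array([c[0] for c in clean], dtype=np.int64)
            ends = np.array([c[1] for c in clean], dtype=np.int64)
            codes = np.array([c[2] for c in clean], dtype=np.int32)
            self._index[key] = (starts, ends, codes)

    # -- queries ---------------------------------------------------------
    def origin_code(self, origin: FounderChromosomeId) -> int:
        return self._origin_code[origin]

    def origin_codes_at(
        self, carrier: str, slot: int, chrom: str, positions: np.ndarray
    ) -> np.ndarray:
        """Vectorized origin lookup: code per position, -1 where unknown."""
        out = np.full(len(positions), -1, dtype=np.int32)
        entry = self._index.get((carrier, slot, chrom))
        if entry is None:
            return out
        starts, ends, codes = entry
        k = np.searchsorted(starts, positions, side="right") - 1
        ok = (k >= 0) & (positions < ends[np.clip(k, 0, len(ends) - 1)])
        out[ok] = codes[k[ok]]
        return out

    def query_origin(
        self, carrier: str, slot: int, chrom: str, position: int
    ) -> FounderChromosomeId | None:
        """Origin of the covering segment, or ``None`` inside an uncertainty
        gap (or off any traced segment)."""
        code = self.origin_codes_at(
            carrier, slot, chrom, np.asarray([position], dtype=np.int64)
        )[0]
        return None if code < 0 else self.origins[code]

    def segments_for(self, carrier: str, chrom: str | None = None) -> list[IBDSegment]:
        return [
            s for s in self.segments
            if s.carrier == carrier and (chrom is None or s.chrom == chrom)
        ]

    def shared_ibd(
        self, id1: str, id2: str, chrom: str
    ) -> list[tuple[tuple[int, int], FounderChromosomeId]]:
        """Intervals where any slot of ``id1`` and any slot of ``id2`` trace
        to the same founder chromosome."""
        out = []
        for s1 in self.segments_for(id1, chrom):
            for s2 in self.segments_for(id2, chrom):
                if s1.origin != s2.origin:
                    continue
                iv = intersect_intervals(s1.interval(), s2.interval())
                if iv is not None:
                    out.append((iv, s1.origin))
        # merge duplicates per origin
        merged: dict[FounderChromosomeId, list[tuple[int, int]]] = {}
        for iv, o in out:
            merged.setdefault(o, []).append(iv)
        result = []
        for o in sorted(merged):
            for iv in _merge_intervals(merged[o]):
                result.append((iv, o))
        result.sort(key=lambda t: (t[0], t[1]))
        return result

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "carrier": s.carrier, "slot": s.slot, "chrom": s.chrom,
                "start_bp": s.start_bp, "end_bp": s.end_bp,
                "origin_founder": s.origin[0], "origin_homolog": "AB"[s.origin[1]],
                "path": ",".join(s.path),
            }
            for s in self.segments
        ]
        df = pd.DataFrame(
            rows,
            columns=["carrier", "slot", "chrom", "start_bp", "end_bp",
                     "origin_founder", "origin_homolog", "path"],
        )
        return df.sort_values(
            ["carrier", "slot", "chrom", "start_bp", "end_bp", "path"]
        ).reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NonfounderMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"carrier": str, "chrom": str,
                                                "origin_founder": str, "path": str})
        segs = [
            IBDSegment(
                str(r.carrier), int(r.slot), str(r.chrom),
                int(r.start_bp), int(r.end_bp),
                tuple(str(r.path).split(",")),
                (str(r.origin_founder), "AB".index(r.origin_homolog)),
            )
            for r in df.itertuples()
        ]
        return cls(segs)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge touching/overlapping half-open intervals."""
    out: list[tuple[int, int]] = []
    for lo, hi in sorted(ivals):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def trace_inheritance(
    ped: Pedigree,
    local: list[LocalSegment],
    gm: GenotypeMatrix | None = None,
) -> NonfounderMatrix:
    """Build the nonfounder matrix from local segments.

    Depth-first (explicit work stack, no recursion-depth limit) from each
    founder homolog: at each meiosis the current intervals are intersected
    with the child's local segments attributed to the current parent homolog;
    non-empty intersections extend the path.  Founders' own chromosomes are
    emitted as chromosome-spanning segments with length-1 paths.
    """
    by_edge: dict[tuple[str, str, int, str], list[LocalSegment]] = {}
    chroms: set[str] = set()
    for s in local:
        by_edge.setdefault((s.chrom, s.path[-2], s.parent_slot, s.carrier), []).append(s)
        chroms.add(s.chrom)
    if gm is not None:
        chroms.update(gm.chroms)

    out: list[IBDSegment] = []
    for chrom in sorted(chroms):
        for founder in ped.founders:
            for h in (0, 1):
                origin = (founder, h)
                out.append(
                    IBDSegment(founder, h, chrom, 0, FULL_SPAN_BP, (founder,), origin)
                )
                stack: list[tuple[str, int, list[tuple[int, int]], tuple[str, ...]]] = [
                    (founder, h, [(0, FULL_SPAN_BP)], (founder,))
                ]
                while stack:
                    pid, pslot, intervals, path = stack.pop()
                    for child in ped.children_of(pid):
                        cslot = 0 if ped.members[child].father_id == pid else 1
                        segs = by_edge.get((chrom, pid, pslot, child))
                        if not segs:
                            continue
                        pieces: list[tuple[int, int]] = []
                        for seg in segs:
                            for iv in intervals:
                                got = intersect_intervals(seg.interval(), iv)
                                if got is not None:
                                    pieces.append(got)
                        if not pieces:
                            continue
                        pieces = _merge_intervals(pieces)
                        newpath = path + (child,)
                        for lo, hi in pieces:
                            out.append(
                                IBDSegment(child, cslot, chrom, lo, hi, newpath, origin)
                            )
                        stack.append((child, cslot, pieces, newpath))
    return NonfounderMatrix(out)
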