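"""Core in-memory containers: diploid genotype matrices and phase matrices.

Genotypes are stored as alternate-allele dosages in ``{0, 1, 2}`` with ``-1``
for missing, markers in rows and individuals in columns.  Phase is stored as
two ordered haploid allele tracks per individual: slot 0 is the paternal
allele and slot 1 the maternal allele for non-founders; for pedigree founders
the two slots hold the proxy homologs A and B produced by founder phasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

#: sentinel for a missing dosage or an unknown haploid allele
MISSING = -1

MARKER_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class PhaseStatus(IntEnum):
    """Per-locus, per-individual phase resolution status."""

    AMBIGUOUS = 0          # heterozygote not (yet) resolved by Mendelian logic
    PHASED = 1             # both haploid alleles known
    UNPHASED_MISSING = 2   # underlying diploid genotype missing
    MENDELIAN_ERROR = 3    # trio logic found the genotypes inconsistent


def make_markers(chrom, pos, ids=None, ref=None, alt=None) -> pd.DataFrame:
    """Assemble a marker table with the canonical columns."""
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    chrom = np.broadcast_to(np.asarray(chrom, dtype=object), (n,))
    if ids is None:
        ids = [f"{c}:{p}" for c, p in zip(chrom, pos)]
    if ref is None:
        ref = ["A"] * n
    if alt is None:
        alt = ["G"] * n
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "id": ids, "ref": ref, "alt": alt}
    )


@dataclass
class GenotypeMatrix:
    """Markers x individuals alternate-allele dosage matrix.

    Parameters
    ----------
    markers
        DataFrame with columns ``chrom, pos, id, ref, alt``; positions must be
        strictly increasing within each chromosome.
    samples
        Ordered individual identifiers (column labels).
    dosages
        ``(n_markers, n_samples)`` int8 array over ``{-1, 0, 1, 2}``.
    """

    markers: pd.DataFrame
    samples: list[str]
    dosages: np.ndarray
    _sample_idx: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.dosages, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")
        for chrom in self.chroms:
            p = self.markers.loc[self.markers.chrom == chrom, "pos"].to_numpy()
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        if len(self._sample_idx) != len(self.samples):
            raise ValueError("duplicate sample ids")

    # -- basic accessors -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chroms(self) -> list[str]:
        seen, out = set(), []
        for c in self.markers["chrom"]:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def sample_idx(self, sample: str) -> int:
        return self._sample_idx[sample]

    def has_sample(self, sample: str) -> bool:
        return sample in self._sample_idx

    def chrom_rows(self, chrom) -> np.ndarray:
        """Row indices of all markers on ``chrom`` (in position order)."""
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())

    def positions(self, chrom) -> np.ndarray:
        return self.markers["pos"].to_numpy()[self.chrom_rows(chrom)]

    # -- derived matrices ------------------------------------------------
    def subset_samples(self, samples) -> "GenotypeMatrix":
        idx = [self._sample_idx[s] for s in samples]
        return GenotypeMatrix(self.markers.copy(), list(samples), self.dosages[:, idx].copy())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.markers.copy(), list(self.samples), self.dosages.copy())


@dataclass
class PhaseMatrix:
    """Two ordered haploid allele tracks per individual plus per-locus status.

    ``alleles`` has shape ``(n_markers, n_samples, 2)`` over ``{-1, 0, 1}``;
    ``status`` has shape ``(n_markers, n_samples)`` with :class:`PhaseStatus`
    codes.
    """

    markers: pd.DataFrame
    samples: list[str]
    alleles: np.ndarray
    status: np.ndarray
    _sample_idx: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.samples = list(self.samples)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.status = np.asarray(self.status, dtype=np.uint8)
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}

    @classmethod
    def from_genotypes(cls, gm: GenotypeMatrix) -> "PhaseMatrix":
        """Initialize phase from dosages alone: homozygotes split into two
        identical haploid alleles, heterozygotes start ambiguous."""
        alleles = np.full((gm.n_markers, gm.n_samples, 2), MISSING, dtype=np.int8)
        status = np.full((gm.n_markers, gm.n_samples), PhaseStatus.AMBIGUOUS, dtype=np.uint8)
        d = gm.dosages
        status[d == MISSING] = PhaseStatus.UNPHASED_MISSING
        for hom, allele in ((0, 0), (2, 1)):
            m = d == hom
            alleles[m] = allele
            status[m] = PhaseStatus.PHASED
        return cls(gm.markers, gm.samples, alleles, status)

    def sample_idx(self, sample: str) -> int:
        return self._sample_idx[sample]

    def has_sample(self, sample: str) -> bool:
        return sample in self._sample_idx

    def chrom_rows(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())

    def dosage_consistent(self, gm: GenotypeMatrix) -> bool:
        """True when every fully known allele pair sums to the diploid dosage."""
        known = (self.alleles != MISSING).all(axis=2)
        s = self.alleles[..., 0].astype(np.int16) + self.alleles[..., 1]
        ok = ~known | (gm.dosages == MISSING) | (s == gm.dosages)
        return bool(ok.all())

    def copy(self) -> "PhaseMatrix":
        return PhaseMatrix(self.markers, list(self.samples), self.alleles.copy(), self.status.copy())
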