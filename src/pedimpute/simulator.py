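"""Gene-dropping synthetic data: pedigrees, founder haplotypes, crossovers.

Founder haplotypes are drawn marker-by-marker from a minor-allele-frequency
spectrum (a rare-skewed Beta component mixed with a uniform common-variant
component, so every MAF bin is populated).  Gametes are formed under a
Haldane (no-interference) model: the crossover count of each meiosis is
Poisson with mean equal to the map length in Morgans and positions are
uniform on a uniform genetic map.  Every simulation records the full truth —
haplotypes, founder origins per position, crossovers per meiosis — for use
as an oracle.

The sparse framework ("set 1") markers sit on a uniform grid; the dense
payload ("set 2") markers are uniform-random at distinct other positions, so
they fall both inside and between IBD-segment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrices import MISSING, GenotypeMatrix, make_markers
from .pedigree import Individual, Pedigree, write_ped

__all__ = [
    "SimConfig", "SimTruth", "SimResult", "figure1_like_pedigree",
    "random_pedigree", "simulate_founder_haplotypes", "gene_drop",
    "corrupt", "simulate_dataset", "write_fixture",
]


@dataclass
class SimConfig:
    """Simulation parameters (defaults build the packaged demo fixture)."""

    chrom: str = "1"
    length_bp: int = 100_000_000
    morgans: float = 1.0
    n_set1: int = 500
    n_set2: int = 2000
    maf_rare_fraction: float = 0.5   # weight of the Beta (rare-skewed) component
    maf_beta_a: float = 0.6
    maf_beta_b: float = 6.0
    maf_uniform_low: float = 0.01
    maf_min: float = 0.001
    error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.maf_rare_fraction, self.error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0,1]")
        if self.n_set1 < 1 or self.n_set2 < 1:
            raise ValueError("marker counts must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Ground truth of one gene-dropping run."""

    positions: np.ndarray            # all marker positions, sorted
    set1_mask: np.ndarray            # bool: which positions are set 1
    origin_labels: list[tuple[str, int]]
    haplotypes: dict[str, np.ndarray]   # id -> (2, n_all) alleles
    origins: dict[str, np.ndarray]      # id -> (2, n_all) origin-label index
    crossovers: pd.DataFrame            # parent, child, child_slot, pos_bp
    config: SimConfig
    seed: int

    def origin_at(self, individual: str, slot: int, pos: int) -> tuple[str, int]:
        k = int(np.searchsorted(self.positions, pos))
        if k >= len(self.positions) or self.positions[k] != pos:
            raise KeyError(f"position {pos} not simulated")
        return self.origin_labels[self.origins[individual][slot, k]]

    def haplotype_subset(self, individual: str, mask: np.ndarray) -> np.ndarray:
        return self.haplotypes[individual][:, mask]

    def dosage_matrix(self, samples, mask) -> np.ndarray:
        cols = [self.haplotypes[s][:, mask].sum(axis=0) for s in samples]
        return np.stack(cols, axis=1).astype(np.int8)


@dataclass
class SimResult:
    ped: Pedigree
    set1: GenotypeMatrix
    set2: GenotypeMatrix
    truth: SimTruth
    config: SimConfig


# ----------------------------------------------------------------------
# pedigrees
# ----------------------------------------------------------------------

def _couple(inds, fam, fa, mo, children):
    for c in children:
        inds.append(Individual(c, father_id=fa, mother_id=mo, family=fam))


def figure1_like_pedigree(family: str = "1") -> Pedigree:
    """A fixed 4-generation, 37-member pedigree exercising every code path:
    founder couples with 4/2/1 offspring (multi-offspring dichotomization,
    two-offspring arbitrary assignment, single-offspring proxy phasing),
    non-founders who are both trio offspring and trio parents (both
    chromosome subtypes), and marrying-in founders in every generation."""
    inds: list[Individual] = []
    # generation 1: three founder couples
    for iid, sex in (("F01", 1), ("M01", 2), ("F02", 1), ("M02", 2),
                     ("F03", 1), ("M03", 2)):
        inds.append(Individual(iid, sex=sex, family=family))
    _couple(inds, family, "F01", "M01", ["A1", "A2", "A3", "A4"])
    _couple(inds, family, "F02", "M02", ["B1", "B2"])
    _couple(inds, family, "F03", "M03", ["C1"])
    # generation 2 spouses (founders marrying in)
    for iid, sex in (("S01", 2), ("S02", 1), ("S03", 2), ("S04", 1)):
        inds.append(Individual(iid, sex=sex, family=family))
    _couple(inds, family, "A1", "S01", ["D1", "D2", "D3"])
    _couple(inds, family, "S02", "A2", ["E1", "E2"])
    _couple(inds, family, "B1", "S03", ["G1", "G2"])
    _couple(inds, family, "S04", "C1", ["H1"])
    # generation 3 spouses
    for iid, sex in (("T01", 2), ("T02", 1), ("T03", 2), ("T04", 1)):
        inds.append(Individual(iid, sex=sex, family=family))
    _couple(inds, family, "D1", "T01", ["K1", "K2", "K3"])
    _couple(inds, family, "T02", "E1", ["L1", "L2"])
    _couple(inds, family, "G1", "T03", ["N1", "N2"])
    _couple(inds, family, "T04", "H1", ["P1"])
    # fix sexes for individuals used as parents
    sex_of = {"A1": 1, "A2": 2, "B1": 1, "C1": 2, "D1": 1, "E1": 2,
              "G1": 1, "H1": 2}
    fixed = []
    for ind in inds:
        if ind.id in sex_of:
            ind = Individual(ind.id, ind.father_id, ind.mother_id,
                             sex_of[ind.id], ind.family)
        fixed.append(ind)
    return Pedigree(fixed, family=family)


def random_pedigree(
    generations: int = 4,
    n_founder_couples: int = 2,
    mean_children: float = 2.5,
    marry_prob: float = 0.6,
    seed: int = 0,
    family: str = "1",
) -> Pedigree:
    """A random multigenerational pedigree: each generation's members marry
    newly introduced founders with probability ``marry_prob`` and have
    1 + Poisson(mean_children - 1) children."""
    rng = np.random.default_rng(seed)
    inds: list[Individual] = []
    counter = [0]

    def new_id(prefix):
        counter[0] += 1
        return f"{prefix}{counter[0]:03d}"

    current: list[str] = []
    for _ in range(n_founder_couples):
        fa, mo = new_id("I"), new_id("I")
        inds.append(Individual(fa, sex=1, family=family))
        inds.append(Individual(mo, sex=2, family=family))
        for _ in range(1 + rng.poisson(mean_children - 1)):
            c = new_id("I")
            inds.append(Individual(c, father_id=fa, mother_id=mo,
                                   sex=int(1 + rng.integers(2)), family=family))
            current.append(c)
    for _ in range(generations - 2):
        nxt: list[str] = []
        for iid in current:
            if rng.random() >= marry_prob:
                continue
            spouse = new_id("I")
            me = next(i for i in inds if i.id == iid)
            inds.append(Individual(spouse, sex=3 - me.sex if me.sex else 1,
                                   family=family))
            fa, mo = (iid, spouse) if me.sex == 1 else (spouse, iid)
            for _ in range(1 + rng.poisson(mean_children - 1)):
                c = new_id("I")
                inds.append(Individual(c, father_id=fa, mother_id=mo,
                                       sex=int(1 + rng.integers(2)), family=family))
                nxt.append(c)
        if not nxt:
            break
        current = nxt
    return Pedigree(inds, family=family)


# ----------------------------------------------------------------------
# haplotypes and gene dropping
# ----------------------------------------------------------------------

def _marker_positions(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """All positions (sorted) and the set-1 membership mask."""
    set1 = np.unique(np.linspace(1, cfg.length_bp, cfg.n_set1).astype(np.int64))
    taken = set(set1.tolist())
    set2 = []
    while len(set2) < cfg.n_set2:
        cand = rng.integers(1, cfg.length_bp + 1, size=cfg.n_set2)
        for p in cand:
            p = int(p)
            if p not in taken:
                taken.add(p)
                set2.append(p)
                if len(set2) == cfg.n_set2:
                    break
    pos = np.sort(np.concatenate([set1, np.array(set2, dtype=np.int64)]))
    mask = np.isin(pos, set1)
    return pos, mask


def sample_maf_spectrum(cfg: SimConfig, n: int, rng) -> np.ndarray:
    """Alternate-allele frequencies from the configured MAF spectrum."""
    rare = rng.random(n) < cfg.maf_rare_fraction
    q = np.empty(n)
    q[rare] = rng.beta(cfg.maf_beta_a, cfg.maf_beta_b, size=int(rare.sum())) * 0.5
    q[~rare] = rng.uniform(cfg.maf_uniform_low, 0.5, size=int((~rare).sum()))
    return np.clip(q, cfg.maf_min, 0.5)


def simulate_founder_haplotypes(
    cfg: SimConfig, founders: list[str], n_markers: int, rng, freqs=None
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """i.i.d. Bernoulli founder haplotypes at spectrum-drawn frequencies."""
    if freqs is None:
        freqs = sample_maf_spectrum(cfg, n_markers, rng)
    haps = {
        f: (rng.random((2, n_markers)) < freqs).astype(np.int8) for f in founders
    }
    return haps, freqs


def _gamete(hap, org, cfg: SimConfig, positions, rng):
    """One meiosis: crossover positions, transmitted haplotype + origins."""
    k = rng.poisson(cfg.morgans)
    xpos = np.sort(rng.integers(1, cfg.length_bp + 1, size=k))
    start = int(rng.integers(2))
    # homolog index per marker: parity of #crossovers to the left
    h = (start + np.searchsorted(xpos, positions, side="left")) % 2
    idx = np.arange(len(positions))
    return hap[h, idx], org[h, idx], xpos


def gene_drop(
    ped: Pedigree,
    founder_haps: dict[str, np.ndarray],
    cfg: SimConfig,
    positions: np.ndarray,
    set1_mask: np.ndarray,
    rng,
) -> SimTruth:
    """Drop founder haplotypes through the pedigree with Haldane crossovers."""
    labels: list[tuple[str, int]] = []
    label_idx: dict[tuple[str, int], int] = {}
    for f in ped.founders:
        for h in (0, 1):
            label_idx[(f, h)] = len(labels)
            labels.append((f, h))
    haps: dict[str, np.ndarray] = {}
    origins: dict[str, np.ndarray] = {}
    xrec = []
    for iid in ped.topological_order():
        if ped.is_founder(iid):
            haps[iid] = founder_haps[iid].copy()
            origins[iid] = np.stack([
                np.full(len(positions), label_idx[(iid, 0)], np.int16),
                np.full(len(positions), label_idx[(iid, 1)], np.int16),
            ])
            continue
        ind = ped.members[iid]
        pair_h, pair_o = [], []
        for slot, parent in ((0, ind.father_id), (1, ind.mother_id)):
            h, o, xpos = _gamete(haps[parent], origins[parent], cfg, positions, rng)
            pair_h.append(h)
            pair_o.append(o)
            for p in xpos:
                xrec.append({"parent": parent, "child": iid,
                             "child_slot": slot, "pos_bp": int(p)})
        haps[iid] = np.stack(pair_h).astype(np.int8)
        origins[iid] = np.stack(pair_o).astype(np.int16)
    crossovers = pd.DataFrame(xrec, columns=["parent", "child", "child_slot", "pos_bp"])
    return SimTruth(positions, set1_mask, labels, haps, origins, crossovers,
                    cfg, cfg.seed)


def corrupt(
    gm: GenotypeMatrix, error_rate: float, missing_rate: float, seed: int
) -> GenotypeMatrix:
    """Inject genotyping error (resample uniformly from the two other
    dosages) and missingness, each i.i.d. per cell."""
    if not (0.0 <= error_rate <= 1.0 and 0.0 <= missing_rate <= 1.0):
        raise ValueError("rates must be in [0,1]")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    d = out.dosages
    known = d != MISSING
    drop = known & (rng.random(d.shape) < missing_rate)
    d[drop] = MISSING
    known = d != MISSING
    err = known & (rng.random(d.shape) < error_rate)
    if err.any():
        shift = rng.integers(1, 3, size=int(err.sum()))
        d[err] = ((d[err] + shift) % 3).astype(np.int8)
    return out


def simulate_dataset(
    ped: Pedigree | None = None,
    cfg: SimConfig | None = None,
    seed: int | None = None,
) -> SimResult:
    """Full synthetic study: pedigree + set 1 + set 2 matrices + truth."""
    cfg = cfg if cfg is not None else SimConfig()
    if seed is not None:
        cfg = SimConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    if ped is None:
        ped = figure1_like_pedigree()
    positions, set1_mask = _marker_positions(cfg, rng)
    fh, _ = simulate_founder_haplotypes(cfg, ped.founders, len(positions), rng)
    truth = gene_drop(ped, fh, cfg, positions, set1_mask, rng)
    samples = ped.ids

    def matrix(mask):
        markers = make_markers(cfg.chrom, positions[mask])
        return GenotypeMatrix(markers, samples, truth.dosage_matrix(samples, mask))

    set1 = matrix(set1_mask)
    set2 = matrix(~set1_mask)
    if cfg.error_rate > 0 or cfg.missing_rate > 0:
        sub = np.random.default_rng(cfg.seed + 1)
        set1 = corrupt(set1, cfg.error_rate, cfg.missing_rate,
                       int(sub.integers(2**31)))
        set2 = corrupt(set2, cfg.error_rate, cfg.missing_rate,
                       int(sub.integers(2**31)))
    return SimResult(ped, set1, set2, truth, cfg)


def write_fixture(outdir, sim: SimResult) -> dict[str, Path]:
    """Write PED, set 1/2 VCFs, truth TSVs and a config echo to ``outdir``."""
    from .vcfio import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": outdir / "pedigree.ped",
        "set1": outdir / "set1.vcf",
        "set2": outdir / "set2.vcf",
        "truth_haplotypes": outdir / "truth_haplotypes.tsv",
        "truth_origins": outdir / "truth_origins.tsv",
        "truth_crossovers": outdir / "truth_crossovers.tsv",
        "config": outdir / "config.yaml",
    }
    write_ped(sim.ped, paths["ped"])
    write_vcf(paths["set1"], sim.set1, seed=sim.config.seed)
    write_vcf(paths["set2"], sim.set2, seed=sim.config.seed)
    t = sim.truth
    ids = sim.ped.ids
    hap_rows = {
        f"{iid}.{slot}": t.haplotypes[iid][slot]
        for iid in ids for slot in (0, 1)
    }
    pd.DataFrame(hap_rows, index=t.positions).rename_axis("pos").to_csv(
        paths["truth_haplotypes"], sep="\t")
    org_rows = {
        f"{iid}.{slot}": [
            "{}|{}".format(*t.origin_labels[c]) for c in t.origins[iid][slot]
        ]
        for iid in ids for slot in (0, 1)
    }
    pd.DataFrame(org_rows, index=t.positions).rename_axis("pos").to_csv(
        paths["truth_origins"], sep="\t")
    t.crossovers.to_csv(paths["truth_crossovers"], sep="\t", index=False)
    sim.config.to_yaml(paths["config"])
    return paths
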