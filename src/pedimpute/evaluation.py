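"""Masking experiments and imputation quality statistics.

IQS is the chance-corrected concordance between imputed and held-out
genotypes: on the 3x3 dosage agreement table with counts ``n_ij``,
``Po = sum_i n_ii / N``, ``Pc = sum_i row_i * col_i / N^2`` and
``IQS = (Po - Pc) / (1 - Pc)`` — the kappa construction with marginals taken
from the comparison table itself.  Markers whose chance concordance equals 1
(e.g. monomorphic agreement) are excluded from reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imputation import ImputedMatrix, ImputeSource
from .matrices import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: MAF bin edges, left-open/right-closed except the first bin closed at 0
MAF_BIN_EDGES = [0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5]
MAF_BIN_LABELS = ["(0,0.01]", "(0.01,0.05]", "(0.05,0.1]", "(0.1,0.2]",
                  "(0.2,0.3]", "(0.3,0.4]", "(0.4,0.5]"]

#: availability (fraction of set 2 genotypes known pre-imputation) bin edges
AVAIL_BIN_EDGES = [0.0, 0.1, 0.25, 0.75, 0.9, 1.0]
AVAIL_BIN_LABELS = ["[0,0.1]", "(0.1,0.25]", "(0.25,0.75]", "(0.75,0.9]", "(0.9,1]"]


@dataclass
class MaskRecord:
    """Reproducible record of masked cells.

    ``scheme`` is ``uniform_rate`` (one masking probability for every cell)
    or ``per_marker_uniform`` (a per-marker probability drawn Uniform(0,1)).
    """

    scheme: str
    seed: int
    rate: float | None
    marker_rows: np.ndarray    # row index of each masked cell
    sample_ids: list[str]      # sample id of each masked cell
    per_marker_prob: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.marker_rows)

    def to_tsv(self, path, markers: pd.DataFrame) -> None:
        with open(path, "w") as fh:
            fh.write(f"# scheme={self.scheme} seed={self.seed} rate={self.rate}\n")
            fh.write("marker_id\tindividual\n")
            mid = markers["id"].to_numpy()
            for r, s in zip(self.marker_rows, self.sample_ids):
                fh.write(f"{mid[r]}\t{s}\n")


def mask_cells(
    gm: GenotypeMatrix,
    scheme: str = "uniform_rate",
    rate: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypeMatrix, MaskRecord]:
    """Randomly mask non-missing cells; fully reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    probs = None
    if scheme == "uniform_rate":
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rate must be in [0,1]")
        p = np.full(gm.n_markers, rate)
    elif scheme == "per_marker_uniform":
        probs = rng.uniform(0.0, 1.0, size=gm.n_markers)
        p = probs
    else:
        raise ValueError(f"unknown masking scheme {scheme!r}")
    draw = rng.random(gm.dosages.shape)
    mask = (draw < p[:, None]) & (gm.dosages != MISSING)
    masked = gm.copy()
    masked.dosages[mask] = MISSING
    rows, cols = np.nonzero(mask)
    record = MaskRecord(
        scheme, seed, rate if scheme == "uniform_rate" else None,
        rows, [gm.samples[c] for c in cols], per_marker_prob=probs,
    )
    return masked, record


def iqs_from_table(table: np.ndarray) -> tuple[float | None, float, float]:
    """(IQS or None-if-excluded, observed concordance, chance concordance)
    from a 3x3 agreement count table (rows imputed, columns true)."""
    table = np.asarray(table, dtype=np.float64)
    n = table.sum()
    if n == 0:
        return None, float("nan"), float("nan")
    po = np.trace(table) / n
    pc = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / n**2
    if pc >= 1.0:
        return None, float(po), float(pc)
    return float((po - pc) / (1.0 - pc)), float(po), float(pc)


def iqs_marker(
    imputed: np.ndarray, truth: np.ndarray, compare: np.ndarray
) -> tuple[float | None, float, float, int]:
    """Per-marker IQS restricted to ``compare`` cells (masked and imputed).

    Returns (IQS or None, Po, Pc, n compared).
    """
    i = imputed[compare]
    t = truth[compare]
    ok = (i != MISSING) & (t != MISSING)
    i, t = i[ok], t[ok]
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (i, t), 1)
    iqs, po, pc = iqs_from_table(table)
    return iqs, po, pc, int(len(i))


def maf(gm: GenotypeMatrix, individuals) -> np.ndarray:
    """Per-marker minor allele frequency over the given individuals
    (missing cells excluded per marker; all-missing markers -> NaN)."""
    idx = [gm.sample_idx(s) for s in individuals]
    d = gm.dosages[:, idx].astype(np.float64)
    known = d != MISSING
    alt = np.where(known, d, 0.0).sum(axis=1)
    n = 2.0 * known.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / n, np.nan)
    return np.minimum(freq, 1.0 - freq)


def availability(gm: GenotypeMatrix, individuals=None) -> np.ndarray:
    """Per-marker fraction of individuals with a known (unmasked) genotype."""
    if individuals is None:
        individuals = gm.samples
    idx = [gm.sample_idx(s) for s in individuals]
    return (gm.dosages[:, idx] != MISSING).mean(axis=1)


@dataclass
class IQSReport:
    per_marker: pd.DataFrame
    by_maf: pd.DataFrame
    by_availability: pd.DataFrame
    mean_iqs: float
    n_reported: int
    n_imputed_cells: int


def evaluate_imputation(
    imp: ImputedMatrix,
    truth_set2: GenotypeMatrix,
    record: MaskRecord,
    masked_set2: GenotypeMatrix,
    unrelated: list[str],
) -> IQSReport:
    """Full masking-experiment evaluation: per-marker IQS over cells that
    were masked and imputed, MAF over the unrelated set, availability over
    the masked input, and binned summaries."""
    n_m = truth_set2.n_markers
    mask_matrix = np.zeros((n_m, len(imp.samples)), bool)
    col_of = {s: j for j, s in enumerate(imp.samples)}
    for r, s in zip(record.marker_rows, record.sample_ids):
        if s in col_of:
            mask_matrix[r, col_of[s]] = True

    truth = np.full_like(imp.dosages, MISSING)
    for j, s in enumerate(imp.samples):
        if truth_set2.has_sample(s):
            truth[:, j] = truth_set2.dosages[:, truth_set2.sample_idx(s)]

    imputed_mask = imp.source == ImputeSource.IMPUTED
    compare = mask_matrix & imputed_mask
    marker_maf = maf(truth_set2, [s for s in unrelated if truth_set2.has_sample(s)])
    avail = availability(masked_set2)

    recs = []
    for r in range(n_m):
        iqs, po, pc, n = iqs_marker(imp.dosages[r], truth[r], compare[r])
        recs.append({
            "marker_id": truth_set2.markers["id"].iloc[r],
            "iqs": iqs, "po": po, "pc": pc, "n_compared": n,
            "n_masked": int(mask_matrix[r].sum()),
            "n_imputed_of_masked": int(compare[r].sum()),
            "maf": marker_maf[r], "availability": avail[r],
            "excluded": iqs is None,
        })
    per_marker = pd.DataFrame(recs)
    reported = per_marker[~per_marker["excluded"]]
    mean_iqs = float(reported["iqs"].mean()) if len(reported) else float("nan")

    per_marker = per_marker.assign(
        maf_bin=pd.cut(per_marker["maf"], MAF_BIN_EDGES, labels=MAF_BIN_LABELS,
                       include_lowest=True),
        avail_bin=pd.cut(per_marker["availability"], AVAIL_BIN_EDGES,
                         labels=AVAIL_BIN_LABELS, include_lowest=True),
    )
    rep = per_marker[~per_marker["excluded"]]
    by_maf = (
        rep.groupby("maf_bin", observed=False)["iqs"]
        .agg(mean_iqs="mean", n_markers="count")
        .reset_index()
    )
    grp = per_marker.groupby("avail_bin", observed=False)
    by_avail = grp.agg(
        n_markers=("marker_id", "count"),
        n_masked=("n_masked", "sum"),
        n_imputed=("n_imputed_of_masked", "sum"),
    ).reset_index()
    iqs_avail = (
        rep.groupby("avail_bin", observed=False)["iqs"].mean().reset_index(drop=True)
    )
    by_avail["mean_iqs"] = iqs_avail
    with np.errstate(invalid="ignore", divide="ignore"):
        by_avail["imputable_fraction"] = np.where(
            by_avail["n_masked"] > 0, by_avail["n_imputed"] / by_avail["n_masked"],
            np.nan,
        )
    return IQSReport(
        per_marker=per_marker,
        by_maf=by_maf,
        by_availability=by_avail,
        mean_iqs=mean_iqs,
        n_reported=int(len(reported)),
        n_imputed_cells=int(compare.sum()),
    )


def summarize(per_marker: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Binned summaries from a per-marker frame with columns
    ``iqs, maf, availability, excluded`` (empty bins stay empty/NaN)."""
    df = per_marker.assign(
        maf_bin=pd.cut(per_marker["maf"], MAF_BIN_EDGES, labels=MAF_BIN_LABELS,
                       include_lowest=True),
        avail_bin=pd.cut(per_marker["availability"], AVAIL_BIN_EDGES,
                         labels=AVAIL_BIN_LABELS, include_lowest=True),
    )
    rep = df[~df["excluded"]]
    by_maf = (
        rep.groupby("maf_bin", observed=False)["iqs"]
        .agg(mean_iqs="mean", n_markers="count").reset_index()
    )
    by_avail = (
        rep.groupby("avail_bin", observed=False)["iqs"]
        .agg(mean_iqs="mean", n_markers="count").reset_index()
    )
    overall = float(rep["iqs"].mean()) if len(rep) else float("nan")
    return by_maf, by_avail, overall
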