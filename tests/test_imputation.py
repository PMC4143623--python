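import numpy as np
import pytest

from pedimpute.ibd import trace_inheritance
from pedimpute.imputation import (
    CONFLICT, UNKNOWN, FounderAlleleTable, ImputeSource, impute_diploid,
    imputation_yield, infer_complement, phase_set2, project_to_founders,
)
from pedimpute.matrices import MISSING, GenotypeMatrix, make_markers
from pedimpute.pedigree import Individual, Pedigree
from pedimpute.pipeline import impute_pedigrees, run_masking_experiment
from pedimpute.recombination import collect_local_segments
from pedimpute.trio_phasing import phase_all, phase_trio_marker


class TestPhaseSet2:
    def test_homozygote_splitting(self):
        ped = Pedigree([Individual("X", sex=1)])
        gm = GenotypeMatrix(make_markers("1", [10, 20]), ["X"],
                            np.array([[2], [0]], np.int8))
        pm = phase_set2(gm, ped)
        assert pm.alleles[0, 0].tolist() == [1, 1]
        assert pm.alleles[1, 0].tolist() == [0, 0]

    def test_het_in_sequenced_trio_forced(self):
        ped = Pedigree([
            Individual("F", sex=1), Individual("M", sex=2),
            Individual("C", "F", "M", 1),
        ])
        gm = GenotypeMatrix(make_markers("1", [10]), ["F", "M", "C"],
                            np.array([[0, 2, 1]], np.int8))
        pm = phase_set2(gm, ped)
        assert pm.alleles[0, 2].tolist() == [0, 1]

    def test_het_without_relatives_unphased(self):
        ped = Pedigree([Individual("X", sex=1)])
        gm = GenotypeMatrix(make_markers("1", [10]), ["X"],
                            np.array([[1]], np.int8))
        pm = phase_set2(gm, ped)
        assert pm.alleles[0, 0].tolist() == [MISSING, MISSING]


class TestComplementInference:
    def _table(self, n0a=0, n1a=0):
        t = FounderAlleleTable([("F", 0), ("F", 1)], 1)
        t.n0[0, 0] = n0a
        t.n1[0, 0] = n1a
        return t

    @pytest.mark.parametrize("dosage,known,expected", [
        (1, 0, 1), (2, 1, 1), (1, 1, 0),
    ])
    def test_complement_value(self, dosage, known, expected):
        ped = Pedigree([Individual("F", sex=1)])
        gm = GenotypeMatrix(make_markers("1", [10]), ["F"],
                            np.array([[dosage]], np.int8))
        segs, _ = collect_local_segments(ped, gm, phase_all(gm, ped)[0])
        nfm = trace_inheritance(ped, segs, gm)
        t = self._table(n0a=1 if known == 0 else 0, n1a=1 if known == 1 else 0)
        infer_complement(gm, ped, nfm, t, "abstain")
        resolved = t.resolve("abstain")
        assert resolved[1, 0] == expected
        assert t.complemented[1, 0]

    def test_impossible_complement_conflicts_both(self):
        ped = Pedigree([Individual("F", sex=1)])
        gm = GenotypeMatrix(make_markers("1", [10]), ["F"],
                            np.array([[0]], np.int8))
        segs, _ = collect_local_segments(ped, gm, phase_all(gm, ped)[0])
        nfm = trace_inheritance(ped, segs, gm)
        t = self._table(n1a=1)  # homolog A claims allele 1, dosage is 0
        infer_complement(gm, ped, nfm, t, "abstain")
        resolved = t.resolve("abstain")
        assert resolved[0, 0] == CONFLICT and resolved[1, 0] == CONFLICT


class TestConflictPolicies:
    def test_abstain_vs_majority(self):
        t = FounderAlleleTable([("F", 0)], 3)
        t.n0[0] = [2, 2, 1]
        t.n1[0] = [1, 0, 1]
        ab = t.resolve("abstain")
        mj = t.resolve("majority")
        assert ab.tolist() == [[CONFLICT, 0, CONFLICT]]
        assert mj.tolist() == [[0, 0, CONFLICT]]


class TestEndToEnd:
    def test_error_free_imputation_equals_truth(self, dense_sim, dense_masked):
        """Perfect recovery: on error-free data every imputed cell equals
        the gene-drop truth and observations are preserved verbatim."""
        sim = dense_sim
        imp = dense_masked["imp"]
        record = dense_masked["record"]
        masked_dos = {s: None for s in imp.samples}
        truth = sim.set2
        n_imputed = 0
        for j, s in enumerate(imp.samples):
            tj = truth.sample_idx(s)
            m = imp.source[:, j] == ImputeSource.IMPUTED
            assert (imp.dosages[m, j] == truth.dosages[m, tj]).all()
            n_imputed += int(m.sum())
        assert n_imputed > 10000

    def test_observed_cells_bit_identical(self, dense_sim, dense_masked):
        sim = dense_sim
        imp = dense_masked["imp"]
        record = dense_masked["record"]
        masked = sim.set2.copy()
        cols = [masked.sample_idx(s) for s in record.sample_ids]
        masked.dosages[record.marker_rows, cols] = MISSING
        for j, s in enumerate(imp.samples):
            obs = imp.source[:, j] == ImputeSource.OBSERVED
            assert (imp.dosages[obs, j] ==
                    masked.dosages[obs, masked.sample_idx(s)]).all()

    def test_no_new_mendelian_errors(self, dense_sim, dense_masked):
        sim = dense_sim
        imp = dense_masked["imp"]
        col = {s: j for j, s in enumerate(imp.samples)}
        for t in sim.ped.trios:
            f, m, c = (imp.dosages[:, col[t.father.id]],
                       imp.dosages[:, col[t.mother.id]],
                       imp.dosages[:, col[t.child.id]])
            for r in range(imp.dosages.shape[0]):
                if MISSING in (f[r], m[r], c[r]):
                    continue
                assert not phase_trio_marker(
                    int(f[r]), int(m[r]), int(c[r])
                ).mendelian_error

    def test_worked_example_distant_imputation(self):
        """A haploid genotype observed in one grandchild propagates through
        the shared founder chromosome into a cousin who carries the same
        segment identical by descent."""
        # 583x584 -> 619, 628; 619x651 -> 650; 628x627 -> 629
        inds = [
            Individual("583", sex=1), Individual("584", sex=2),
            Individual("619", "583", "584", 1),
            Individual("628", "583", "584", 2),
            Individual("652", sex=1), Individual("653", sex=2),
            Individual("651", "652", "653", 2),
            Individual("627", sex=1),
            Individual("650", "619", "651", 1),
            Individual("629", "627", "628", 2),
        ]
        ped = Pedigree(inds)
        from pedimpute.simulator import SimConfig, simulate_dataset
        sim = simulate_dataset(ped=ped, cfg=SimConfig(n_set1=1500, n_set2=300),
                               seed=5)
        # sequence only 650 (and founders to resolve complements): here give
        # set 2 data to everyone except 629, then check 629 was imputed where
        # it shares IBD with 650 via 583/584
        set2 = sim.set2.subset_samples([s for s in ped.ids if s != "629"])
        res = impute_pedigrees([ped], sim.set1, set2)
        j = res.imputed.samples.index("629")
        imputed = res.imputed.source[:, j] == ImputeSource.IMPUTED
        assert imputed.sum() > 0
        truth = sim.set2.sample_idx("629")
        assert (res.imputed.dosages[imputed, j] ==
                sim.set2.dosages[imputed, truth]).all()

    def test_more_masking_never_more_imputable(self, dense_sim):
        """Imputable yield shrinks monotonically as more input is masked."""
        _, rep_half, _, _ = run_masking_experiment(dense_sim, rate=0.5, seed=7)
        _, rep_most, _, _ = run_masking_experiment(dense_sim, rate=0.9, seed=7)
        frac_half = rep_half.n_imputed_cells / max(1, len(rep_half.per_marker))
        assert rep_most.per_marker["n_imputed_of_masked"].sum() / \
            rep_most.per_marker["n_masked"].sum() <= \
            rep_half.per_marker["n_imputed_of_masked"].sum() / \
            rep_half.per_marker["n_masked"].sum()


class TestYield:
    def test_roi_hand_count(self):
        """Five-individual toy: ROI equals the hand count."""
        from pedimpute.imputation import ImputedMatrix
        markers = make_markers("1", [10, 20])
        set2 = GenotypeMatrix(markers, ["A", "B"],
                              np.array([[1, MISSING], [0, MISSING]], np.int8))
        dos = np.array([[1, 1], [0, MISSING]], np.int8)
        src = np.array([
            [ImputeSource.OBSERVED, ImputeSource.IMPUTED],
            [ImputeSource.OBSERVED, ImputeSource.NOT_IMPUTABLE],
        ], np.uint8)
        haps = np.full((2, 2, 2), MISSING, np.int8)
        imp = ImputedMatrix(markers, ["A", "B"], dos, src, haps)
        y = imputation_yield(imp, set2)
        # 1 imputed cell (het) / 2 observed input cells = 50%
        assert y["total_imputed"] == 1
        assert y["observed_input_cells"] == 2
        assert y["return_on_investment_pct"] == pytest.approx(50.0)
        per = y["per_individual"].set_index("individual")
        assert per.loc["B", "imputed_het"] == 1
        assert per.loc["B", "imputed_hom"] == 0

    def test_roi_positive_when_half_sequenced(self, dense_sim):
        sim = dense_sim
        half = sorted(sim.ped.ids)[::2]
        set2 = sim.set2.subset_samples(half)
        res = impute_pedigrees([sim.ped], sim.set1, set2)
        y = imputation_yield(res.imputed, set2)
        assert y["return_on_investment_pct"] > 0
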