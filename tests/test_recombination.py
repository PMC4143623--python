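import itertools

import numpy as np
import pytest

from pedimpute.matrices import MISSING, GenotypeMatrix, PhaseMatrix, make_markers
from pedimpute.pedigree import Individual, Pedigree
from pedimpute.recombination import (
    DichotomyTable, _min_recomb_orientations, collect_local_segments,
    dichotomize_offspring, infer_crossovers_multi_meiosis,
    min_recomb_phase_founder, proxy_phase_single_offspring,
)
from pedimpute.simulator import SimConfig, simulate_dataset
from pedimpute.trio_phasing import phase_all


def _trio_ped(kids=("C1",), extra=()):
    inds = [Individual("F", sex=1), Individual("M", sex=2)]
    inds += [Individual(k, "F", "M", 1) for k in kids]
    inds += list(extra)
    return Pedigree(inds)


def brute_force_min_recomb(alleles):
    """Exhaustive oracle: minimum total group flips over all orientation
    sequences (2^M enumeration)."""
    n_m, n_off = alleles.shape
    best = None
    for xs in itertools.product((0, 1), repeat=n_m):
        cost = 0
        prev = [None] * n_off
        for k in range(n_m):
            for j in range(n_off):
                if alleles[k, j] == MISSING:
                    continue
                g = 0 if alleles[k, j] == xs[k] else 1
                if prev[j] is not None and g != prev[j]:
                    cost += 1
                prev[j] = g
        best = cost if best is None else min(best, cost)
    return best


class TestMinRecombDP:
    @pytest.mark.parametrize("seed", range(8))
    def test_dp_equals_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n_m = int(rng.integers(2, 9))
        n_off = int(rng.integers(2, 4))
        a = rng.integers(0, 2, size=(n_m, n_off)).astype(np.int8)
        a[rng.random((n_m, n_off)) < 0.3] = MISSING
        rank = np.arange(n_off)
        _, _, _, total = _min_recomb_orientations(a, rank)
        assert total == brute_force_min_recomb(a)

    def test_no_group_change_zero_events(self):
        # 3 offspring, constant dichotomy pattern -> no crossovers
        a = np.array([[0, 1, 1], [1, 0, 0], [0, 1, 1]], dtype=np.int8)
        _, flips, _, total = _min_recomb_orientations(a, np.arange(3))
        assert total == 0
        assert all(len(f) == 0 for f in flips)

    def test_single_flip_detected(self):
        # offspring 1 changes group relative to the other two
        a = np.array([[0, 1, 1], [0, 0, 1]], dtype=np.int8)
        _, flips, _, total = _min_recomb_orientations(a, np.arange(3))
        assert total == 1
        assert flips[1] == (1,)


def _founder_family_phase(dosages_founder, offspring_alleles, other_parent=0):
    """Build a phased two-generation family for founder-strategy tests.

    ``offspring_alleles[k][j]`` is what offspring j inherited from founder F
    at marker k; the other parent is homozygous ``other_parent`` so trio
    phasing is forced everywhere.
    """
    off = np.asarray(offspring_alleles, dtype=np.int8)
    n_m, n_off = off.shape
    kids = [f"C{j+1}" for j in range(n_off)]
    ped = _trio_ped(kids)
    samples = ["F", "M"] + kids
    dos = np.zeros((n_m, len(samples)), np.int8)
    dos[:, 0] = dosages_founder
    dos[:, 1] = 2 * other_parent
    for j in range(n_off):
        dos[:, 2 + j] = off[:, j] + other_parent
    gm = GenotypeMatrix(make_markers("1", (np.arange(n_m) + 1) * 1000),
                        samples, dos)
    pm, _ = phase_all(gm, ped, require_complete=True)
    return ped, gm, pm


class TestFounderStrategy:
    def test_dichotomize_groups_and_homozygous_skip(self):
        # marker 0: founder het, C1 inherited 0, C2 inherited 1
        # marker 1: founder homozygous -> absent from the table
        ped, gm, pm = _founder_family_phase([1, 0], [[0, 1], [0, 0]])
        table = dichotomize_offspring(ped, gm, pm, "F", "1")
        assert list(table.marker_idx) == [0]
        assert table.alleles.tolist() == [[0, 1]]

    def test_two_offspring_event_arbitrarily_assigned(self):
        # constant groups, then both offspring show the same inherited allele:
        # one of them recombined but which cannot be determined
        alleles = [[0, 1], [0, 1], [0, 0], [0, 0]]
        ped, gm, pm = _founder_family_phase([1, 1, 1, 1], alleles)
        table = dichotomize_offspring(ped, gm, pm, "F", "1")
        events, segs = min_recomb_phase_founder(ped, gm, pm, table)
        assert len(events) == 1
        assert events[0].arbitrarily_assigned
        # determinization: assigned to the lexicographically smaller offspring
        assert events[0].child == "C1"

    def test_three_offspring_events_match_truth(self, dense_sim):
        """On the error-free dense simulation, founder-strategy event counts
        equal the true crossover counts for every founder family whose
        crossovers are separated by anchored informative markers."""
        sim = dense_sim
        gm = sim.set1.subset_samples(sim.ped.ids)
        pm, _ = phase_all(gm, sim.ped, require_complete=True)
        xo = sim.truth.crossovers
        checked = 0
        for founder in sim.ped.founders:
            kids = sim.ped.children_of(founder)
            if len(kids) < 2:
                continue
            table = dichotomize_offspring(ped=sim.ped, gm=gm, pm=pm,
                                          founder=founder, chrom="1")
            events, _ = min_recomb_phase_founder(sim.ped, gm, pm, table)
            true_n = int((xo.parent == founder).sum())
            assert len(events) <= true_n
            # equality when every true crossover is flanked by anchored
            # markers of its offspring with no other family crossover between
            pos = gm.positions("1")
            anchored = table.marker_idx[
                (table.alleles != MISSING).sum(axis=1) >= 2
            ]
            fam = xo[xo.parent == founder]
            clean = True
            for _, row in fam.iterrows():
                j = kids.index(row.child)
                own = anchored[table.alleles[
                    np.isin(table.marker_idx, anchored), j] != MISSING]
                own_pos = pos[own]
                left = own_pos[own_pos < row.pos_bp]
                right = own_pos[own_pos > row.pos_bp]
                if not len(left) or not len(right):
                    clean = False
                    continue
                window = (left[-1], right[0])
                others = fam[fam.pos_bp.between(*window) &
                             (fam.pos_bp != row.pos_bp)]
                if len(others):
                    clean = False
            if clean:
                assert len(events) == true_n
                checked += 1
        assert checked > 0

    def test_proxy_single_offspring_complement(self):
        # founder F3 with a single child: homolog A = transmitted haplotype,
        # homolog B = dosage complement
        ped = Pedigree([
            Individual("F3", sex=1), Individual("M3", sex=2),
            Individual("K", "F3", "M3", 1),
        ])
        samples = ["F3", "M3", "K"]
        # F3 dosages (1, 2); M3 hom 0 -> transmitted alleles forced
        dos = np.array([[1, 0, 0], [2, 0, 1]], dtype=np.int8)
        gm = GenotypeMatrix(make_markers("1", [1000, 2000]), samples, dos)
        pm, _ = phase_all(gm, ped, require_complete=True)
        segs = proxy_phase_single_offspring(ped, gm, pm, "F3", "1")
        fi = gm.sample_idx("F3")
        # dosage 1, transmitted 0 -> proxy (0|1); dosage 2, transmitted 1 -> (1|1)
        assert pm.alleles[0, fi].tolist() == [0, 1]
        assert pm.alleles[1, fi].tolist() == [1, 1]
        assert len(segs) == 1 and segs[0].parent_slot == 0
        assert segs[0].path == ("F3", "K")


class TestMultiMeiosis:
    @pytest.fixture()
    def chain(self):
        """Three generations: founders G1,G2 -> P (phased), P x S -> C."""
        ped = Pedigree([
            Individual("G1", sex=1), Individual("G2", sex=2),
            Individual("P", "G1", "G2", 2),
            Individual("S", sex=1),
            Individual("C", "S", "P", 1),
        ])
        return ped

    def _matrices(self, ped, g1, g2, s, c_from_p):
        """P inherits g1 from G1 (paternal) and g2 from G2; S homozygous."""
        g1, g2, s, c_from_p = map(np.asarray, (g1, g2, s, c_from_p))
        n = len(g1)
        samples = ["G1", "G2", "P", "S", "C"]
        dos = np.zeros((n, 5), np.int8)
        dos[:, 0] = 2 * g1
        dos[:, 1] = 2 * g2
        dos[:, 2] = g1 + g2
        dos[:, 3] = 2 * s
        dos[:, 4] = s + c_from_p
        gm = GenotypeMatrix(make_markers("1", (np.arange(n) + 1) * 1000),
                            samples, dos)
        pm, _ = phase_all(gm, ped, require_complete=True)
        return gm, pm

    def test_single_crossover_between_informative_markers(self, chain):
        # P is het everywhere; C switches from G1's allele to G2's at marker 2
        g1 = [0, 0, 0, 0]
        g2 = [1, 1, 1, 1]
        c_from_p = [0, 0, 1, 1]
        gm, pm = self._matrices(chain, g1, g2, [0] * 4, c_from_p)
        events, segs = infer_crossovers_multi_meiosis(chain, gm, pm, "P", "C", "1")
        assert len(events) == 1
        assert (events[0].left_idx, events[0].right_idx) == (1, 2)
        assert len(segs) == 2
        assert segs[0].path == ("G1", "P", "C")
        assert segs[1].path == ("G2", "P", "C")

    def test_zero_crossovers_single_spanning_segment(self, chain):
        gm, pm = self._matrices(chain, [0, 0, 0], [1, 1, 1], [0] * 3,
                                [1, 1, 1])
        events, segs = infer_crossovers_multi_meiosis(chain, gm, pm, "P", "C", "1")
        assert events == []
        assert len(segs) == 1
        assert segs[0].path == ("G2", "P", "C")

    def test_undetectable_double_crossover(self, chain):
        # two crossovers between informative markers: P het only at the
        # flanks, identical origin there -> nothing observable
        g1 = [0, 0, 0]
        g2 = [1, 0, 1]  # middle marker uninformative (P homozygous)
        c_from_p = [0, 0, 0]  # truth could have double-crossed in between
        gm, pm = self._matrices(chain, g1, g2, [0] * 3, c_from_p)
        events, segs = infer_crossovers_multi_meiosis(chain, gm, pm, "P", "C", "1")
        assert events == []

    def test_detected_events_contain_true_crossovers(self, dense_sim):
        """Error-free simulation: every inferred multi-meiosis event interval
        contains a true crossover of that meiosis."""
        sim = dense_sim
        gm = sim.set1.subset_samples(sim.ped.ids)
        pm, _ = phase_all(gm, sim.ped, require_complete=True)
        xo = sim.truth.crossovers
        n_events = 0
        for parent in sim.ped.nonfounders:
            for child in sim.ped.children_of(parent):
                events, _ = infer_crossovers_multi_meiosis(
                    sim.ped, gm, pm, parent, child, "1"
                )
                slot = 0 if sim.ped.members[child].father_id == parent else 1
                true_pos = xo[(xo.parent == parent) & (xo.child == child)
                              & (xo.child_slot == slot)].pos_bp.to_numpy()
                for e in events:
                    assert ((true_pos > e.left_bp) & (true_pos < e.right_bp)).any()
                    n_events += 1
        assert n_events > 0


class TestCollectLocalSegments:
    def test_segments_disjoint_and_sorted_per_slot(self, dense_sim):
        sim = dense_sim
        gm = sim.set1.subset_samples(sim.ped.ids)
        pm, _ = phase_all(gm, sim.ped, require_complete=True)
        segments, _ = collect_local_segments(sim.ped, gm, pm)
        bykey = {}
        for s in segments:
            bykey.setdefault((s.carrier, s.slot), []).append(s)
        for segs in bykey.values():
            segs.sort(key=lambda s: s.start_bp)
            for a, b in zip(segs, segs[1:]):
                assert a.end_bp <= b.start_bp

    def test_every_nonfounder_slot_covered(self, dense_sim):
        sim = dense_sim
        gm = sim.set1.subset_samples(sim.ped.ids)
        pm, _ = phase_all(gm, sim.ped, require_complete=True)
        segments, _ = collect_local_segments(sim.ped, gm, pm)
        covered = {(s.carrier, s.slot) for s in segments}
        for iid in sim.ped.nonfounders:
            assert (iid, 0) in covered and (iid, 1) in covered
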