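"""Reporter metabolites, subnetwork expansion, Welch/BH and DE merging."""

import itertools

import numpy as np
import pytest
import scipy.stats

from gutflux import expression_stats as es
from gutflux.model_core import MetabolicModel, Metabolite, Reaction
from gutflux.rmetd import DEGene, DETable


def star_model(n_genes=4, p=0.5):
    """One hub metabolite fed by n reactions, one gene each."""
    m = MetabolicModel(id="star")
    m.metabolites["hub[c]"] = Metabolite("hub[c]")
    pvals = {}
    for i in range(n_genes):
        mid = f"S{i}[c]"
        m.metabolites[mid] = Metabolite(mid)
        m.reactions[f"R{i}"] = Reaction(
            f"R{i}", {mid: -1, "hub[c]": 1}, 0, 10, gpr=f"g{i}")
        pvals[f"g{i}"] = p
    return m, pvals


def chain10_model():
    m = MetabolicModel(id="chain10")
    for i in range(10):
        m.metabolites[f"M{i}"] = Metabolite(f"M{i}")
    for i in range(9):
        m.reactions[f"R{i}"] = Reaction(
            f"R{i}", {f"M{i}": -1, f"M{i+1}": 1}, 0, 10, gpr=f"g{i}")
    return m


def random_null_model(n_genes=50, n_mets=150, n_rxns=450, seed=0):
    rng = np.random.default_rng(seed)
    m = MetabolicModel(id="nulltoy")
    for i in range(n_mets):
        m.metabolites[f"M{i}[c]"] = Metabolite(f"M{i}[c]")
    for j in range(n_rxns):
        a, b = rng.choice(n_mets, size=2, replace=False)
        m.reactions[f"R{j}"] = Reaction(
            f"R{j}", {f"M{a}[c]": -1, f"M{b}[c]": 1}, 0, 10,
            gpr=f"g{rng.integers(n_genes)}")
    return m


class TestReporterMetabolites:
    def test_neutral_neighbors_give_zero_raw_score(self):
        model, pvals = star_model(n_genes=4, p=0.5)
        scores = es.reporter_metabolites(model, pvals, n_background=500, seed=0)
        hub = next(s for s in scores if s.metabolite_id == "hub[c]")
        assert hub.k == 4
        assert hub.z_raw == pytest.approx(0.0, abs=1e-12)

    def test_single_neighbor_quantile(self):
        """p = 0.0228 sits two standard deviations into the normal tail."""
        model, _ = star_model(n_genes=1)
        scores = es.reporter_metabolites(model, {"g0": 0.0228},
                                         n_background=500, seed=0)
        hub = next(s for s in scores if s.metabolite_id == "hub[c]")
        assert hub.z_raw == pytest.approx(2.0, abs=0.005)

    def test_unscored_metabolites_omitted(self):
        model, pvals = star_model(n_genes=2)
        model.metabolites["lonely[c]"] = Metabolite("lonely[c]")
        model.reactions["R_no_gene"] = Reaction(
            "R_no_gene", {"lonely[c]": -1}, 0, 10)
        scores = es.reporter_metabolites(model, pvals, n_background=200, seed=0)
        assert "lonely[c]" not in {s.metabolite_id for s in scores}

    def test_no_gene_overlap_raises(self):
        model, _ = star_model(n_genes=2)
        with pytest.raises(ValueError, match="overlap"):
            es.reporter_metabolites(model, {"not_a_gene": 0.1})

    def test_null_scores_approximately_standard_normal(self):
        """Background correction must calibrate z_corrected to ~N(0,1).

        A single null score table leaves a shared-gene bias of up to ~0.15
        in the metabolite mean, so the check pools eight independent null
        tables on the same 50-gene network.
        """
        model = random_null_model(seed=0)
        pooled = []
        for score_seed in range(100, 108):
            rng = np.random.default_rng(score_seed)
            pvals = {f"g{i}": float(rng.uniform(0.001, 0.999))
                     for i in range(50)}
            scores = es.reporter_metabolites(model, pvals, n_background=3000,
                                             seed=7)
            pooled.extend(s.z_corrected for s in scores if s.k >= 3)
        pooled = np.array(pooled)
        assert abs(pooled.mean()) < 0.1
        assert 0.8 < pooled.std() < 1.2


class TestGreedySubnetwork:
    def plant(self, hot=range(2, 8), p_hot=0.001, p_null=0.6):
        model = chain10_model()
        pvals = {f"g{i}": (p_hot if i in hot else p_null) for i in range(9)}
        scores = es.reporter_metabolites(model, pvals, n_background=5000,
                                         seed=3)
        return model, scores

    def test_single_scored_metabolite_is_its_own_subnetwork(self):
        model, pvals = star_model(n_genes=2, p=0.001)
        scores = es.reporter_metabolites(model, pvals, n_background=500, seed=0)
        hub = [s for s in scores if s.metabolite_id == "hub[c]"]
        sub = es.greedy_reporter_subnetwork(model, hub, size_limit=5)
        assert sub.metabolite_ids == ["hub[c]"]
        assert sub.reaction_ids == {"R0", "R1"}

    def test_tie_broken_lexicographically(self):
        model, pvals = star_model(n_genes=2, p=0.2)
        scores = es.reporter_metabolites(model, pvals, n_background=500, seed=0)
        equal = [s for s in scores if s.metabolite_id.startswith("S")]
        assert equal[0].z_corrected == equal[1].z_corrected
        sub = es.greedy_reporter_subnetwork(model, equal, size_limit=1)
        assert sub.metabolite_ids == ["S0[c]"]

    def test_planted_signal_recovered_and_matches_exhaustive(self):
        """Greedy must find the five consecutive planted metabolites; an
        exhaustive search over all connected 5-subsets is the oracle."""
        model, scores = self.plant()
        sub = es.greedy_reporter_subnetwork(model, scores, size_limit=7)
        planted = {f"M{i}" for i in range(3, 8)}
        assert planted <= set(sub.metabolite_ids)

        z = {s.metabolite_id: s.z_corrected for s in scores}
        adj = {f"M{i}": {f"M{j}" for j in (i - 1, i + 1) if 0 <= j <= 9}
               for i in range(10)}
        best, best_mean = None, -np.inf
        for comb in itertools.combinations(z, 5):
            nodes = set(comb)
            stack, seen = [next(iter(nodes))], set()
            while stack:
                x = stack.pop()
                if x not in seen:
                    seen.add(x)
                    stack.extend(adj[x] & nodes)
            if seen != nodes:
                continue
            mean = np.mean([z[c] for c in comb])
            if mean > best_mean:
                best, best_mean = nodes, mean
        assert best == planted
        assert set(sub.metabolite_ids) >= best


class TestWelch:
    def test_identical_groups(self):
        c = es.welch_test([1, 2, 3], [1, 2, 3])
        assert c.t == 0.0
        assert c.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """Closed-form Welch on (1..4) vs (3..6): t = -2/sqrt(5/6), df = 6."""
        c = es.welch_test([1, 2, 3, 4], [3, 4, 5, 6])
        assert c.t == pytest.approx(-2.0 / np.sqrt(5 / 6), abs=1e-9)
        assert c.t == pytest.approx(-2.191, abs=1e-3)
        assert c.df == pytest.approx(6.0, abs=1e-9)

    def test_scale_invariance(self):
        a, b = [1.0, 2.5, 3.2], [2.1, 4.0, 4.4]
        c1 = es.welch_test(a, b)
        c2 = es.welch_test([10 * x for x in a], [10 * x for x in b])
        assert c1.t == pytest.approx(c2.t, abs=1e-12)
        assert c1.p == pytest.approx(c2.p, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 6)
        c = es.welch_test(a, b)
        ref = scipy.stats.ttest_ind(a, b, equal_var=False)
        assert c.t == pytest.approx(ref.statistic, abs=1e-12)
        assert c.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_equal_variance_equal_n_matches_pooled_t(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        welch = es.welch_test(a, b)
        pooled = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert welch.t == pytest.approx(pooled.statistic, abs=1e-12)

    def test_degenerate_cases(self):
        assert es.welch_test([2, 2, 2], [2, 2, 2]).p == 1.0
        with pytest.raises(ValueError, match="zero variance"):
            es.welch_test([2, 2, 2], [3, 3, 3])
        with pytest.raises(ValueError, match="n >= 2"):
            es.welch_test([1], [1, 2])


class TestBhFdr:
    def test_step_up_arithmetic(self):
        """(0.01,0.02,0.03,0.04): q_i = min over j>=i of p_j * 4/j = 0.04."""
        assert es.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_and_saturated(self):
        assert es.bh_fdr([0.3]) == pytest.approx([0.3])
        assert es.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        q = es.bh_fdr(p)
        q_perm = es.bh_fdr(p[perm])
        assert np.allclose(q[perm], q_perm)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        q = es.bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            es.bh_fdr([])


class TestMergeSegmentDe:
    def make(self, *entries):
        return DETable(entries=[DEGene(*e) for e in entries])

    def test_lowest_q_wins(self):
        merged = es.merge_segment_de([
            self.make(("gA", "up", 0.04)),
            self.make(("gA", "up", 0.01)),
        ])
        entry, = merged.entries
        assert entry.q_value == 0.01

    def test_conflicting_significant_directions_dropped(self):
        merged = es.merge_segment_de([
            self.make(("gA", "up", 0.01), ("gB", "down", 0.02)),
            self.make(("gA", "down", 0.01)),
        ])
        assert {e.gene_id for e in merged} == {"gB"}

    def test_insignificant_conflict_not_dropped(self):
        merged = es.merge_segment_de([
            self.make(("gA", "up", 0.01)),
            self.make(("gA", "down", 0.50)),   # not significant, no conflict
        ])
        entry, = merged.entries
        assert entry.direction == "up"

    def test_disjoint_tables_union(self):
        merged = es.merge_segment_de([
            self.make(("gA", "up", 0.1)),
            self.make(("gB", "down", 0.2)),
        ])
        assert {e.gene_id for e in merged} == {"gA", "gB"}
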