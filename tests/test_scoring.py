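import numpy as np
import pytest

from coevo import io as cio
from coevo.orthologs import OrthologSet, ScoredOrtholog
from coevo.scoring import (
    coevolution_score,
    distance_matrix,
    max_cooccurrence_distance,
    organism_distance,
    score_all_pairs,
    score_matrix,
)


def panel_with_counts(n_a, n_b):
    panel = cio.OrganismPanel()
    for i in range(n_a):
        panel.add(cio.GeneLocus("A", f"a{i}", "chr", i, "+", 100))
    for i in range(n_b):
        panel.add(cio.GeneLocus("B", f"b{i}", "chr", i, "+", 100))
    return panel


def selected_sets(pairs):
    sets = {}
    for a, b in pairs:
        c = ScoredOrtholog(a, "B", b, 90.0, 1.0, 90.0)
        sets[a] = OrthologSet(target_gene=a, candidates=[c], selected=[c])
    return sets


class TestOrganismDistance:
    def test_self_distance_is_zero(self):
        panel = panel_with_counts(2, 2)
        assert organism_distance(panel, {}, "A", "A") == 0.0

    def test_no_shared_genes_is_maximal(self):
        panel = panel_with_counts(3, 2)
        assert organism_distance(panel, {}, "A", "B") == 1.0

    def test_shared_fraction_arithmetic(self):
        # N(A)=5, N(B)=4, N(A,B)=3 -> 1 - 3/5
        panel = panel_with_counts(5, 4)
        sets = selected_sets([("a0", "b0"), ("a1", "b1"), ("a2", "b2")])
        assert organism_distance(panel, sets, "A", "B") == pytest.approx(0.4)

    def test_counts_pairs_selected_from_either_direction(self):
        panel = panel_with_counts(2, 2)
        # selection retained only from the B side
        c = ScoredOrtholog("b0", "A", "a0", 90.0, 1.0, 90.0)
        sets = {"b0": OrthologSet(target_gene="b0", candidates=[c], selected=[c])}
        assert organism_distance(panel, sets, "A", "B") == pytest.approx(0.5)

    def test_unknown_organism_is_fatal(self):
        panel = panel_with_counts(1, 1)
        with pytest.raises(KeyError):
            organism_distance(panel, {}, "A", "Q")

    def test_matrix_agrees_with_scalar_form(self, worked):
        panel, sets = worked["panel"], worked["sets"]
        d = worked["D"]
        orgs = panel.organisms
        for i, oa in enumerate(orgs):
            for j, ob in enumerate(orgs):
                assert d[i, j] == pytest.approx(organism_distance(panel, sets, oa, ob))
                assert d[i, j] == pytest.approx(d[j, i])


class TestMaxCooccurrenceDistance:
    def test_no_cooccurrence_gives_zero(self):
        d = np.ones((4, 4))
        assert max_cooccurrence_distance(np.zeros(4), np.ones(4), d) == 0.0

    def test_single_shared_organism_gives_zero(self):
        d = np.ones((4, 4))
        px = np.array([1, 0, 0, 0])
        assert max_cooccurrence_distance(px, px, d) == 0.0

    def test_two_shared_organisms_read_their_distance(self):
        d = np.zeros((3, 3))
        d[0, 2] = d[2, 0] = 0.7
        px = np.array([1, 0, 1])
        assert max_cooccurrence_distance(px, px, d) == pytest.approx(0.7)

    def test_matches_brute_force_pairwise_max(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 12))
            d = rng.uniform(0, 1, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            px = rng.integers(0, 2, size=n)
            py = rng.integers(0, 2, size=n)
            got = max_cooccurrence_distance(px, py, d)
            shared = [i for i in range(n) if px[i] and py[i]]
            if len(shared) <= 1:
                assert got == 0.0
            else:
                expect = max(d[i, j] for i in shared for j in shared)
                assert got == pytest.approx(expect)


class TestCoevolutionScore:
    def test_perfect_signal_scores_one(self):
        profiles = {"x": np.array([1, 1, 0]), "y": np.array([1, 1, 0])}
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = 1.0
        score = coevolution_score("x", "y", profiles, d, lambda a, b: 1.0)
        assert score.c == pytest.approx(1.0)

    def test_weighting_arithmetic(self):
        # phi=0.9 impossible to stage exactly with binary vectors, so check
        # the multiplicative form through its components on a staged case:
        # phi=1, dmax=0.5, K=0.9 -> C = 0.1125; and the printed worked case
        # 0.9 * 0.5**3 * 0.9 = 0.10125 as plain arithmetic of the formula
        profiles = {"x": np.array([1, 1, 0]), "y": np.array([1, 1, 0])}
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = 0.5
        score = coevolution_score("x", "y", profiles, d, lambda a, b: 0.9)
        assert score.c == pytest.approx(1.0 * 0.5**3 * 0.9)
        assert 0.9 * 0.5**3 * 0.9 == pytest.approx(0.10125)

    def test_symmetric_under_argument_swap(self, worked):
        profiles, d = worked["profiles"], worked["D"]
        k = lambda a, b: 1.0
        s1 = coevolution_score("a1_O1", "b1_O1", profiles, d, k)
        s2 = coevolution_score("b1_O1", "a1_O1", profiles, d, k)
        assert s1.c == pytest.approx(s2.c)
        assert s1.phi == pytest.approx(s2.phi)

    def test_cubic_weighting_is_monotone_in_dmax(self):
        profiles = {"x": np.array([1, 1, 0]), "y": np.array([1, 1, 0])}
        last = -1.0
        for dmax in np.linspace(0, 1, 21):
            d = np.zeros((3, 3))
            d[0, 1] = d[1, 0] = dmax
            c = coevolution_score("x", "y", profiles, d, lambda a, b: 1.0).c
            assert c >= last - 1e-15
            last = c


class TestScoreAllPairs:
    def test_three_genes_yield_three_unordered_pairs(self, worked):
        genes = ["a1_O1", "a2_O1", "b1_O1"]
        phi, dmax, c = score_matrix(genes, worked["profiles"], worked["D"], np.ones((3, 3)))
        iu = np.triu_indices(3, 1)
        assert len(iu[0]) == 3
        assert np.allclose(c, c.T)

    def test_impossible_threshold_empties_the_network(self, worked):
        genes = worked["genes"]
        net = score_all_pairs(
            genes, worked["profiles"], worked["D"], worked["K"], threshold=1.1
        )
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == len(genes)

    def test_raising_threshold_never_adds_edges(self, worked):
        genes = worked["genes"]
        prev = None
        for t in [0.02, 0.05, 0.08, 0.2, 0.3]:
            net = score_all_pairs(
                genes, worked["profiles"], worked["D"], worked["K"], threshold=t
            )
            edges = {frozenset(e) for e in net.edges}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_planted_modules_dominate_retained_network(self, worked):
        net = score_all_pairs(
            worked["genes"], worked["profiles"], worked["D"], worked["K"], threshold=0.07
        )
        mods = {g: g[0] for g in worked["genes"] if g[0] in "ab"}
        for u, v in net.edges:
            assert mods.get(u) == mods.get(v)  # only in-module edges survive
        in_a = sum(1 for u, v in net.edges if u.startswith("a"))
        assert in_a == 6  # all C(4,2) pairs of the four-gene module
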