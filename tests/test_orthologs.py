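import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import gaussian_kde

from coevo import io as cio
from coevo.orthologs import (
    OrthologSet,
    ScoredOrtholog,
    alignment_coverage,
    bidirectional_best_hits,
    build_ortholog_sets,
    hits_to_frame,
    score_density,
    select_orthologs,
    similarity_score,
)


def make_panel(org_genes, length=100):
    panel = cio.OrganismPanel()
    for org, genes in org_genes.items():
        for rank, g in enumerate(genes):
            panel.add(cio.GeneLocus(org, g, "chr", rank, "+", length))
    return panel


def cross_hits(panel, rows):
    """rows: (query, subject, identity, alen) -> reciprocal HitRecords."""
    hits = []
    for q, s, ident, alen in rows:
        self_hit = panel.organism_of(q) == panel.organism_of(s)
        hits.append(cio.HitRecord(q, s, ident, alen, self_hit))
        hits.append(cio.HitRecord(s, q, ident, alen, self_hit))
    return hits


class TestSimilarityScore:
    @pytest.mark.parametrize(
        "identity,coverage,expected",
        [(100.0, 1.0, 100.0), (0.0, 1.0, 0.0), (90.0, 0.5, 45.0)],
    )
    def test_product_of_identity_and_coverage(self, identity, coverage, expected):
        assert similarity_score(identity, coverage) == expected

    @pytest.mark.parametrize("identity,coverage", [(-1, 1.0), (101, 1.0), (50, 0.0), (50, 1.5)])
    def test_out_of_range_inputs_rejected(self, identity, coverage):
        with pytest.raises(ValueError):
            similarity_score(identity, coverage)

    def test_coverage_uses_longest_protein_and_clamps(self):
        assert alignment_coverage(50, 100, 200) == 0.25
        assert alignment_coverage(250, 100, 200) == 1.0


class TestBidirectionalBestHits:
    def test_mutual_best_pair(self):
        panel = make_panel({"A": ["a1"], "B": ["b1"]})
        hits = cross_hits(panel, [("a1", "b1", 90, 100)])
        assert bidirectional_best_hits(hits, panel, "A", "B") == [("a1", "b1")]

    def test_one_sided_best_is_unpaired(self):
        panel = make_panel({"A": ["a1", "a2"], "B": ["b1"]})
        # a1's best is b1 but b1's best is a2
        hits = cross_hits(panel, [("a1", "b1", 80, 100), ("a2", "b1", 95, 100)])
        assert bidirectional_best_hits(hits, panel, "A", "B") == [("a2", "b1")]

    def test_duplicate_hit_rows_keep_best_score(self):
        panel = make_panel({"A": ["a1"], "B": ["b1"]})
        hits = [
            cio.HitRecord("a1", "b1", 70.0, 50),
            cio.HitRecord("a1", "b1", 90.0, 100),
            cio.HitRecord("b1", "a1", 88.0, 100),
        ]
        frame = hits_to_frame(hits, panel)
        assert len(frame) == 1
        assert frame.iloc[0]["s"] == pytest.approx(90.0)

    def test_tie_breaks_are_deterministic(self):
        # equal s: higher identity wins; then lexicographic subject id
        panel = make_panel({"A": ["a1"], "B": ["b1", "b2"]})
        hits = cross_hits(
            panel, [("a1", "b1", 90, 50), ("a1", "b2", 45, 100)]
        )  # equal s = 45
        assert bidirectional_best_hits(hits, panel, "A", "B") == [("a1", "b1")]
        hits = cross_hits(
            panel, [("a1", "b2", 90, 100), ("a1", "b1", 90, 100)]
        )  # full tie: lexicographic
        assert bidirectional_best_hits(hits, panel, "A", "B") == [("a1", "b1")]

    @pytest.mark.parametrize("n,m,seed", [(5, 7, 0), (20, 20, 1), (50, 50, 2)])
    def test_matches_exhaustive_mutual_argmax(self, n, m, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(10, 95, size=(n, m))
        a_genes = [f"a{i:02d}" for i in range(n)]
        b_genes = [f"b{j:02d}" for j in range(m)]
        panel = make_panel({"A": a_genes, "B": b_genes})
        hits = cross_hits(
            panel,
            [
                (a_genes[i], b_genes[j], float(scores[i, j]), 100)
                for i in range(n)
                for j in range(m)
            ],
        )
        got = bidirectional_best_hits(hits, panel, "A", "B")
        # independent oracle: brute-force mutual argmax on the score matrix
        expect = []
        for i in range(n):
            j = int(np.argmax(scores[i]))
            if int(np.argmax(scores[:, j])) == i:
                expect.append((a_genes[i], b_genes[j]))
        assert got == sorted(expect)


class TestScoreDensity:
    def test_single_score_uses_unit_convention(self):
        assert score_density([42.0]).tolist() == [1.0]

    def test_identical_scores_share_one_density(self):
        d = score_density([50.0] * 5)
        assert np.all(d == d[0])

    def test_dense_mass_beats_outlier(self):
        scores = [80.0 + eps for eps in np.linspace(-1, 1, 10)] + [20.0]
        d = score_density(scores)
        assert d[0] > d[-1]

    def test_matches_scipy_silverman_kde(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(20, 95, size=25)
        expect = gaussian_kde(scores, bw_method="silverman")(scores)
        assert np.allclose(score_density(scores), expect, atol=1e-12)

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(20, 95, size=15)
        perm = rng.permutation(15)
        assert np.allclose(score_density(scores)[perm], score_density(scores[perm]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            score_density([])


def candidates_from_scores(scores):
    return [
        ScoredOrtholog("g", f"org{i}", f"o{i}", s, 1.0, s)
        for i, s in enumerate(scores)
    ]


def oracle_selection(scores):
    """Independent evaluation of the retention rule (scipy KDE)."""
    s = np.asarray(scores, dtype=float)
    if s.size == 1 or np.ptp(s) == 0:
        d = np.ones_like(s)
    else:
        d = gaussian_kde(s, bw_method="silverman")(s)
    mask = (s > s.mean()) | (d > d.mean())
    if not mask.any():
        mask[:] = True
    return set(np.flatnonzero(mask).tolist())


class TestSelectOrthologs:
    def test_above_mean_scores_pass(self):
        oset = select_orthologs(candidates_from_scores([90.0, 80.0, 10.0]))
        kept = {c.s for c in oset.selected}
        assert {90.0, 80.0} <= kept
        assert kept == {c.s for i, c in enumerate(oset.candidates) if i in oracle_selection([90, 80, 10])}

    def test_all_equal_scores_all_retained(self):
        oset = select_orthologs(candidates_from_scores([50.0] * 4))
        assert len(oset.selected) == 4

    def test_clustered_mass_retained_outlier_dropped(self):
        scores = [80.0 + e for e in np.linspace(-2, 2, 10)] + [20.0]
        oset = select_orthologs(candidates_from_scores(scores))
        kept = {c.organism for c in oset.selected}
        assert "org10" not in kept  # the lone low-score candidate
        assert kept == {f"org{i}" for i in oracle_selection(scores)}

    def test_empty_candidates_empty_selection(self):
        oset = select_orthologs([])
        assert oset.selected == [] and oset.candidates == []

    @given(st.lists(st.floats(1.0, 99.0), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_union_rule_contains_mean_rule_and_matches_oracle(self, scores):
        cands = candidates_from_scores(scores)
        oset = select_orthologs(cands)
        kept = {c.organism for c in oset.selected}
        s = np.asarray(scores)
        eq2 = {c.organism for c in cands if c.s > s.mean()}
        assert eq2 <= kept
        assert kept == {f"org{i}" for i in oracle_selection(scores)}

    @given(st.lists(st.floats(1.0, 99.0), min_size=2, max_size=30), st.randoms())
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_selection_ignores_candidate_order(self, scores, rnd):
        cands = candidates_from_scores(scores)
        shuffled = list(cands)
        rnd.shuffle(shuffled)
        kept_a = {c.organism for c in select_orthologs(cands).selected}
        kept_b = {c.organism for c in select_orthologs(shuffled).selected}
        assert kept_a == kept_b


class TestBuildOrthologSets:
    def test_paralog_hits_never_become_candidates(self):
        panel = make_panel({"A": ["a1", "a2"], "B": ["b1"]})
        hits = cross_hits(panel, [("a1", "b1", 90, 100), ("a1", "a2", 99, 100)])
        sets = build_ortholog_sets(hits, panel)
        assert {c.organism for c in sets["a1"].candidates} == {"B"}

    def test_every_panel_gene_gets_a_set(self):
        panel = make_panel({"A": ["a1"], "B": ["b1"], "C": ["c1"]})
        sets = build_ortholog_sets([], panel)
        assert set(sets) == {"a1", "b1", "c1"}
        assert all(s.candidates == [] for s in sets.values())

    def test_consistent_with_per_pair_bbh(self, worked):
        res, panel = worked["res"], worked["panel"]
        sets = worked["sets"]
        for org_a, org_b in [("O1", "O2"), ("O1", "O4"), ("O2", "O5")]:
            pairs = bidirectional_best_hits(res.hits, panel, org_a, org_b)
            for a, b in pairs:
                assert any(c.ortholog_gene == b for c in sets[a].candidates)
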