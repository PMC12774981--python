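"""Elite-pair inference: FPI threshold rule, IBS/QGI, clustering/DAPC/PGI."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elitepool import (
    AcceptableRange,
    TraitArchitecture,
    dapc_fit,
    evaluate_approaches,
    find_clusters,
    fpi_classify,
    ibs_matrix,
    optimize_a_score,
    pgi_select_pairs,
    qgi_classify,
    true_elite_type,
)
from elitepool.inference import ElitePairCall, IBSMatrix, call_all_pairs_qgi

from conftest import build_panel

WINDOW = AcceptableRange(52.5, 57.5)


def _arch(qtl_sites, effect, h2=0.6):
    qtl_sites = np.asarray(qtl_sites)
    return TraitArchitecture(
        name="t", trait_role="attained", qtl_sites=qtl_sites,
        effects=np.full(len(qtl_sites), float(effect)), h2=h2,
        target_mean=55.0, target_variance=10.0, intercept=55.0,
        Ve=10.0 * 0.4 / 0.6, acceptable_range=WINDOW,
    )


class TestFpi:
    @pytest.mark.parametrize(
        "n_outside,expected", [(80, "allo"), (75, "iso"), (76, "allo"), (0, "iso")]
    )
    def test_threshold_is_strict(self, random_panel, n_outside, expected):
        arch = _arch([0, 1], 4.0)
        phenos = np.full(100, 55.0)
        phenos[:n_outside] = 70.0  # far outside the window
        call = fpi_classify(
            random_panel, 0, 1, arch, np.random.default_rng(0), f2_phenotypes=phenos
        )
        assert call.call == expected
        assert call.score == pytest.approx(n_outside / 100)

    def test_identical_homozygous_parents_with_no_noise_are_iso(self):
        haps = np.zeros((2, 2, 6), dtype=np.int8)
        haps[:, :, 0] = 1  # both parents homozygous derived at the QTL
        panel = build_panel(haps)
        arch = _arch([0], 4.0, h2=1.0)
        arch.Ve = 0.0
        arch.intercept = 53.0  # genotype value 8 -> phenotype 61? keep in range:
        arch.intercept = 47.0  # 47 + 2*4 = 55, mid-window
        call = fpi_classify(panel, 0, 1, arch, np.random.default_rng(1), n_f2=50,
                            heritability_mode="fixed")
        assert call.call == "iso" and call.score == 0.0

    def test_invalid_threshold_rejected(self, random_panel):
        arch = _arch([0], 4.0)
        with pytest.raises(ValueError):
            fpi_classify(random_panel, 0, 1, arch, np.random.default_rng(0),
                         threshold=1.0, f2_phenotypes=np.zeros(10))


class TestIbsAndQgi:
    def test_matches_brute_force_per_site_oracle(self, random_panel):
        markers = np.arange(0, 40, 3)
        ibs = ibs_matrix(random_panel, markers)
        from elitepool import dosage_matrix

        d = dosage_matrix(random_panel, markers)
        n = len(random_panel.ids)
        for i, j in itertools.combinations(range(n), 2):
            brute = np.mean([d[i, k] == d[j, k] for k in range(d.shape[1])])
            assert ibs.values[i, j] == pytest.approx(brute)

    def test_symmetric_unit_diagonal_bounded(self, random_panel):
        ibs = ibs_matrix(random_panel, np.arange(10))
        assert np.allclose(ibs.values, ibs.values.T)
        assert np.allclose(np.diag(ibs.values), 1.0)
        assert ibs.values.min() >= 0 and ibs.values.max() <= 1

    def test_empty_marker_set_rejected(self, random_panel):
        with pytest.raises(ValueError):
            ibs_matrix(random_panel, np.array([], dtype=int))

    def test_qgi_strict_rule(self):
        ibs = IBSMatrix(ids=["a", "b", "c"], values=np.array(
            [[1.0, 1.0, 0.999], [1.0, 1.0, 0.5], [0.999, 0.5, 1.0]]
        ))
        assert qgi_classify(("a", "b"), ibs).call == "iso"
        assert qgi_classify(("a", "c"), ibs).call == "allo"
        with pytest.raises(KeyError):
            qgi_classify(("a", "zzz"), ibs)

    def test_qgi_equals_truth_on_causal_markers(self):
        """On homozygous lines with markers = causal QTLs, the QGI call is the
        ground-truth elite type by construction."""
        rng = np.random.default_rng(2)
        haps = np.repeat(rng.integers(0, 2, size=(12, 1, 25)), 2, axis=1).astype(np.int8)
        panel = build_panel(haps)
        arch = _arch([2, 9, 17], 2.0)
        calls = call_all_pairs_qgi(panel, arch.qtl_sites)
        for call in calls:
            truth = true_elite_type(panel, call.pair[0], call.pair[1], arch)
            assert call.call == truth

    def test_truth_requires_homozygous_lines(self, random_panel):
        arch = _arch([0, 1, 2], 2.0)
        with pytest.raises(ValueError, match="heterozygous"):
            true_elite_type(random_panel, 0, 1, arch)

    @given(st.permutations(range(8)))
    @settings(deadline=None, max_examples=15)
    def test_calls_invariant_to_line_relabeling(self, perm):
        rng = np.random.default_rng(3)
        haps = np.repeat(rng.integers(0, 2, size=(8, 1, 12)), 2, axis=1).astype(np.int8)
        panel = build_panel(haps)
        markers = np.arange(12)
        ibs = ibs_matrix(panel, markers)
        shuffled = panel.subset(list(perm))
        ibs2 = ibs_matrix(shuffled, markers)
        for i, j in itertools.combinations(range(8), 2):
            a, b = panel.ids[perm[i]], panel.ids[perm[j]]
            assert ibs2.pair(a, b) == pytest.approx(ibs.pair(a, b))


def _blobs(rng, n_per=30, sep=40.0, n_feat=12, k=2):
    centers = rng.integers(0, 2, size=(k, n_feat)) * sep
    X = np.vstack([centers[i] + rng.normal(0, 1, size=(n_per, n_feat)) for i in range(k)])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


class TestClustering:
    def test_two_separated_blobs_found(self):
        rng = np.random.default_rng(4)
        X, labels = _blobs(rng)
        sol = find_clusters(X, np.random.default_rng(5), max_k=5, n_pcs=5)
        assert sol.k == 2
        # assignments match generating labels up to relabeling
        same = (sol.assignments[:30] == sol.assignments[0]).all() and (
            sol.assignments[30:] == sol.assignments[30]
        ).all()
        assert same and sol.assignments[0] != sol.assignments[30]

    def test_identical_points_give_one_cluster(self):
        X = np.zeros((20, 5))
        sol = find_clusters(X, np.random.default_rng(6), max_k=4, n_pcs=3)
        assert sol.k == 1

    def test_bic_scan_covers_requested_range(self):
        rng = np.random.default_rng(7)
        X, _ = _blobs(rng, k=3)
        sol = find_clusters(X, np.random.default_rng(8), max_k=6, n_pcs=6)
        assert set(sol.bic) == set(range(1, 7))

    def test_npcs_too_large_rejected(self):
        with pytest.raises(ValueError):
            find_clusters(np.zeros((5, 3)), np.random.default_rng(0), n_pcs=10)


class TestDapc:
    def test_perfect_separation_reassigns_fully(self):
        rng = np.random.default_rng(9)
        X, labels = _blobs(rng)
        model = dapc_fit(X, labels, n_pcs=4)
        assert model.reassignment_by_cluster == {0: 1.0, 1: 1.0}
        assert model.n_axes == 1  # min(k-1, n_pcs)

    def test_axis_count_bound(self):
        rng = np.random.default_rng(10)
        X, labels = _blobs(rng, k=4, n_per=15)
        model = dapc_fit(X, labels, n_pcs=6)
        assert model.n_axes == min(4 - 1, 6)

    def test_random_labels_on_noise_reassign_near_chance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(120, 10))
        rates = []
        for rep in range(30):
            labels = np.random.default_rng(rep).integers(0, 3, size=120)
            rates.append(dapc_fit(X, labels, n_pcs=4).mean_reassignment)
        # slightly above 1/k from LDA overfitting on 4 PCs; wide 3 SE band
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - 1 / 3) < 3 * se + 0.12

    def test_a_score_prefers_informative_pcs_and_stays_in_candidates(self):
        rng = np.random.default_rng(12)
        X, labels = _blobs(rng, sep=25.0)
        best = optimize_a_score(X, labels, [1, 2, 5], np.random.default_rng(13),
                                n_permutations=5)
        assert best in (1, 2, 5)
        model = dapc_fit(X, labels, best)
        null = dapc_fit(X, np.random.default_rng(1).permutation(labels), best)
        assert model.mean_reassignment - null.mean_reassignment > 0.3

    def test_a_score_near_zero_on_structureless_data(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(80, 8))
        labels = rng.integers(0, 2, size=80)
        obs = dapc_fit(X, labels, 3).mean_reassignment
        nulls = [
            dapc_fit(X, np.random.default_rng(r).permutation(labels), 3).mean_reassignment
            for r in range(10)
        ]
        assert abs(obs - np.mean(nulls)) < 0.2


class TestPgiPairs:
    def test_euclidean_three_four_five(self):
        from elitepool.inference import DAPCModel

        coords = np.array([[0.0, 0.0], [3.0, 4.0], [0.5, 0.5]])
        model = DAPCModel(
            n_pcs=2, pc_scores=coords, coordinates=coords,
            assignments=np.zeros(3, dtype=int), predicted=np.zeros(3, dtype=int),
            reassignment_by_cluster={0: 1.0}, ids=["a", "b", "c"],
        )
        # force a second cluster so DAPC preconditions hold for selection
        model.assignments = np.array([0, 0, 0])
        iso, allo = pgi_select_pairs(model)
        assert allo[0].pair == ("a", "b") and allo[0].score == pytest.approx(5.0)

    def test_min_max_match_brute_force_scan(self):
        rng = np.random.default_rng(15)
        X, labels = _blobs(rng, n_per=20)
        model = dapc_fit(X, labels, n_pcs=3, ids=[f"l{i}" for i in range(40)])
        iso, allo = pgi_select_pairs(model)
        best = max(
            model.reassignment_by_cluster,
            key=lambda c: (model.reassignment_by_cluster[c], (model.assignments == c).sum()),
        )
        members = np.flatnonzero(model.assignments == best)
        coords = model.coordinates[members][:, : min(2, model.n_axes)]
        dists = {
            (model.ids[members[i]], model.ids[members[j]]): np.linalg.norm(coords[i] - coords[j])
            for i, j in itertools.combinations(range(len(members)), 2)
        }
        assert iso[0].score == pytest.approx(min(dists.values()))
        assert allo[0].score == pytest.approx(max(dists.values()))

    def test_two_member_cluster_flags_degenerate(self):
        from elitepool.inference import DAPCModel

        coords = np.array([[0.0], [1.0], [10.0], [11.0], [12.0]])
        model = DAPCModel(
            n_pcs=1, pc_scores=coords, coordinates=coords,
            assignments=np.array([0, 0, 1, 1, 1]),
            predicted=np.array([0, 0, 1, 1, 1]),
            reassignment_by_cluster={0: 1.0, 1: 0.9},
            ids=list("abcde"),
        )
        iso, allo = pgi_select_pairs(model)
        assert iso[0].pair == allo[0].pair == ("a", "b")
        assert iso[0].degenerate and allo[0].degenerate


class TestEvaluation:
    def test_accuracy_and_conservation(self):
        calls = [
            ElitePairCall(("a", "b"), "QGI", 1.0, "iso", truth="iso"),
            ElitePairCall(("a", "c"), "QGI", 0.5, "allo", truth="allo"),
            ElitePairCall(("b", "c"), "QGI", 0.5, "allo", truth="iso"),
            ElitePairCall(("a", "d"), "FPI", 0.8, "allo", truth="allo"),
        ]
        table = evaluate_approaches(calls)
        qgi = table.query("approach == 'QGI'").iloc[0]
        assert qgi["accuracy"] == pytest.approx(2 / 3)
        assert qgi["n_iso_called"] + qgi["n_allo_called"] == qgi["n_pairs"]
        assert table.query("approach == 'FPI'").iloc[0]["accuracy"] == 1.0

    def test_missing_truth_rejected(self):
        calls = [ElitePairCall(("a", "b"), "QGI", 1.0, "iso")]
        with pytest.raises(ValueError, match="truth"):
            evaluate_approaches(calls)
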