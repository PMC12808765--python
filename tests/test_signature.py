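"""Signature derivation: shared-effect filter, clustering, onset selection, scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from grsig import normde, signature, simulate
from grsig.errors import DataError
from conftest import dex_vs_vehicle_groups


def _de_frame(logfc, fdr, genes=None):
    genes = genes or [f"g{i}" for i in range(len(logfc))]
    return pd.DataFrame({"logFC": logfc, "fdr": fdr,
                         "p_value": fdr}, index=genes)


class TestSharedEffect:
    def test_concordant_significant_gene_included(self):
        a = _de_frame([2.5], [1e-4])
        b = _de_frame([2.2], [1e-3])
        assert list(signature.shared_effect_genes(a, b)) == ["g0"]

    def test_sign_discordant_gene_excluded(self):
        a = _de_frame([2.5], [1e-4])
        b = _de_frame([-2.5], [1e-4])
        assert len(signature.shared_effect_genes(a, b)) == 0
        params = signature.SignatureParams(require_sign_concordance=False)
        assert len(signature.shared_effect_genes(a, b, params)) == 1

    def test_both_directions_retained(self):
        a = _de_frame([2.5, -2.5], [1e-4, 1e-4])
        b = _de_frame([2.2, -2.2], [1e-4, 1e-4])
        assert set(signature.shared_effect_genes(a, b)) == {"g0", "g1"}

    def test_disjoint_universes_error(self):
        a = _de_frame([2.5], [1e-4], genes=["x"])
        b = _de_frame([2.5], [1e-4], genes=["y"])
        with pytest.raises(DataError):
            signature.shared_effect_genes(a, b)

    def test_matches_direct_rule_on_planted_data(self, small_counts):
        _, counts, samples, truth = small_counts
        keep = normde.filter_low_expressed(counts, samples)
        lcpm = normde.logcpm(counts.loc[keep], normde.tmm_factors(counts.loc[keep]))
        de = {}
        for m in ("A", "B"):
            ga, gb = dex_vs_vehicle_groups(samples, m, "24h")
            de[m] = normde.de_test(lcpm, ga, gb)
        got = set(signature.shared_effect_genes(de["A"], de["B"]))
        want = set()
        for g in de["A"].index:
            ra, rb = de["A"].loc[g], de["B"].loc[g]
            if (abs(ra.logFC) > 2 and ra.fdr < 0.01 and abs(rb.logFC) > 2
                    and rb.fdr < 0.01 and np.sign(ra.logFC) == np.sign(rb.logFC)):
                want.add(g)
        assert got == want


class TestCenterAndCluster:
    def test_mean_center_rows(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                         index=["a", "b"], columns=["s1", "s2", "s3"])
        c = signature.mean_center(m, ["a", "b"])
        assert np.allclose(c.loc["a"], [-1, 0, 1])
        assert np.allclose(c.loc["b"], 0)

    def test_row_means_vanish_on_random_matrix(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(30, 10)),
                         index=[f"g{i}" for i in range(30)])
        c = signature.mean_center(m, list(m.index))
        assert np.abs(c.mean(axis=1)).max() < 1e-12

    def test_unknown_gene_is_an_error(self):
        m = pd.DataFrame([[1.0]], index=["a"], columns=["s"])
        with pytest.raises(DataError):
            signature.mean_center(m, ["zzz"])

    def test_recovers_four_separated_profiles(self):
        rng = np.random.default_rng(1)
        protos = np.array([
            [3, 3, 3, 3], [0, 0, 3, 3], [-3, -3, -3, -3], [0, 0, -3, -3],
        ], dtype=float)
        rows, labels = [], []
        for k, proto in enumerate(protos):
            for _ in range(40):
                rows.append(np.repeat(proto, 6) + rng.normal(0, 0.3, 24))
                labels.append(k)
        m = pd.DataFrame(rows, index=[f"g{i}" for i in range(160)])
        got, inertia = signature.kmeans_cluster(m, signature.SignatureParams(seed=0))
        assert adjusted_rand_score(labels, got.to_numpy()) >= 0.95
        assert inertia > 0

    def test_identical_rows_have_zero_inertia(self):
        m = pd.DataFrame(np.ones((10, 4)), index=[f"g{i}" for i in range(10)])
        _, inertia = signature.kmeans_cluster(
            m, signature.SignatureParams(k=2, n_restarts=5, seed=0))
        assert inertia == pytest.approx(0.0, abs=1e-12)

    def test_fewer_rows_than_k_is_an_error(self):
        m = pd.DataFrame(np.ones((2, 4)), index=["a", "b"])
        with pytest.raises(DataError):
            signature.kmeans_cluster(m, signature.SignatureParams(k=4))


class TestOnsetAndSelection:
    @staticmethod
    def _design():
        rows = []
        for m in ("A", "B"):
            for trt in ("vehicle", "dex"):
                for tp in ("8h", "24h"):
                    for r in (1, 2):
                        rows.append({"sample_id": f"{m}_{trt}_{tp}_r{r}", "model": m,
                                     "treatment": trt, "timepoint": tp, "replicate": r})
        return pd.DataFrame(rows)

    def test_constant_matrix_has_zero_onset(self):
        samples = self._design()
        m = pd.DataFrame(np.ones((3, len(samples))), columns=samples.sample_id,
                         index=["a", "b", "c"])
        assert signature.onset_score(["a", "b"], m, samples) == 0.0

    def test_uniform_plus_two_onset(self):
        samples = self._design()
        m = pd.DataFrame(np.zeros((2, len(samples))), columns=samples.sample_id,
                         index=["a", "b"])
        dex8 = samples.loc[(samples.treatment == "dex") & (samples.timepoint == "8h"),
                           "sample_id"]
        m[list(dex8)] = 2.0
        dex24 = samples.loc[(samples.treatment == "dex") & (samples.timepoint == "24h"),
                            "sample_id"]
        m[list(dex24)] = 1.0  # irrelevant to the onset definition
        assert signature.onset_score(["a", "b"], m, samples) == pytest.approx(2.0)

    def test_matches_direct_two_mean_computation(self):
        samples = self._design()
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(5, len(samples))), columns=samples.sample_id,
                         index=[f"g{i}" for i in range(5)])
        got = signature.onset_score(["g0", "g3"], m, samples)
        dex8 = samples.loc[(samples.treatment == "dex") & (samples.timepoint == "8h"),
                           "sample_id"]
        veh = samples.loc[samples.treatment == "vehicle", "sample_id"]
        want = np.mean([m.loc[g, list(dex8)].mean() - m.loc[g, list(veh)].mean()
                        for g in ("g0", "g3")])
        assert got == pytest.approx(want, abs=1e-12)

    def test_argmax_onset_cluster_selected(self):
        samples = self._design()
        dex8 = list(samples.loc[(samples.treatment == "dex")
                                & (samples.timepoint == "8h"), "sample_id"])
        onsets = [-1.0, 0.5, 2.0, 0.1]
        rows, labels = [], []
        for lab, ons in enumerate(onsets):
            for i in range(3):
                row = pd.Series(0.0, index=samples.sample_id)
                row[dex8] = ons
                rows.append(row)
                labels.append(lab)
        m = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        lab = pd.Series(labels, index=m.index)
        sig = signature.select_signature(lab, m, samples)
        assert sig.cluster_label == 2
        assert set(sig.gene_ids) == {"g6", "g7", "g8"}
        assert sig.onset_scores[2] == pytest.approx(2.0)

    def test_no_positive_onset_is_an_error(self):
        samples = self._design()
        dex8 = list(samples.loc[(samples.treatment == "dex")
                                & (samples.timepoint == "8h"), "sample_id"])
        m = pd.DataFrame(0.0, index=["a", "b"], columns=samples.sample_id)
        m.loc[:, dex8] = -1.0
        lab = pd.Series([0, 1], index=["a", "b"])
        with pytest.raises(DataError, match="positive"):
            signature.select_signature(lab, m, samples)


class TestTiming:
    def test_rule_table(self):
        sig, ns = 1e-4, 0.5
        de8a = _de_frame([-2.0, 0.1, 2.0], [sig, ns, sig])
        de8b = _de_frame([-2.0, 0.1, 2.0], [sig, ns, sig])
        de24a = _de_frame([-2.0, -2.0, 2.0], [sig, sig, sig])
        de24b = _de_frame([-2.0, -2.0, 2.0], [sig, sig, sig])
        got = signature.classify_response_timing(de8a, de8b, de24a, de24b)
        assert got.tolist() == ["early_down", "late_down", "early_up"]

    def test_planted_recovery(self, default_counts):
        _, counts, samples, truth = default_counts
        keep = normde.filter_low_expressed(counts, samples)
        lcpm = normde.logcpm(counts.loc[keep], normde.tmm_factors(counts.loc[keep]))
        de = {}
        for m in ("A", "B"):
            for tp in ("8h", "24h"):
                ga, gb = dex_vs_vehicle_groups(samples, m, tp)
                de[(m, tp)] = normde.de_test(lcpm, ga, gb)
        got = signature.classify_response_timing(
            de[("A", "8h")], de[("B", "8h")], de[("A", "24h")], de[("B", "24h")])
        planted = truth.loc[got.index, "planted_class"]
        for cls in simulate.PLANTED_CLASSES:
            genes = planted.index[planted == cls]
            assert (got.loc[genes] == cls).mean() >= 0.9, cls


def _sig(genes):
    return signature.Signature(gene_ids=tuple(genes), cluster_label=0,
                               onset_scores={0: 1.0}, inertia=0.0)


class TestScoring:
    def test_sum_of_expression(self):
        expr = pd.DataFrame({"s1": [3.0, 4.0]}, index=["g1", "g2"])
        got = signature.score_samples(expr, _sig(["g1", "g2"]))
        assert got["s1"] == pytest.approx(7.0)

    def test_constant_shift_is_linear_in_signature_size(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(4, 3)), index=list("abcd"))
        sig = _sig(["a", "c"])
        base = signature.score_samples(expr, sig)
        shifted = signature.score_samples(expr + 1.5, sig)
        assert np.allclose(shifted - base, 2 * 1.5)

    def test_partial_overlap_warns_then_errors(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning):
            got = signature.score_samples(expr, _sig(["g1", "g2", "g3", "g4"]))
        assert got["s1"] == pytest.approx(3.0)
        with pytest.raises(DataError):
            signature.score_samples(expr, _sig(["g1", "x", "y", "z"]))

    def test_cohort_score_tracks_planted_score(self, cohort_default):
        cfg, cohort, truth = cohort_default
        sig = _sig(cfg.resolved_signature())
        got = signature.score_cohort(cohort, sig)
        r = stats.pearsonr(got, truth["score"]).statistic
        assert r >= 0.99


class TestDeriveSignature:
    def test_recovers_planted_early_up(self, default_counts):
        _, counts, samples, truth = default_counts
        sig = signature.derive_signature(counts, samples,
                                         signature.SignatureParams(seed=1))
        planted = set(truth.index[truth.planted_class == "early_up"])
        got = set(sig.gene_ids)
        assert len(got & planted) / len(got | planted) >= 0.9
        # containment chain: signature <= shared-effect <= filtered universe
        assert sig.provenance["n_signature"] <= sig.provenance["n_shared_effect"]
        assert sig.provenance["n_shared_effect"] <= sig.provenance["n_after_filter"]
        # selected cluster has the maximal onset by construction
        assert sig.onset_scores[sig.cluster_label] == max(sig.onset_scores.values())

    def test_deterministic_and_order_invariant(self, small_counts):
        _, counts, samples, _ = small_counts
        params = signature.SignatureParams(seed=5)
        a = signature.derive_signature(counts, samples, params)
        b = signature.derive_signature(counts, samples, params)
        assert a.gene_ids == b.gene_ids
        rng = np.random.default_rng(0)
        counts_shuf = counts.iloc[rng.permutation(len(counts))]
        counts_shuf = counts_shuf[list(counts.columns[::-1])]
        c = signature.derive_signature(counts_shuf, samples, params)
        assert set(c.gene_ids) == set(a.gene_ids)

    def test_no_effect_anywhere_is_an_error(self):
        cfg = simulate.SimCountConfig(n_genes=400, class_sizes={}, effect=0.0, seed=2)
        counts, samples, _ = simulate.simulate_counts(cfg)
        with pytest.raises(DataError):
            signature.derive_signature(counts, samples)

    def test_roundtrip_json(self, tmp_path, small_counts):
        _, counts, samples, _ = small_counts
        sig = signature.derive_signature(counts, samples,
                                         signature.SignatureParams(seed=5))
        path = tmp_path / "sig.json"
        sig.to_json(path)
        back = signature.Signature.from_json(path)
        assert back.gene_ids == sig.gene_ids
        assert back.onset_scores == sig.onset_scores
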