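"""Reference network and per-patient perturbation statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from idpn.features import FEATURE_NAMES, edge_list
from idpn.network import (
    batch_idpn,
    build_reference_network,
    compute_idpn,
    idpn_edge_table,
    spearman_matrix,
)

from conftest import make_feature_table


def brute_spearman(x, y):
    """Independent oracle: Pearson correlation of average ranks, computed
    directly from sorted positions."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearmanMatrix:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([x, np.exp(x)])
        scc = spearman_matrix(X)
        assert scc[0, 1] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        x = rng.normal(size=40)
        scc = spearman_matrix(np.column_stack([x, -x]))
        assert scc[0, 1] == pytest.approx(-1.0)

    def test_small_example(self):
        # d^2 sum = 4 over n = 5: rho = 1 - 6*4/(5*24) = 0.8
        X = np.column_stack([[1, 2, 3, 4, 5], [2, 1, 4, 3, 5]])
        assert spearman_matrix(X)[0, 1] == pytest.approx(0.8)

    def test_matches_scipy_with_ties(self, rng):
        X = rng.integers(0, 5, size=(30, 4)).astype(float)
        scc = spearman_matrix(X)
        expected = stats.spearmanr(X).statistic
        np.testing.assert_allclose(scc, expected, atol=1e-12)

    def test_constant_feature_named(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="feature_1"):
            spearman_matrix(X)

    def test_too_few_respondents(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman_matrix(np.ones((2, 3)))


class TestReferenceNetwork:
    def test_edge_count_is_136(self, rng):
        table = make_feature_table(rng.normal(size=(50, 17)))
        ref = build_reference_network(table)
        assert ref.n_edges == 136 == len(edge_list(ref.feature_names))

    def test_order_invariance(self, rng):
        X = rng.normal(size=(40, 17))
        t1 = make_feature_table(X)
        t2 = make_feature_table(X[::-1], ids=[f"R{i:04d}" for i in range(39, -1, -1)])
        np.testing.assert_allclose(
            build_reference_network(t1).scc, build_reference_network(t2).scc
        )

    def test_flagged_patient_rejected(self, rng):
        table = make_feature_table(rng.normal(size=(10, 17)))
        table.loc[3, "nssi_flag"] = True
        with pytest.raises(ValueError, match="NSSI-free"):
            build_reference_network(table)


class TestComputeIdpn:
    def test_null_patient_edge(self, rng):
        """An edge whose perturbed correlation equals the reference has z = 0,
        p = 1, and is not significant."""
        X = rng.normal(size=(20, 17))
        controls = make_feature_table(X)
        ref = build_reference_network(controls)
        patient = controls.iloc[5].copy()
        patient["respondent_id"] = "P0001"
        net = compute_idpn(ref, controls, patient)
        # ties with an existing row leave many edges nearly unperturbed; check
        # the exact identity delta == 0 -> z == 0, p == 1 entrywise
        zero = np.isclose(net.delta, 0.0, atol=0)
        assert np.all(net.z[zero & net.evaluable] == 0)
        assert np.all(net.p[zero & net.evaluable] == 1.0)
        assert not net.sig[zero].any()

    def test_z_matches_ratio_formula(self, rng):
        """z(i,j) = delta / ((1 - scc^2)/(n-1)) exactly, for every edge."""
        X = rng.normal(size=(25, 17))
        controls = make_feature_table(X)
        ref = build_reference_network(controls)
        patient = make_feature_table(rng.normal(size=(1, 17)), ids=["P1"]).iloc[0]
        net = compute_idpn(ref, controls, patient)
        with np.errstate(invalid="ignore"):
            expected = net.delta / ((1 - ref.scc**2) / (ref.n - 1))
        iu = np.triu_indices(17, 1)
        np.testing.assert_allclose(net.z[iu], expected[iu], atol=1e-13)

    def test_formula_point_value(self):
        # scc = 0.5, n = 10, delta = 0.1 -> z = 0.1 / (0.75/9) = 1.2
        assert 0.1 / ((1 - 0.5**2) / (10 - 1)) == pytest.approx(1.2)

    def test_bonferroni_cutoff(self):
        # alpha 0.05 over 136 edges: two-sided p < 3.6765e-4, i.e. |z| > 3.5623
        cutoff = stats.norm.isf(0.05 / 136 / 2)
        assert cutoff == pytest.approx(3.56228, abs=5e-5)
        assert 0.05 / 136 == pytest.approx(3.6765e-4, abs=5e-8)
        assert 2 * stats.norm.sf(cutoff) == pytest.approx(0.05 / 136)

    def test_sign_and_dominance(self, rng):
        X = rng.normal(size=(30, 17))
        controls = make_feature_table(X)
        ref = build_reference_network(controls)
        patient = make_feature_table(5 * rng.normal(size=(1, 17)), ids=["P1"]).iloc[0]
        net = compute_idpn(ref, controls, patient)
        ev = net.evaluable
        assert np.all(np.sign(net.z[ev]) == np.sign(net.delta[ev]))
        assert net.sig.sum() <= (net.p[ev] < net.alpha).sum()

    def test_degenerate_edge_flagged(self, rng):
        """A reference correlation of exactly +/-1 yields a non-evaluable
        edge rather than an infinite z."""
        x = rng.normal(size=30)
        X = rng.normal(size=(30, 17))
        X[:, 0], X[:, 1] = x, 2 * x + 1  # strictly monotone pair: scc = 1
        controls = make_feature_table(X)
        ref = build_reference_network(controls)
        patient = make_feature_table(rng.normal(size=(1, 17)), ids=["P1"]).iloc[0]
        net = compute_idpn(ref, controls, patient)
        assert not net.evaluable[0, 1]
        assert np.isnan(net.z[0, 1]) and not net.sig[0, 1]

    def test_monotone_in_delta_and_n(self):
        z = lambda delta, scc, n: delta / ((1 - scc**2) / (n - 1))
        assert abs(z(0.2, 0.5, 10)) > abs(z(0.1, 0.5, 10))
        assert abs(z(0.1, 0.5, 50)) > abs(z(0.1, 0.5, 10))

    def test_sqrt_variant_larger_denominator(self, rng):
        X = rng.normal(size=(40, 17))
        controls = make_feature_table(X)
        ref = build_reference_network(controls)
        patient = make_feature_table(rng.normal(size=(1, 17)), ids=["P1"]).iloc[0]
        net_ratio = compute_idpn(ref, controls, patient, formula="ratio")
        net_sqrt = compute_idpn(ref, controls, patient, formula="sqrt")
        iu = np.triu_indices(17, 1)
        # z_ratio / z_sqrt = sqrt(denom) / denom = 1 / sqrt(denom)
        ratio = net_ratio.z[iu] / net_sqrt.z[iu]
        expected = 1.0 / np.sqrt((1 - ref.scc[iu] ** 2) / (ref.n - 1))
        np.testing.assert_allclose(ratio, expected, rtol=1e-10)


class TestBatch:
    def test_duplicate_ids_rejected(self, rng):
        controls = make_feature_table(rng.normal(size=(10, 17)))
        patients = controls.iloc[[2]].copy()
        with pytest.raises(ValueError, match="both sets"):
            batch_idpn(controls, patients)

    def test_empty_patients(self, rng):
        controls = make_feature_table(rng.normal(size=(10, 17)))
        patients = controls.iloc[0:0]
        assert batch_idpn(controls, patients) == []

    def test_identical_patients_identical_networks(self, rng):
        controls = make_feature_table(rng.normal(size=(15, 17)))
        row = rng.normal(size=(1, 17))
        patients = make_feature_table(np.vstack([row, row]), ids=["P1", "P2"], flags=True)
        nets = batch_idpn(controls, patients)
        np.testing.assert_array_equal(nets[0].z, nets[1].z)
        np.testing.assert_array_equal(nets[0].sig, nets[1].sig)

    def test_edge_table_shape_and_roundtrip(self, rng, tmp_path):
        controls = make_feature_table(rng.normal(size=(15, 17)))
        patients = make_feature_table(
            rng.normal(size=(3, 17)), ids=["P1", "P2", "P3"], flags=True
        )
        ref = build_reference_network(controls)
        nets = batch_idpn(controls, patients, ref=ref)
        table = idpn_edge_table(nets, ref)
        assert len(table) == 3 * 136
        path = tmp_path / "edges.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        np.testing.assert_allclose(back["z"], table["z"])


class TestOracleEquivalence:
    def test_delta_matches_brute_force(self, rng):
        """Every delta equals the difference of two independently recomputed
        pairwise Spearman coefficients, to 1e-12."""
        names = FEATURE_NAMES[:5]
        for _ in range(10):
            n = int(rng.integers(10, 51))
            Xc = rng.normal(size=(n, 5))
            controls = make_feature_table_5(Xc, names)
            ref = build_reference_network(controls, names)
            xp = rng.normal(size=5)
            patient = pd.Series(
                {"respondent_id": "P1", **dict(zip(names, xp))}
            )
            net = compute_idpn(ref, controls, patient)
            Xp = np.vstack([Xc, xp])
            for i in range(5):
                for j in range(i + 1, 5):
                    expected = brute_spearman(Xp[:, i], Xp[:, j]) - brute_spearman(
                        Xc[:, i], Xc[:, j]
                    )
                    assert net.delta[i, j] == pytest.approx(expected, abs=1e-12)


def make_feature_table_5(X, names):
    table = pd.DataFrame(X, columns=list(names))
    table.insert(0, "respondent_id", [f"R{i}" for i in range(len(X))])
    table["nssi_flag"] = False
    table["nssi_severity"] = 0
    return table
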