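import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mpalkit.cluster import (
    consensus_kmeans,
    intersect_platforms,
    joint_lineage_classify,
    pca_embedding,
    select_variable_probes,
    silhouette_widths,
)
from mpalkit.io import BetaMatrix, Probe, ProbeManifest
from tests.conftest import make_beta


def two_blob_beta(n_probes=300, n_per_group=15, delta=0.4, sd=0.05, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.2, 0.8, n_probes)
    sign = rng.choice([-1.0, 1.0], n_probes)
    g1 = np.clip(base[:, None] + sign[:, None] * delta / 2
                 + rng.normal(0, sd, (n_probes, n_per_group)), 0, 1)
    g2 = np.clip(base[:, None] - sign[:, None] * delta / 2
                 + rng.normal(0, sd, (n_probes, n_per_group)), 0, 1)
    return make_beta(np.hstack([g1, g2]))


class TestSelectVariableProbes:
    def test_constant_probe_ranked_last(self):
        vals = np.vstack([np.full(6, 0.5), [0.1, 0.9, 0.1, 0.9, 0.1, 0.9]])
        beta = make_beta(vals)
        assert select_variable_probes(beta, n=1) == ["cg00001"]

    def test_full_selection_is_identity_set(self):
        beta = two_blob_beta(n_probes=40)
        assert set(select_variable_probes(beta, n=40)) == set(beta.probe_ids)

    def test_ranking_matches_brute_force_sd(self):
        rng = np.random.default_rng(4)
        beta = make_beta(rng.uniform(0, 1, (50, 8)))
        picked = select_variable_probes(beta, n=10)
        sds = beta.values.std(axis=1, ddof=1)
        expected = sorted(sds.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
        assert picked == [k for k, _ in expected]

    def test_fraction_selection(self):
        beta = two_blob_beta(n_probes=200)
        assert len(select_variable_probes(beta, fraction=0.01)) == 2

    def test_overlong_request_warns_and_returns_all(self):
        beta = two_blob_beta(n_probes=20)
        with pytest.warns(UserWarning):
            assert len(select_variable_probes(beta, n=100)) == 20

    def test_high_missingness_probe_excluded(self):
        vals = np.full((5, 4), 0.5)
        vals[0] = [0.0, 1.0, np.nan, np.nan]  # most variable but half missing
        beta = make_beta(vals)
        assert "cg00000" not in select_variable_probes(beta, n=4)


class TestConsensusKmeans:
    def test_planted_two_groups_recovered(self):
        beta = two_blob_beta(seed=2)
        res = consensus_kmeans(beta, k_range=range(2, 5), n_resamples=150, seed=1)
        truth = [0] * 15 + [1] * 15
        assert res.chosen_k == 2
        assert adjusted_rand_score(truth, res.labels[2]) == 1.0
        cons = res.consensus_matrices[2]
        within = np.concatenate([cons[:15, :15].ravel(), cons[15:, 15:].ravel()])
        between = cons[:15, 15:].ravel()
        assert within.min() >= 0.95
        assert between.max() <= 0.05

    def test_consensus_matrix_valid(self):
        beta = two_blob_beta(n_probes=100, seed=5)
        res = consensus_kmeans(beta, k_range=range(2, 4), n_resamples=120, seed=2)
        for k, cons in res.consensus_matrices.items():
            assert np.allclose(cons, cons.T)
            assert np.allclose(np.diag(cons), 1.0)
            assert cons.min() >= 0.0 and cons.max() <= 1.0

    def test_sample_order_permutation_same_partition(self):
        beta = two_blob_beta(n_probes=120, seed=7)
        perm = np.random.default_rng(0).permutation(30)
        beta_perm = BetaMatrix(beta.values.iloc[:, perm])
        res_a = consensus_kmeans(beta, k_range=[2], n_resamples=120, seed=3)
        res_b = consensus_kmeans(beta_perm, k_range=[2], n_resamples=120, seed=3)
        la = pd.Series(res_a.labels[2], index=beta.sample_ids)
        lb = pd.Series(res_b.labels[2], index=beta_perm.sample_ids)
        assert adjusted_rand_score(la[beta.sample_ids], lb[beta.sample_ids]) == 1.0

    def test_model_selection_recovers_planted_k3(self):
        # three planted groups: cophenetic maximum should sit at k=3
        rng = np.random.default_rng(11)
        n_probes, per = 200, 10
        centers = rng.uniform(0.2, 0.8, (n_probes, 3))
        centers[:60, 0] += 0.35
        centers[60:120, 1] += 0.35
        centers[120:180, 2] += 0.35
        cols = [
            np.clip(centers[:, g][:, None] + rng.normal(0, 0.05, (n_probes, per)), 0, 1)
            for g in range(3)
        ]
        beta = make_beta(np.hstack(cols))
        res = consensus_kmeans(beta, k_range=range(2, 6), n_resamples=200, seed=9)
        assert res.chosen_k == 3
        assert adjusted_rand_score([0] * 10 + [1] * 10 + [2] * 10, res.labels[3]) == 1.0

    def test_identical_samples_fully_co_assigned(self):
        beta = make_beta(np.tile(np.linspace(0.1, 0.9, 50)[:, None], (1, 8)))
        res = consensus_kmeans(beta, k_range=[2], n_resamples=150, seed=4)
        assert np.allclose(res.consensus_matrices[2], 1.0)

    def test_too_few_resamples_rejected(self):
        beta = two_blob_beta(n_probes=50)
        with pytest.raises(ValueError, match="resamples"):
            consensus_kmeans(beta, k_range=[2], n_resamples=10, seed=0)


class TestSilhouette:
    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = rng.integers(6, 15)
            pts = rng.normal(0, 1, (n, 3))
            labels = rng.integers(0, 3, n)
            if len(np.unique(labels)) < 2:
                continue
            D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            s, _ = silhouette_widths(D, labels)
            for i in range(n):
                own = [j for j in range(n) if labels[j] == labels[i] and j != i]
                if not own:
                    assert s[i] == 0.0
                    continue
                a = np.mean([D[i, j] for j in own])
                b = min(
                    np.mean([D[i, j] for j in range(n) if labels[j] == c])
                    for c in np.unique(labels) if c != labels[i]
                )
                assert s[i] == pytest.approx((b - a) / max(a, b))

    def test_separated_blobs_high_width(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        s, per_cluster = silhouette_widths(D, [0] * 10 + [1] * 10)
        assert s.mean() > 0.9

    def test_single_cluster_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError, match="k must be"):
            silhouette_widths(D, [0, 0, 0, 0])

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            silhouette_widths(np.zeros((3, 3)), [0, 1])


class TestIntersectPlatforms:
    def _manifest(self, platforms):
        return ProbeManifest(
            [Probe(f"cg{i}", "1", i * 10, platforms=frozenset(p))
             for i, p in enumerate(platforms)]
        )

    def test_all_dual_is_identity(self):
        m = self._manifest([("EPIC", "HM450")] * 5)
        assert len(intersect_platforms(m)) == 5

    def test_disjoint_platforms_rejected(self):
        m = self._manifest([("EPIC",), ("HM450",)])
        with pytest.raises(ValueError, match="shared"):
            intersect_platforms(m)

    def test_mixed_fixture(self):
        m = self._manifest([("EPIC", "HM450")] * 6 + [("EPIC",)] * 4)
        assert len(intersect_platforms(m)) == 6


class TestJointLineageClassification:
    def _refs(self, rng, base, sig_blocks, per=10, sd=0.05):
        out = {}
        for lineage, mean in sig_blocks.items():
            cols = np.clip(mean[:, None] + rng.normal(0, sd, (len(mean), per)), 0, 1)
            out[lineage] = make_beta(cols, sample_prefix=lineage)
        return out

    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 240
        base = rng.uniform(0.3, 0.7, n)
        blocks = {}
        for i, lineage in enumerate(("AML", "B_ALL", "T_ALL")):
            m = base.copy()
            m[i * 60 : (i + 1) * 60] = 0.8
            m[[j for j in range(180) if not (i * 60 <= j < (i + 1) * 60)]] = 0.2
            blocks[lineage] = m
        return rng, base, blocks

    def test_planted_signatures_classified(self):
        rng, base, blocks = self._setup()
        refs = self._refs(rng, base, blocks)
        mpal_cols = {}
        truth = {}
        for i, lineage in enumerate(["T_ALL", "AML", "B_ALL", "T_ALL", "AML"]):
            s = f"MPAL{i:02d}"
            mpal_cols[s] = np.clip(
                blocks[lineage] + rng.normal(0, 0.05, len(base)), 0, 1
            )
            truth[s] = "AML_like" if lineage == "AML" else "ALL_like"
        mpal = BetaMatrix(
            pd.DataFrame(mpal_cols, index=refs["AML"].values.index)
        )
        res = joint_lineage_classify(mpal, refs, n_probes=240)
        for s, expected in truth.items():
            assert res.labels[s] == expected

    def test_reference_only_clusters_pure(self):
        rng, base, blocks = self._setup(seed=3)
        refs = self._refs(rng, base, blocks)
        # a single MPAL sample per lineage keeps clusters anchored
        mpal = BetaMatrix(refs["AML"].values.iloc[:, :1].rename(columns=lambda c: "M0"))
        res = joint_lineage_classify(mpal, refs, n_probes=240)
        assign = res.cluster_assignments
        for lineage in ("AML", "B_ALL", "T_ALL"):
            members = [k for k in assign.index if k.endswith(f"|{lineage}")]
            assert len(set(assign[members])) == 1

    def test_wrong_reference_keys_rejected(self):
        rng, base, blocks = self._setup()
        refs = self._refs(rng, base, blocks)
        del refs["T_ALL"]
        mpal = refs["AML"]
        with pytest.raises(ValueError, match="lineages"):
            joint_lineage_classify(mpal, refs)


def test_pca_embedding_shape_and_centering():
    beta = two_blob_beta(n_probes=80, seed=8)
    pcs = pca_embedding(beta, n_components=2)
    assert pcs.shape == (30, 2)
    assert np.allclose(pcs.mean(axis=0), 0.0, atol=1e-9)
    # two planted groups separate on PC1
    g1, g2 = pcs.iloc[:15, 0], pcs.iloc[15:, 0]
    assert (g1.max() < g2.min()) or (g2.max() < g1.min())
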