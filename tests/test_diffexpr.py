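import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import mpalkit.diffexpr as de_mod
from mpalkit.diffexpr import (
    DeRecord,
    DmpRecord,
    bh_adjust,
    call_dmps,
    differential_expression,
    mean_beta_summaries,
    moderated_t,
    ora_fisher,
    size_factors,
    starburst_integrate,
)
from mpalkit.io import Probe, ProbeManifest
from tests.conftest import make_beta


def _frame(X):
    return pd.DataFrame(
        X, index=[f"f{i}" for i in range(X.shape[0])],
        columns=[f"s{j}" for j in range(X.shape[1])],
    )


class TestModeratedT:
    def test_equal_group_means_give_zero_t(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (50, 8))
        X[0, 4:] = X[0, :4]  # feature 0: identical values per group
        res = moderated_t(_frame(X), ["A"] * 4 + ["B"] * 4)
        assert res["t"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_vanishing_prior_reduces_to_pooled_t(self, monkeypatch):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (100, 10))
        monkeypatch.setattr(de_mod, "_fit_variance_prior", lambda s2, d: (1e-12, 1.0))
        res = moderated_t(_frame(X), ["A"] * 5 + ["B"] * 5)
        ref = sps.ttest_ind(X[:, :5], X[:, 5:], axis=1, equal_var=True)
        assert np.allclose(res["t"], ref.statistic, atol=1e-6)
        assert np.allclose(res["p"], ref.pvalue, atol=1e-6)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0.5, 0.3, (5000, 12))
        res = moderated_t(_frame(X), ["A"] * 6 + ["B"] * 6)
        ks = sps.kstest(res["p"], "uniform").statistic
        assert ks < 0.03

    def test_matches_bioconductor_limma(self, tmp_path):
        """Independent cross-check of the empirical-Bayes shrinkage."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        rng = np.random.default_rng(3)
        d0_true, s02 = 6.0, 0.5
        var = d0_true * s02 / rng.chisquare(d0_true, size=200)
        X = rng.normal(0, np.sqrt(var)[:, None], size=(200, 12))
        X[:20, :6] += 1.0
        df = _frame(X)
        fixture = tmp_path / "m.tsv"
        df.to_csv(fixture, sep="\t")
        out = tmp_path / "limma.tsv"
        r = f'''
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{fixture}", row.names=1))
        design <- model.matrix(~0+factor(rep(c("A","B"), each=6)))
        colnames(design) <- c("A","B")
        fit <- eBayes(contrasts.fit(lmFit(x, design), makeContrasts(A-B, levels=design)))
        write.table(data.frame(t=fit$t, p=fit$p.value), "{out}", sep="\\t", quote=FALSE)
        '''
        subprocess.run(["Rscript", "-e", r], check=True, capture_output=True)
        lim = pd.read_csv(out, sep="\t")
        res = moderated_t(df, ["A"] * 6 + ["B"] * 6)
        assert np.allclose(res["t"], lim.iloc[:, 0], atol=1e-8)
        assert np.allclose(res["p"], lim.iloc[:, 1], atol=1e-8)

    def test_small_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="n ≥ 2"):
            moderated_t(_frame(X), ["A", "B", "B"])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        # step-up: adj_i = min over j>=i of m*p_j/j; here all collapse to 0.04
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 40)
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_bounds_and_monotonicity_against_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            adj = bh_adjust(p)
            m = len(p)
            assert ((adj >= p - 1e-12) & (adj <= np.minimum(1, m * p) + 1e-12)).all()
            # independent step-up oracle
            order = np.argsort(p)
            expected = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, m * p[i] / rank)
                expected[i] = running
            assert np.allclose(adj, expected)


class TestCallDmps:
    def _planted(self, seed=0, n_null=1500, n_signal=60, n=15, delta=0.3, sd=0.05):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.25, 0.75, n_null + n_signal)
        sign = rng.choice([-1.0, 1.0], n_null + n_signal)
        g1 = base[:, None] + rng.normal(0, sd, (len(base), n))
        g2 = base[:, None] + rng.normal(0, sd, (len(base), n))
        g1[:n_signal] += (sign[:n_signal] * delta / 2)[:, None]
        g2[:n_signal] -= (sign[:n_signal] * delta / 2)[:, None]
        beta = make_beta(np.clip(np.hstack([g1, g2]), 0, 1))
        labels = ["myeloid_B"] * n + ["myeloid_T"] * n
        return beta, labels, n_signal

    def test_planted_signal_recovered_with_fdr_control(self):
        beta, labels, n_signal = self._planted()
        dmps = call_dmps(beta, labels)
        called = {d.probe_id for d in dmps if d.is_dmp}
        planted = {f"cg{i:05d}" for i in range(n_signal)}
        assert len(called & planted) >= 0.95 * n_signal
        assert len(called - planted) <= 1

    def test_no_signal_rarely_calls_dmps(self):
        false_runs = 0
        for seed in range(10):
            beta, labels, _ = self._planted(seed=seed + 50, n_signal=0, n_null=800)
            dmps = call_dmps(beta, labels)
            false_runs += any(d.is_dmp for d in dmps)
        assert false_runs <= 1

    def test_joint_rule_is_a_strict_conjunction(self):
        beta, labels, _ = self._planted(seed=9)
        for d in call_dmps(beta, labels):
            assert d.is_dmp == (d.fdr < 0.1 and abs(d.delta_beta) > 0.15)
        # boundary cases excluded on both arms
        rec = DmpRecord("cg", 0.5, 0.3, 0.2, 3.0, 0.001, 0.1, False, "hyper_in_B")
        assert not (rec.fdr < 0.1)
        rec2 = DmpRecord("cg", 0.5, 0.35, 0.15, 3.0, 0.001, 0.01, False, "hyper_in_B")
        assert not (abs(rec2.delta_beta) > 0.15)

    def test_promoter_only_restricts_before_testing(self):
        beta, labels, _ = self._planted(seed=3, n_null=100, n_signal=10)
        probes = [
            Probe(pid, "1", i * 100, gene="G" if i < 50 else "",
                  region_class="TSS200" if i < 50 else "Body")
            for i, pid in enumerate(beta.probe_ids)
        ]
        manifest = ProbeManifest(probes)
        dmps = call_dmps(beta, labels, promoter_only=True, manifest=manifest)
        assert len(dmps) == 50

    def test_empty_promoter_set_rejected(self):
        beta, labels, _ = self._planted(seed=4, n_null=20, n_signal=0)
        manifest = ProbeManifest(
            [Probe(pid, "1", i, region_class="Body")
             for i, pid in enumerate(beta.probe_ids)]
        )
        with pytest.raises(ValueError, match="promoter"):
            call_dmps(beta, labels, promoter_only=True, manifest=manifest)


class TestMeanBetaSummaries:
    def test_constant_matrix(self):
        beta = make_beta(np.full((100, 10), 0.5))
        out = mean_beta_summaries(beta, ["A"] * 5 + ["B"] * 5, top_fraction=0.01)
        assert np.allclose(out["all_probes"], 0.5)
        assert out["all_probes_p"] == pytest.approx(1.0)

    def test_uniform_shift_propagates_exactly(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.2, 0.7, (100, 5))
        beta = make_beta(np.hstack([base, base + 0.1]))
        out = mean_beta_summaries(beta, ["A"] * 5 + ["B"] * 5)
        diff = out["all_probes"][5:].to_numpy() - out["all_probes"][:5].to_numpy()
        assert np.allclose(diff, 0.1)

    def test_top_fraction_matches_brute_force(self):
        rng = np.random.default_rng(8)
        beta = make_beta(rng.uniform(0, 1, (200, 8)))
        out = mean_beta_summaries(beta, ["A"] * 4 + ["B"] * 4, top_fraction=0.05)
        sds = beta.values.std(axis=1, ddof=1)
        top = sorted(sds.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
        expected = beta.values.loc[[k for k, _ in top]].mean(axis=0)
        assert np.allclose(out["top_variable"], expected)


class TestDifferentialExpression:
    def test_identical_columns_unit_size_factors(self):
        col = np.array([100, 200, 50, 400, 10])
        counts = _frame(np.tile(col[:, None], (1, 6)))
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_size_factor_two(self):
        rng = np.random.default_rng(9)
        col = rng.integers(10, 1000, size=300).astype(float)
        base = np.tile(col[:, None], (1, 6))
        base[:, 0] *= 2  # same library scaled 2x on every gene
        sf = size_factors(_frame(base))
        assert sf.iloc[0] == pytest.approx(2.0, rel=1e-6)
        assert np.allclose(sf.iloc[1:], 1.0)

    def test_all_zero_sample_rejected(self):
        X = np.ones((5, 4))
        X[:, 2] = 0
        with pytest.raises(ValueError, match="all-zero"):
            size_factors(_frame(X))

    def test_planted_fold_changes_recovered(self):
        rng = np.random.default_rng(10)
        n_genes, n = 500, 10
        mu = np.exp(rng.normal(np.log(400), 0.8, n_genes)).clip(20)
        lfc = np.zeros(n_genes)
        lfc[:40] = rng.choice([-1.0, 1.0], 40)  # planted 2-fold genes
        cols = []
        for j in range(2 * n):
            shift = lfc / 2 if j < n else -lfc / 2
            sf = rng.uniform(0.8, 1.3)
            cols.append(rng.poisson(mu * 2.0 ** shift * sf))
        counts = _frame(np.column_stack(cols))
        res = differential_expression(counts, ["A"] * n + ["B"] * n)
        for i in range(40):
            assert res[i].log2_fold_change == pytest.approx(lfc[i], abs=0.3)
            assert np.sign(res[i].log2_fold_change) == np.sign(lfc[i])


class TestStarburst:
    def _dmp(self, probe, delta, is_dmp=True):
        return DmpRecord(probe, 0.5 + delta / 2, 0.5 - delta / 2, delta, 4.0,
                         1e-4, 1e-3, is_dmp, "hyper_in_B" if delta > 0 else "hyper_in_T")

    def test_hyper_down_quadrant(self):
        dmps = [self._dmp("cg1", 0.3)]
        de = [DeRecord("G1", -1.5, 1e-5, 1e-4)]
        tbl = starburst_integrate(dmps, de, {"cg1": "G1"})
        assert tbl.iloc[0]["quadrant"] == "hyper+down"

    def test_nonsignificant_expression_blocks_pair(self):
        dmps = [self._dmp("cg1", 0.3)]
        de = [DeRecord("G1", -1.5, 0.5, 0.8)]
        tbl = starburst_integrate(dmps, de, {"cg1": "G1"})
        assert tbl.iloc[0]["quadrant"] == "not significant"

    def test_unmapped_probe_warns_and_skips(self):
        dmps = [self._dmp("cg1", 0.3), self._dmp("cg2", -0.2)]
        de = [DeRecord("G1", -1.5, 1e-5, 1e-4)]
        with pytest.warns(UserWarning, match="skipped"):
            tbl = starburst_integrate(dmps, de, {"cg1": "G1"})
        assert len(tbl) == 1


class TestOraFisher:
    def test_hit_set_itself_enriched(self):
        universe = {f"G{i}" for i in range(40)}
        hits = {f"G{i}" for i in range(20)}
        res = ora_fisher(hits, universe, {"set1": set(hits)})
        assert res.loc["set1", "p"] < 0.05
        assert bool(res.loc["set1", "or_unbounded"])

    def test_disjoint_set_skipped(self):
        universe = {"A", "B"}
        with pytest.warns(UserWarning, match="disjoint"):
            res = ora_fisher({"A"}, universe, {"s": {"X", "Y"}})
        assert len(res) == 0

    def test_null_pvalues_near_uniform(self):
        rng = np.random.default_rng(11)
        universe = {f"G{i}" for i in range(400)}
        hits = set(rng.choice(sorted(universe), 60, replace=False))
        sets = {
            f"s{k}": set(rng.choice(sorted(universe), 40, replace=False))
            for k in range(200)
        }
        res = ora_fisher(hits, universe, sets)
        # Fisher p-values are discrete, hence conservative rather than exactly
        # uniform: check type-I control at several levels
        for alpha in (0.05, 0.1, 0.25):
            assert (res["p"] <= alpha).mean() <= alpha + 0.05
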