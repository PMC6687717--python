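"""Usage, normalisation, pairing, PCA, treemap and qPCR statistics."""
import numpy as np
import pandas as pd
import pytest

from pubtcr.cdr3 import ClonotypeTable
from pubtcr.io import ValidationError
from pubtcr.stats import (
    UsageVector,
    cohort_mean_pairing,
    normalize_to_cohort,
    qpcr_ratio,
    treemap_export,
    usage_pca,
    usage_vector,
    vj_pairing_matrix,
)
from pubtcr import datasets

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_table(rng, sample_id="S", n=25):
    counts = {}
    while len(counts) < n:
        key = (
            f"TRBV{rng.integers(1, 7)}",
            f"TRBJ{rng.integers(1, 4)}",
            "".join(rng.choice(AA, size=int(rng.integers(8, 15)))),
        )
        counts[key] = int(rng.integers(1, 500))
    return ClonotypeTable.from_counts(counts, sample_id=sample_id)


def _usage_from_freqs(freqs, axis="V", total=None):
    return UsageVector(axis=axis, entries=pd.Series(freqs), total_reads=total)


class TestUsageVector:
    def test_single_gene(self):
        t = ClonotypeTable.from_counts(
            {("TRBV12-4", "TRBJ2-2", "ASSLAGELF"): 7,
             ("TRBV12-4", "TRBJ2-7", "ASSLAGEYY"): 3},
            sample_id="S",
        )
        u = usage_vector(t, "V")
        assert u.entries.to_dict() == {"TRBV12-4": 1.0}

    def test_70_30_split(self):
        t = ClonotypeTable.from_counts(
            {("TRBV12-4", "TRBJ1", "AAAA"): 70, ("TRBV27", "TRBJ1", "CCCC"): 30},
            sample_id="S",
        )
        u = usage_vector(t, "V").entries
        assert u["TRBV12-4"] == 0.7 and u["TRBV27"] == 0.3

    def test_simulated_cohort_recovers_target_mean(self):
        from pubtcr.simulate import study_cohort

        cs = study_cohort(seed=21, depth=20_000, n_background=800)
        vals = np.array([
            usage_vector(t, "V").entries.get("TRBV12-4", 0.0)
            for t in cs.tables("case")
        ])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - datasets.TRBV12_4_BLISTER_MEAN) <= 3 * se


class TestNormalizeToCohort:
    def test_identity_against_own_cohort(self):
        u = _usage_from_freqs({"TRBV1": 0.4, "TRBV2": 0.6})
        fc = normalize_to_cohort(u, [u, u, u], pseudocount=0.001)
        assert np.allclose(fc.entries, 1.0)

    def test_hundredfold_change(self):
        sample = _usage_from_freqs({"TRBV1": 0.10, "TRBV2": 0.90})
        ctrl = _usage_from_freqs({"TRBV1": 0.001, "TRBV2": 0.999})
        fc = normalize_to_cohort(sample, [ctrl], pseudocount=0.0)
        assert fc.entries["TRBV1"] == pytest.approx(100.0)

    def test_matches_elementwise_division_oracle(self, rng):
        genes = [f"TRBV{i}" for i in range(8)]
        def rand_usage():
            x = rng.dirichlet(np.ones(len(genes)))
            return _usage_from_freqs(dict(zip(genes, x)))
        sample = rand_usage()
        controls = [rand_usage() for _ in range(5)]
        pc = 1e-4
        fc = normalize_to_cohort(sample, controls, pseudocount=pc)
        mean = np.mean([c.entries[genes].to_numpy() for c in controls], axis=0)
        expected = (sample.entries[genes].to_numpy() + pc) / (mean + pc)
        assert np.allclose(fc.entries[genes].to_numpy(), expected)

    def test_axis_mismatch_rejected(self):
        u = _usage_from_freqs({"TRBV1": 1.0}, axis="V")
        j = _usage_from_freqs({"TRBJ1": 1.0}, axis="J")
        with pytest.raises(ValidationError, match="axis"):
            normalize_to_cohort(u, [j])


class TestVJPairing:
    def test_single_clonotype_cell(self):
        t = ClonotypeTable.from_counts(
            {("TRBV12-4", "TRBJ2-2", "ASSLAGELF"): 5}, sample_id="S"
        )
        m = vj_pairing_matrix(t)
        assert m.df.loc["TRBV12-4", "TRBJ2-2"] == 1.0

    def test_planted_60_40(self):
        t = ClonotypeTable.from_counts(
            {("TRBV12-4", "TRBJ2-2", "AAAA"): 60, ("TRBV27", "TRBJ2-7", "CCCC"): 40},
            sample_id="S",
        )
        m = vj_pairing_matrix(t).df
        assert m.loc["TRBV12-4", "TRBJ2-2"] == 0.6
        assert m.loc["TRBV27", "TRBJ2-7"] == 0.4
        assert m.loc["TRBV12-4", "TRBJ2-7"] == 0.0

    def test_matches_groupby_oracle_and_marginals(self, rng):
        t = _random_table(rng)
        m = vj_pairing_matrix(t)
        oracle = (
            t.df.groupby(["v_gene", "j_gene"])["count"].sum() / t.total_reads
        )
        for (v, j), val in oracle.items():
            assert m.df.loc[v, j] == pytest.approx(val, abs=1e-15)
        assert np.allclose(
            m.row_usage(), usage_vector(t, "V").entries.reindex(m.df.index),
            atol=1e-12,
        )
        assert np.allclose(
            m.col_usage(), usage_vector(t, "J").entries.reindex(m.df.columns),
            atol=1e-12,
        )

    def test_cohort_mean(self, rng):
        t1 = ClonotypeTable.from_counts(
            {("TRBV1", "TRBJ1", "AAAA"): 20, ("TRBV2", "TRBJ2", "CCCC"): 80},
            sample_id="A",
        )
        t2 = ClonotypeTable.from_counts(
            {("TRBV1", "TRBJ1", "AAAA"): 40, ("TRBV2", "TRBJ2", "CCCC"): 60},
            sample_id="B",
        )
        mats = [vj_pairing_matrix(t1), vj_pairing_matrix(t2)]
        mean = cohort_mean_pairing(mats)
        assert mean.df.loc["TRBV1", "TRBJ1"] == pytest.approx(0.3)
        assert cohort_mean_pairing([mats[0]]).df.equals(mats[0].df)
        # random collection equals the elementwise-mean oracle
        tables = [_random_table(rng, sample_id=f"S{i}") for i in range(7)]
        ms = [vj_pairing_matrix(t) for t in tables]
        mean7 = cohort_mean_pairing(ms)
        aligned = [
            m.df.reindex(index=mean7.df.index, columns=mean7.df.columns,
                         fill_value=0.0).to_numpy()
            for m in ms
        ]
        assert np.allclose(mean7.df.to_numpy(), np.mean(aligned, axis=0))


class TestUsagePca:
    def test_identical_samples_zero_variance(self):
        u = _usage_from_freqs({"TRBV1": 0.5, "TRBV2": 0.5})
        res = usage_pca({"A": u, "B": u}, k=1)
        assert res.explained_variance[0] == 0.0
        assert np.allclose(res.scores.loc["A"], res.scores.loc["B"])

    def test_single_gene_variation_concentrates_loading(self):
        # one gene varies; the compensation is spread thinly over 50 others
        others = [f"TRBV-bg-{i}" for i in range(50)]
        usages = {}
        for i, f in enumerate([0.1, 0.3, 0.5]):
            entries = {"TRBV12-4": f}
            entries.update({g: (1 - f) / len(others) for g in others})
            usages[f"S{i}"] = _usage_from_freqs(entries)
        res = usage_pca(usages, k=1)
        assert abs(res.loadings.loc["TRBV12-4", "PC1"]) >= 0.99
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self, rng):
        genes = [f"TRBV{i}" for i in range(4)]
        usages = {
            f"S{i}": _usage_from_freqs(
                dict(zip(genes, rng.dirichlet(np.ones(4))))
            )
            for i in range(6)
        }
        res = usage_pca(usages, k=4)
        X = np.vstack([usages[s].entries[res.loadings.index].to_numpy()
                       for s in res.scores.index])
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + X.mean(0)
        assert np.allclose(recon, X, atol=1e-8)
        # loadings orthonormal
        G = res.loadings.to_numpy().T @ res.loadings.to_numpy()
        assert np.allclose(G, np.eye(4), atol=1e-6)

    def test_sample_order_invariance_up_to_sign(self, rng):
        genes = [f"TRBV{i}" for i in range(5)]
        usages = {
            f"S{i}": _usage_from_freqs(dict(zip(genes, rng.dirichlet(np.ones(5)))))
            for i in range(5)
        }
        a = usage_pca(usages, k=2)
        b = usage_pca(dict(reversed(list(usages.items()))), k=2)
        for pc in ("PC1", "PC2"):
            x = a.scores[pc].sort_index().to_numpy()
            y = b.scores[pc].sort_index().to_numpy()
            assert np.allclose(x, y, atol=1e-8) or np.allclose(x, -y, atol=1e-8)

    def test_k_too_large_rejected(self):
        u1 = _usage_from_freqs({"TRBV1": 0.2, "TRBV2": 0.8})
        u2 = _usage_from_freqs({"TRBV1": 0.6, "TRBV2": 0.4})
        with pytest.raises(ValidationError, match="k must"):
            usage_pca({"A": u1, "B": u2}, k=2)


class TestTreemap:
    def test_top_n_plus_other(self):
        t = ClonotypeTable.from_counts(
            {("V1", "J1", "AAAA"): 50, ("V2", "J1", "CCCC"): 30,
             ("V3", "J1", "DDDD"): 20},
            sample_id="S",
        )
        entries = treemap_export(t, top_n=2)
        assert len(entries) == 3 and entries[-1].label == "other"
        assert entries[-1].frequency == pytest.approx(0.2)

    def test_reported_case4_top_entry(self):
        entries = treemap_export(datasets.blister_case_table(4), top_n=5)
        top_named = [e for e in entries if e.label.startswith("ASSLAGELF")]
        assert top_named and top_named[0].area == pytest.approx(
            31148 / 72692, abs=1e-12
        )

    def test_weights_sum_to_one(self, rng):
        t = _random_table(rng)
        entries = treemap_export(t, top_n=7)
        assert sum(e.area for e in entries) == pytest.approx(1.0, abs=1e-9)


class TestQpcrRatio:
    def test_closed_form_and_floor(self):
        assert qpcr_ratio(25.0, 25.0).ratio == 1.0
        m = qpcr_ratio(35.0, 25.0)
        assert m.ratio == pytest.approx(2 ** -10) and not m.floored
        low = qpcr_ratio(40.0, 25.0)
        assert low.floored and low.ratio == 0.0001
        nd = qpcr_ratio(None, 25.0)
        assert nd.floored and nd.ratio == 0.0001

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError, match="reference"):
            qpcr_ratio(25.0, float("nan"))
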