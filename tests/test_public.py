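"""Public-clonotype detection, overlap, clustering and group contrasts."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pubtcr.cdr3 import ClonotypeTable
from pubtcr.io import SampleMeta, ValidationError
from pubtcr.public import (
    cdr3_cluster,
    clonotype_group_contrast,
    contrast_frequencies,
    detect_public,
    pairwise_overlap,
)
from pubtcr import datasets

AA = list("ACDEFGHIKLMNPQRSTVWY")
PUBLIC = datasets.PUBLIC_BETA_KEY


def _table(counts, sample_id="S", meta=None):
    return ClonotypeTable.from_counts(counts, sample_id=sample_id, meta=meta)


def _random_table(rng, sample_id, n=20, shared=()):
    counts = {k: int(rng.integers(1, 50)) for k in shared}
    while len(counts) < n:
        key = (
            f"TRBV{rng.integers(1, 9)}",
            f"TRBJ{rng.integers(1, 5)}",
            "".join(rng.choice(AA, size=int(rng.integers(8, 14)))),
        )
        counts.setdefault(key, int(rng.integers(1, 50)))
    return _table(counts, sample_id)


class TestPairwiseOverlap:
    def test_disjoint_and_identical(self):
        a = _table({("V1", "J1", "AAAA"): 1, ("V2", "J1", "CCCC"): 1}, "A")
        b = _table({("V3", "J2", "DDDD"): 1}, "B")
        m = pairwise_overlap([a, b]).df
        assert m.loc["A", "B"] == 0
        counts = {(f"V{i}", "J1", aa * 4): 1
                  for i, aa in enumerate("ACDEF")}
        c = _table(counts, "C")
        d = _table(counts, "D")
        m2 = pairwise_overlap([c, d]).df
        assert m2.loc["C", "D"] == 5 and m2.loc["C", "C"] == 5

    def test_matches_set_intersection_oracle(self, rng):
        shared = [("TRBV1", "TRBJ1", "ASSLAGELF")]
        tables = [
            _random_table(rng, f"S{i}", shared=shared if i % 2 == 0 else ())
            for i in range(5)
        ]
        m = pairwise_overlap(tables).df
        for a, b in itertools.combinations(tables, 2):
            expect = len(a.keys() & b.keys())
            assert m.loc[a.sample_id, b.sample_id] == expect
            assert m.loc[b.sample_id, a.sample_id] == expect

    def test_permutation_equivariance(self, rng):
        tables = [_random_table(rng, f"S{i}") for i in range(4)]
        m1 = pairwise_overlap(tables).df
        m2 = pairwise_overlap(tables[::-1]).df
        assert m1.loc["S0", "S3"] == m2.loc["S0", "S3"]
        assert (m1.sort_index().sort_index(axis=1)
                == m2.sort_index().sort_index(axis=1)).all().all()


def _control_tables():
    return [
        _table({("TRBV5", "TRBJ1", "ASSQQQTDTQY"): 500,
                ("TRBV6", "TRBJ2", "ASSHHHNEQFF"): 500}, f"C{i}")
        for i in range(3)
    ]


class TestDetectPublic:
    def test_reported_cases_flag_only_the_shared_clonotype(self):
        reports = detect_public(datasets.blister_case_tables(),
                                _control_tables())
        assert len(reports) == 1
        assert reports[0].key == PUBLIC
        assert reports[0].n_case_present == 7
        assert reports[0].is_public
        assert ("CBZ", "TEN") in reports[0].specificity_labels

    def test_control_presence_excludes(self):
        cases = datasets.blister_case_tables()
        ctrl = _table({PUBLIC: 2, ("TRBV5", "TRBJ1", "ASSQQQTDTQY"): 98}, "C0")
        reports = detect_public(cases, [ctrl])  # control freq 0.02
        assert reports == []

    def test_simulated_spike_recovered_among_background(self, rng):
        from pubtcr.simulate import SimulationConfig, SpikeIn, simulate_repertoire
        from pubtcr.simulate import simulate_germline
        from pubtcr.io import CohortDesign

        gl = simulate_germline(2, 6, 3)
        spike = SpikeIn(*PUBLIC, frequencies={"case": 0.05})
        cfg = SimulationConfig(seed=9, n_background_clonotypes=1000,
                               depth=20_000, spike_ins=(spike,))
        def mk(sid, cohort, idx):
            meta = SampleMeta(sample_id=sid, cohort=cohort, tissue="PBMC")
            return simulate_repertoire(
                cfg, meta, gl, emit_reads=False, sample_index=idx
            ).to_table()
        cases = [mk(f"BC{i}", "case", i) for i in range(4)]
        controls = [mk(f"H{i}", "healthy", 10 + i) for i in range(4)]
        reports = detect_public(cases, controls)
        assert [r.key for r in reports] == [PUBLIC]

    def test_threshold_validation(self):
        with pytest.raises(ValidationError):
            detect_public(datasets.blister_case_tables(), _control_tables(),
                          min_case_freq=1.5)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        freq_lo=st.floats(0.001, 0.05),
        freq_hi=st.floats(0.05, 0.3),
        ctrl_lo=st.floats(1e-7, 1e-5),
        ctrl_hi=st.floats(1e-5, 1e-3),
        data=st.data(),
    )
    def test_monotone_in_thresholds(self, freq_lo, freq_hi, ctrl_lo, ctrl_hi,
                                    data):
        """Raising max_control_freq never removes a flag; raising
        min_case_freq never adds one."""
        seed = data.draw(st.integers(0, 1000))
        rng = np.random.default_rng(seed)
        shared = [("TRBV1", "TRBJ1", "ASSLAGELF")]
        cases = [_random_table(rng, f"BC{i}", shared=shared) for i in range(3)]
        controls = [_random_table(rng, f"H{i}") for i in range(3)]

        def keys(min_freq, max_ctrl):
            return {
                r.key
                for r in detect_public(
                    cases, controls, min_case_fraction=1.0,
                    min_case_freq=min_freq, max_control_freq=max_ctrl,
                )
            }

        assert keys(freq_lo, ctrl_lo) <= keys(freq_lo, ctrl_hi)
        assert keys(freq_hi, ctrl_hi) <= keys(freq_lo, ctrl_hi)

    def test_spike_in_recovery_across_20_cohorts(self):
        """The spiked clonotype is flagged in every seeded cohort and no
        background clonotype is flagged in more than one."""
        from pubtcr.simulate import (
            SimulationConfig, SpikeIn, simulate_germline, simulate_repertoire,
        )

        gl = simulate_germline(4, 8, 4)
        spike = SpikeIn(*PUBLIC, frequencies={"case": 0.05})
        background_flags = {}
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                seed=1000 + seed, n_background_clonotypes=800,
                depth=10_000, spike_ins=(spike,),
            )
            def mk(sid, cohort, idx):
                meta = SampleMeta(sample_id=sid, cohort=cohort, tissue="PBMC")
                return simulate_repertoire(
                    cfg, meta, gl, emit_reads=False, sample_index=idx
                ).to_table()
            cases = [mk(f"BC{i}", "case", i) for i in range(7)]
            controls = [mk(f"H{i}", "healthy", 100 + i) for i in range(8)]
            flagged = {r.key for r in detect_public(cases, controls)}
            if PUBLIC in flagged:
                hits += 1
            for k in flagged - {PUBLIC}:
                background_flags[k] = background_flags.get(k, 0) + 1
        assert hits == 20
        assert all(v <= 1 for v in background_flags.values())


class TestCdr3Cluster:
    def test_reported_cluster_members(self):
        t = _table({
            ("TRBV12-4", "TRBJ2-2", "ASSLAGELF"): 40,
            ("TRBV12-4", "TRBJ2-2", "ASSLSGELF"): 10,
            ("TRBV12-4", "TRBJ2-2", "ASSFAGELF"): 5,
            ("TRBV6-1", "TRBJ2-7", "ASSYNPGTGTEEYEQY"): 45,
        })
        cl = cdr3_cluster("ASSLAGELF", t)
        assert set(cl.members["cdr3_aa"]) == {
            "ASSLAGELF", "ASSLSGELF", "ASSFAGELF"
        }
        assert cl.cluster_frequency == pytest.approx(0.55)
        assert cl.cluster_frequency >= t.frequency_of(
            ("TRBV12-4", "TRBJ2-2", "ASSLAGELF")
        )

    def test_seed_only(self):
        t = _table({("TRBV1", "TRBJ1", "ASSLAGELF"): 3})
        cl = cdr3_cluster("ASSLAGELF", t)
        assert len(cl.members) == 1
        assert cl.members["distance"].iloc[0] == 0

    def test_matches_brute_force_hamming_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            cdr3s = list({
                "".join(rng.choice(list("AST"), size=int(rng.integers(8, 11))))
                for _ in range(n)
            })
            counts = {("TRBV1", "TRBJ1", c): int(rng.integers(1, 9))
                      for c in cdr3s}
            t = _table(counts)
            seed = cdr3s[int(rng.integers(0, len(cdr3s)))]
            got = set(cdr3_cluster(seed, t).members["cdr3_aa"])
            oracle = {
                c for c in cdr3s
                if len(c) == len(seed)
                and sum(a != b for a, b in zip(c, seed)) <= 1
            }
            assert got == oracle


class TestGroupContrast:
    def test_identical_constant_groups(self):
        gc = contrast_frequencies({"A": [0.1, 0.1, 0.1], "B": [0.1, 0.1]})
        assert gc.pvalues[("A", "B")] == (0.0, 1.0)

    def test_reported_group_means(self):
        case_tables = [
            _table({PUBLIC: 131, ("TRBV5", "TRBJ1", "ASSQQQTDTQY"): 9869},
                   f"P{i}")
            for i in range(11)
        ]
        tol_tables = [
            _table({("TRBV5", "TRBJ1", "ASSQQQTDTQY"): 10_000}, f"T{i}")
            for i in range(12)
        ]
        gc = clonotype_group_contrast(
            PUBLIC, {"case_pbmc": case_tables, "tolerant": tol_tables}
        )
        n, mean, _se = gc.groups["case_pbmc"]
        assert (n, mean) == (11, pytest.approx(0.0131))
        assert gc.groups["tolerant"][1] == 0.0

    def test_singleton_group_skipped(self):
        gc = contrast_frequencies({"A": [0.2], "B": [0.1, 0.3, 0.2]})
        assert gc.groups["A"][2] is None
        assert gc.pvalues[("A", "B")] is None

    def test_type_one_error_calibration(self):
        """Null rejections at the 0.05 level occur in ~5% of replicates."""
        rng = np.random.default_rng(12345)
        n_reps, n_per_group = 1000, 8
        rejections = 0
        for _ in range(n_reps):
            a = rng.normal(0.01, 0.003, size=n_per_group)
            b = rng.normal(0.01, 0.003, size=n_per_group)
            gc = contrast_frequencies({"A": a, "B": b})
            _t, p = gc.pvalues[("A", "B")]
            rejections += p < 0.05
        rate = rejections / n_reps
        assert 0.035 <= rate <= 0.065
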