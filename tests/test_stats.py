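"""Exact/rank tests against brute-force oracles; randomization laws."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from tmdslip.stats import (
    ContingencyTable2x2,
    NullEnsembleConfig,
    TestResult as StatsTestResult,
    Upf1Record,
    _random_starts,
    chi2_association,
    fisher_exact,
    mann_whitney_u,
    nmd_association,
    positional_null_test,
    randomize_tmd_positions,
    sample_random_heptamer_sets,
    term_enrichment,
    transcript_geometry,
)


def enumerate_mwu_p(x, y):
    """Two-sided exact p by full enumeration of rank assignments."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1, n = len(x), len(x) + len(y)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(1, n + 1), n1):
        us.append(sum(comb) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    mean = n1 * (n - n1) / 2
    dev = abs(u_obs - mean)
    return float(np.mean(np.abs(us - mean) >= dev - 1e-9))


def enumerate_fisher_p(a, b, c, d):
    """Two-sided point-probability rule by hypergeometric enumeration."""
    n, K, N = a + b + c + d, a + b, a + c
    lo, hi = max(0, K + N - n), min(K, N)
    probs = {k: hypergeom.pmf(k, n, K, N) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


class TestMannWhitney:
    def test_separated_samples_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0)

    def test_all_values_tied(self):
        res = mann_whitney_u([0.0] * 5, [0.0] * 7)
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            vals = rng.permutation(20)[: n1 + n2]
            x, y = vals[:n1].tolist(), vals[n1:].tolist()
            assert mann_whitney_u(x, y).p_value == pytest.approx(
                enumerate_mwu_p(x, y)
            )

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(1000):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            if mann_whitney_u(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07


class TestFisher:
    def test_balanced_table(self):
        res = fisher_exact(ContingencyTable2x2(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_table(self):
        res = fisher_exact(ContingencyTable2x2(5, 0, 0, 5))
        assert res.p_value == pytest.approx(2 / 252)
        assert math.isinf(res.odds_ratio)

    def test_degenerate_margin(self):
        res = fisher_exact(ContingencyTable2x2(0, 0, 3, 5))
        assert res.p_value == 1.0 and res.odds_ratio is None

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            a, b, c, d = (int(v) for v in rng.integers(0, 8, size=4))
            if a + b + c + d == 0 or (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            res = fisher_exact(ContingencyTable2x2(a, b, c, d))
            assert res.p_value == pytest.approx(
                enumerate_fisher_p(a, b, c, d), abs=1e-12
            )


class TestChi2:
    def test_proportional_table_is_null(self):
        res = chi2_association(ContingencyTable2x2(10, 20, 30, 60))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_formula(self):
        a, b, c, d = 20, 10, 10, 20
        n = a + b + c + d
        expected_stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = chi2_association(ContingencyTable2x2(a, b, c, d))
        assert res.statistic == pytest.approx(expected_stat)
        assert res.odds_ratio == pytest.approx((a * d) / (b * c))

    def test_zero_expected_count_redirects_to_fisher(self):
        with pytest.raises(ValueError, match="fisher"):
            chi2_association(ContingencyTable2x2(0, 0, 3, 5))


class TestRandomizeTmds:
    def test_deterministic_under_seed(self):
        spec = {"t1": (300, [19]), "t2": (400, [19, 21])}
        assert randomize_tmd_positions(spec, 7) == randomize_tmd_positions(spec, 7)
        assert randomize_tmd_positions(spec, 7) != randomize_tmd_positions(spec, 8)

    def test_counts_lengths_bounds_and_overlap(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            plen = int(rng.integers(60, 400))
            k = int(rng.integers(1, 4))
            lengths = [int(rng.integers(16, 26)) for _ in range(k)]
            if sum(lengths) > plen:
                continue
            (spans,) = randomize_tmd_positions({"t": (plen, lengths)}, rng).values()
            assert [b - a + 1 for a, b in spans] == lengths
            assert all(1 <= a <= b <= plen for a, b in spans)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert b1 < a2

    def test_single_segment_start_uniform(self):
        rng = np.random.default_rng(11)
        starts = [_random_starts(100, [19], rng)[0] for _ in range(10000)]
        counts = np.bincount(starts, minlength=83)[1:]
        assert counts.size == 82 and counts.sum() == 10000
        from scipy.stats import chisquare

        stat, p = chisquare(counts)
        assert p > 0.01

    def test_infeasible_transcript_kept_with_warning(self, caplog):
        out = randomize_tmd_positions({"t": (10, [19])}, 0)
        assert out["t"] == []
        assert any("too short" in m for m in caplog.messages)


class TestHeptamerSets:
    def test_full_space_is_unique(self):
        (s,) = sample_random_heptamer_sets(1, 16384, 0)
        assert len(s) == 16384
        with pytest.raises(ValueError):
            sample_random_heptamer_sets(2, 16384, 0)

    def test_sets_distinct_and_sized(self):
        sets = sample_random_heptamer_sets(50, 465, 3)
        assert len({frozenset(s) for s in sets}) == 50
        assert all(len(s) == 465 for s in sets)

    def test_inclusion_frequency_matches_sampling_law(self):
        sets = sample_random_heptamer_sets(2000, 465, 12)
        counts = np.zeros(16384)
        for s in sets:
            counts[list(s)] += 1
        freq = counts / 2000
        expected = 465 / 16384
        se = math.sqrt(expected * (1 - expected) / 2000)
        assert abs(freq.mean() - expected) < 1e-12  # exact by construction
        assert np.all(np.abs(freq - expected) < 6 * se)


@pytest.fixture(scope="module")
def geometries(census):
    from tmdslip import PlantedMotif, SimConfig, generate_transcriptome
    from tmdslip.cli import RunConfig, detect_tmds
    from tmdslip.stats import encode_heptamer

    cfg = SimConfig(n_genes=15, seed=5, planted_motifs=(PlantedMotif(), None))
    records, _ = generate_transcriptome(cfg, census)
    refined = detect_tmds(records, RunConfig(input_fasta="unused"))
    by = {r.transcript_id: r for r in records}
    geoms = [transcript_geometry(by[t], refined[t]) for t in sorted(refined)]
    ids = frozenset(encode_heptamer(h) for h in census.slippery)
    return geoms, ids


class TestPositionalNull:
    def test_single_iteration_is_well_formed(self, geometries):
        geoms, ids = geometries
        res = positional_null_test(geoms, ids, NullEnsembleConfig(1, 0))
        assert res.n_iterations == 1
        assert isinstance(res.mwu, StatsTestResult)
        assert set(res.counts.columns) == {"L", "observed", "null_mean"}

    def test_deterministic_under_seed(self, geometries):
        geoms, ids = geometries
        a = positional_null_test(geoms, ids, NullEnsembleConfig(20, 3))
        b = positional_null_test(geoms, ids, NullEnsembleConfig(20, 3))
        assert a.null_pooled == b.null_pooled and a.mwu == b.mwu

    def test_planted_ideal_spacing_is_detected(self, geometries):
        geoms, ids = geometries
        res = positional_null_test(geoms, ids, NullEnsembleConfig(200, 1))
        assert res.chi2_l45.odds_ratio > 1
        assert res.chi2_l45.p_value < 0.01

    def test_heptamer_set_mode_runs(self, geometries):
        geoms, ids = geometries
        res = positional_null_test(
            geoms, ids, NullEnsembleConfig(50, 2, "randomize_heptamer_sets")
        )
        assert res.chi2_l45.odds_ratio > 1


class TestNmdAssociation:
    def test_planted_shift_detected(self):
        from tmdslip import generate_upf1_table

        table = generate_upf1_table(730, 425, 0.263, 0.5, seed=0)
        res = nmd_association(table)
        assert res["mann_whitney"].p_value < 0.05
        assert res["fisher_up"].odds_ratio > 1
        assert res["fisher_down"].odds_ratio < 1

    def test_null_is_calibrated(self):
        from tmdslip import generate_upf1_table

        rejections, ors = 0, []
        for rep in range(200):
            table = generate_upf1_table(200, 200, 0.0, 0.5, seed=5000 + rep)
            res = nmd_association(table)
            ors.append(res["fisher_up"].odds_ratio)
            if res["mann_whitney"].p_value < 0.05:
                rejections += 1
        assert 0.01 <= rejections / 200 <= 0.10
        assert 0.8 <= float(np.median(ors)) <= 1.25

    def test_all_zero_fold_changes(self):
        recs = [Upf1Record(f"t{i}", 0.0, i % 2 == 0) for i in range(20)]
        res = nmd_association(recs)
        assert res["mann_whitney"].p_value == 1.0

    def test_single_class_rejected(self):
        recs = [Upf1Record(f"t{i}", 0.1, True) for i in range(5)]
        with pytest.raises(ValueError):
            nmd_association(recs)


class TestTermEnrichment:
    def make_annotation(self):
        rows = []
        for g in range(40):
            rows.append(("hitsonly", f"g{g}", 4))
        for g in range(200):
            rows.append(("everything", f"g{g}", 5))
        for g in range(150, 200):
            rows.append(("missesonly", f"g{g}", 6))
        return pd.DataFrame(rows, columns=["term", "gene", "depth"])

    def test_term_covering_exactly_the_hits_is_top(self):
        ann = self.make_annotation()
        hits = {f"g{g}" for g in range(40)}
        bg = {f"g{g}" for g in range(200)}
        df = term_enrichment(hits, bg, ann, min_genes=10, min_fold=1.4)
        assert df.iloc[0]["term"] == "hitsonly"
        assert math.isinf(df.iloc[0]["odds_ratio"])

    def test_fisher_values_match_manual_tables(self):
        ann = self.make_annotation()
        hits = {f"g{g}" for g in range(40)}
        bg = {f"g{g}" for g in range(200)}
        df = term_enrichment(hits, bg, ann, min_genes=1, min_fold=-math.inf)
        row = df[df.term == "hitsonly"].iloc[0]
        manual = fisher_exact(ContingencyTable2x2(40, 0, 0, 160))
        assert row.p == pytest.approx(manual.p_value)

    def test_min_genes_filter(self):
        ann = self.make_annotation()
        hits = {f"g{g}" for g in range(40)}
        bg = {f"g{g}" for g in range(200)}
        df = term_enrichment(hits, bg, ann, min_genes=41, min_fold=1.4)
        assert "hitsonly" not in set(df.term)

    def test_depth_filter_and_empty_annotation(self):
        ann = self.make_annotation()
        hits = {f"g{g}" for g in range(40)}
        bg = {f"g{g}" for g in range(200)}
        df = term_enrichment(hits, bg, ann, min_genes=10, min_fold=1.4, depth_range=(5, 8))
        assert "hitsonly" not in set(df.term)
        empty = term_enrichment(hits, bg, pd.DataFrame(columns=["term", "gene", "depth"]))
        assert empty.empty

    def test_hits_must_be_subset(self):
        with pytest.raises(ValueError):
            term_enrichment({"gX"}, {"gY"}, self.make_annotation())
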