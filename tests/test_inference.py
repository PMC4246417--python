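"""Multiple testing, closed testing, enrichment, QC and phenotype models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.stats import hypergeom

from pairdmr.inference import (
    bh_fdr,
    closed_testing_simes,
    epityper_qc,
    fisher_enrichment,
    phenotype_association,
    platform_concordance,
)

# the six continuous-platform validation p-values for pre-conception-window
# sibling pairs not profiled on the sequencing platform
VALIDATION_PVALUES = [0.027, 0.034, 0.016, 0.13, 0.021, 7.5e-3]

# 28 annotation-level nominal p-values from the genome-scale annotation scan
ANNOTATION_PVALUES = [
    9.1e-4, 1.9e-3, 4.4e-3, 5.8e-3, 6.5e-3, 0.012, 0.015, 0.016, 0.017,
    0.035, 0.036, 0.036, 0.078, 0.078, 0.080, 0.16, 0.20, 0.21, 0.25,
    0.26, 0.28, 0.29, 0.32, 0.32, 0.33, 0.43, 0.55, 0.63,
]


class TestBhFdr:
    def test_reproduces_published_annotation_adjustment(self):
        adj = bh_fdr(ANNOTATION_PVALUES)
        # CGI shores row: nominal 0.017 adjusts to 0.053
        assert round(float(adj[ANNOTATION_PVALUES.index(0.017)]), 3) == 0.053

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_matches_min_over_tail_definition(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            adj = bh_fdr(p)
            n = len(p)
            order = np.argsort(p)
            expected = np.empty(n)
            for rank_pos, idx in enumerate(order):
                tail = [
                    p[order[j]] * n / (j + 1) for j in range(rank_pos, n)
                ]
                expected[idx] = min(1.0, min(tail))
            np.testing.assert_allclose(adj, expected, rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_ranks(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(size=10)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


def exhaustive_closed_testing_bound(pvals, alpha):
    """Oracle: evaluate the Simes intersection test on every subset."""
    k = len(pvals)
    max_nonrejected = 0
    for size in range(1, k + 1):
        for subset in itertools.combinations(pvals, size):
            ps = np.sort(subset)
            ranks = np.arange(1, size + 1)
            rejected = np.any(size * ps / ranks <= alpha)
            if not rejected:
                max_nonrejected = max(max_nonrejected, size)
    return k - max_nonrejected


class TestClosedTesting:
    def test_validation_replication_bound(self):
        res = closed_testing_simes(VALIDATION_PVALUES, alpha=0.05)
        assert res.lower_bound == 3
        assert res.pi1_point == 6

    def test_all_ones_bound_zero(self):
        res = closed_testing_simes([1.0] * 5, alpha=0.05)
        assert res.lower_bound == 0

    def test_shortcut_equals_exhaustive_enumeration(self, rng):
        for k in (5, 8, 10):
            for _ in range(5):
                p = rng.uniform(0, 0.4, size=k)
                for alpha in (0.05, 0.5):
                    shortcut = closed_testing_simes(p, alpha=alpha)
                    bound = (shortcut.lower_bound if alpha == 0.05
                             else shortcut.pi1_point)
                    assert bound == exhaustive_closed_testing_bound(p, alpha)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bound_nondecreasing_when_p_decreases(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(size=6)
        base = closed_testing_simes(p, alpha=0.05).lower_bound
        i = int(r.integers(0, 6))
        p2 = p.copy()
        p2[i] *= r.uniform()
        assert closed_testing_simes(p2, alpha=0.05).lower_bound >= base


def fisher_p_by_enumeration(table):
    """Oracle: sum hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for a2 in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p2 = hypergeom.pmf(a2, n, col1, row1)
        if p2 <= p_obs * (1 + 1e-9):
            total += p2
    return min(total, 1.0)


class TestFisherEnrichment:
    def test_balanced_table_no_association(self):
        res = fisher_enrichment([[10, 10], [10, 10]])
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0)

    def test_p_matches_hypergeometric_enumeration(self, rng):
        tables = [[[5, 1], [2, 8]]]
        for _ in range(25):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() <= 40 and t.sum(axis=0).min() > 0 and t.sum(axis=1).min() > 0:
                tables.append(t.tolist())
        for t in tables:
            res = fisher_enrichment(t)
            assert res.p_value == pytest.approx(fisher_p_by_enumeration(t), rel=1e-9)

    def test_row_swap_inverts_odds_ratio(self):
        res = fisher_enrichment([[5, 1], [2, 8]])
        swapped = fisher_enrichment([[2, 8], [5, 1]])
        assert swapped.odds_ratio == pytest.approx(1 / res.odds_ratio, rel=1e-6)

    def test_ci_brackets_estimate(self):
        res = fisher_enrichment([[12, 3], [4, 11]])
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_zero_margin_flagged(self):
        res = fisher_enrichment([[0, 0], [3, 5]])
        assert res.degenerate and np.isnan(res.odds_ratio)


class TestPlatformConcordance:
    def _tables(self, rng, transform):
        inds = [f"s{i}" for i in range(12)]
        rrbs = pd.DataFrame(rng.uniform(20, 80, size=(4, 12)),
                            index=[f"r{i}" for i in range(4)], columns=inds)
        epi = transform(rrbs)
        return rrbs, epi

    def test_identical_measurements_all_kept(self, rng):
        rrbs, epi = self._tables(rng, lambda x: x.copy())
        out = platform_concordance(rrbs, epi)
        assert out["keep"].all()
        assert np.allclose(out["r"], 1.0)
        assert out.attrs["overall_r"] == pytest.approx(1.0)

    def test_independent_noise_dropped(self, rng):
        rrbs, _ = self._tables(rng, lambda x: x)
        epi = pd.DataFrame(rng.uniform(20, 80, size=rrbs.shape),
                           index=rrbs.index, columns=rrbs.columns)
        out = platform_concordance(rrbs, epi)
        assert (~out["keep"]).sum() >= 3  # near-zero correlations fail r>0.7

    def test_scale_and_shift_invariance(self, rng):
        rrbs, epi = self._tables(rng, lambda x: 0.5 * x + 7.0)
        out = platform_concordance(rrbs, epi)
        assert out["keep"].all()

    def test_zero_variance_region_flagged(self, rng):
        rrbs, epi = self._tables(rng, lambda x: x.copy())
        epi.iloc[0] = 50.0
        out = platform_concordance(rrbs, epi)
        assert out.iloc[0]["degenerate"]


def _triplicate_frame(cells):
    rows = []
    for (unit, sample), values in cells.items():
        for rep, v in enumerate(values):
            rows.append((unit, sample, rep, v))
    return pd.DataFrame(rows, columns=["unit_id", "sample_id", "replicate", "value"])


class TestEpityperQc:
    def test_high_sd_triplicate_dropped(self):
        df = _triplicate_frame({
            ("u1", "a"): (50.0, 51.0, 90.0),
            ("u1", "b"): (50.0, 51.0, 52.0),
        })
        clean = epityper_qc(df, min_success=0.4)
        assert np.isnan(clean.loc["u1", "a"])
        assert clean.loc["u1", "b"] == pytest.approx(51.0)

    def test_low_global_success_unit_dropped(self):
        cells = {("u1", f"s{i}"): ((50.0, 51.0, 52.0) if i < 7
                                   else (np.nan, np.nan, 50.0))
                 for i in range(10)}
        clean = epityper_qc(_triplicate_frame(cells))
        assert "u1" not in clean.index  # 70% success <= 75% rule

    def test_snp_masked_units_removed(self):
        df = _triplicate_frame({
            ("u1", "a"): (50.0, 51.0, 52.0),
            ("u2", "a"): (40.0, 41.0, 42.0),
        })
        clean = epityper_qc(df, min_success=0.4, snp_mask={"u2"})
        assert "u2" not in clean.index

    def test_matches_rule_oracle(self, rng):
        units = [f"u{j}" for j in range(6)]
        samples = [f"s{i}" for i in range(8)]
        cells = {}
        for u in units:
            for s in samples:
                vals = rng.uniform(30, 70, 3)
                fail = rng.random(3) < 0.3
                vals[fail] = np.nan
                if rng.random() < 0.1:
                    vals += np.array([0.0, 0.0, 40.0])  # occasional outlier well
                cells[(u, s)] = tuple(vals)
        clean = epityper_qc(_triplicate_frame(cells), max_sd=10, min_success=0.5)
        # independent re-application of the rules
        expected = {}
        for u in units:
            row = {}
            for s in samples:
                ok = np.array([v for v in cells[(u, s)] if np.isfinite(v)])
                if len(ok) >= 2 and np.std(ok, ddof=1) < 10:
                    row[s] = np.mean(ok)
                else:
                    row[s] = np.nan
            success = np.mean([np.isfinite(v) for v in row.values()])
            if success > 0.5:
                expected[u] = row
        assert sorted(clean.index) == sorted(expected)
        for u in expected:
            for s in samples:
                got = clean.loc[u, s]
                want = expected[u][s]
                assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)


class TestPhenotypeAssociation:
    def _setup(self, rng, n_pairs=30, slope=3.9, noise=0.05):
        ids = [f"P{p}{m}" for p in range(n_pairs) for m in "EC"]
        pairs = pd.Series({s: s[:-1] for s in ids})
        meth = pd.DataFrame(
            rng.uniform(30, 70, size=(1, len(ids))), index=["r1"], columns=ids
        )
        pheno = pd.DataFrame(index=pd.Index(ids))
        pheno["bw"] = 3.4 + (meth.loc["r1"] - meth.loc["r1"].mean()) / slope \
            + rng.normal(0, noise, len(ids))
        return meth, pheno, pairs

    def test_recovers_configured_slope(self, rng):
        meth, pheno, pairs = self._setup(rng, slope=3.9)
        out = phenotype_association(meth, pheno, pairs)
        row = out.iloc[0]
        assert row["beta"] == pytest.approx(3.9, abs=3 * row["se"])
        assert row["q"] < 0.05

    def test_null_phenotype_uniform_p(self, rng):
        ps = []
        for _ in range(40):
            meth, pheno, pairs = self._setup(rng)
            pheno["bw"] = rng.normal(size=len(pheno))
            out = phenotype_association(meth, pheno, pairs)
            ps.append(out.iloc[0]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_exposed_only_phenotype_uses_only_exposed_rows(self, rng):
        meth, pheno, pairs = self._setup(rng)
        pheno.loc[[s for s in pheno.index if s.endswith("C")], "bw"] = np.nan
        out = phenotype_association(meth, pheno, pairs)
        assert out.iloc[0]["n"] == 30

    def test_bh_across_grid(self, rng):
        meth, pheno, pairs = self._setup(rng)
        meth.loc["r2"] = rng.uniform(30, 70, meth.shape[1])
        pheno["noise1"] = rng.normal(size=len(pheno))
        out = phenotype_association(meth, pheno, pairs)
        tested = out["p"].notna()
        np.testing.assert_allclose(
            out.loc[tested, "q"], bh_fdr(out.loc[tested, "p"].to_numpy())
        )
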