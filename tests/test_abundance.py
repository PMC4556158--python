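import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

from tetrabin.abundance import (
    AbundanceConfig,
    CoverageProfile,
    abundance_weight,
    adp_combined,
    adp_single,
    depths_from_bam,
    read_depth_table,
    write_depth_table,
)
from tetrabin.tnf import ContigRecord


def tv_oracle(mu1, v1, mu2, v2):
    """Independent oracle for 0.5*int |phi1 - phi2|.

    Locates the density crossings numerically (bracketing + brentq on a fine
    grid, no closed-form crossing points) and integrates each signed piece
    exactly via CDF differences.
    """
    s1, s2 = math.sqrt(v1), math.sqrt(v2)
    lo = min(mu1 - 13 * s1, mu2 - 13 * s2)
    hi = max(mu1 + 13 * s1, mu2 + 13 * s2)

    def diff(x):
        return norm.pdf(x, mu1, s1) - norm.pdf(x, mu2, s2)

    xs = np.linspace(lo, hi, 4001)
    ys = diff(xs)
    roots = []
    for i in range(len(xs) - 1):
        if ys[i] == 0.0:
            roots.append(xs[i])
        elif ys[i] * ys[i + 1] < 0:
            roots.append(brentq(diff, xs[i], xs[i + 1]))
    pts = [-np.inf] + sorted(roots) + [np.inf]
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        piece = (norm.cdf(b, mu1, s1) - norm.cdf(a, mu1, s1)) - (
            norm.cdf(b, mu2, s2) - norm.cdf(a, mu2, s2)
        )
        total += abs(piece)
    return 0.5 * total


class TestAdpSingle:
    def test_identical_distributions(self):
        assert adp_single(5, 1, 5, 1) == 0.0

    def test_equal_variance_closed_form(self):
        assert np.isclose(adp_single(0, 1, 2, 1), 2 * norm.cdf(1) - 1, atol=1e-12)

    def test_equal_mean_different_variance(self):
        # crossing points at +/- sqrt((8/3) ln 2); oracle value ~ 0.3226
        val = adp_single(0, 1, 0, 4)
        assert np.isclose(val, tv_oracle(0, 1, 0, 4), atol=1e-9)
        assert np.isclose(val, 0.32267457, atol=1e-7)

    def test_symmetry(self):
        assert adp_single(1, 2, 3, 4) == pytest.approx(adp_single(3, 4, 1, 2), abs=1e-14)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            adp_single(float("nan"), 1, 0, 1)
        with pytest.raises(ValueError):
            adp_single(0, float("inf"), 0, 1)

    def test_zero_variance_floored(self):
        # zero variances are floored instead of breaking the crossing formula
        assert adp_single(1.0, 0.0, 1.0, 0.0) == 0.0
        assert 0 < adp_single(1.0, 0.0, 2.0, 0.0) <= 1.0

    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            mu1, mu2 = rng.uniform(0, 50, 2)
            v1, v2 = rng.uniform(0.01, 100, 2)
            assert adp_single(mu1, v1, mu2, v2) == pytest.approx(
                tv_oracle(mu1, v1, mu2, v2), abs=1e-6
            )

    def test_near_equal_variance_stress(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            mu1, mu2 = rng.uniform(0, 20, 2)
            v1 = rng.uniform(0.5, 50)
            v2 = v1 * (1 + 10 ** rng.uniform(-14, -6))
            assert adp_single(mu1, v1, mu2, v2) == pytest.approx(
                tv_oracle(mu1, v1, mu2, v2), abs=1e-6
            )

    @settings(max_examples=60, deadline=None)
    @given(
        st.floats(0, 100), st.floats(0.01, 100),
        st.floats(0, 100), st.floats(0.01, 100),
    )
    def test_unit_interval(self, mu1, v1, mu2, v2):
        assert 0.0 <= adp_single(mu1, v1, mu2, v2) <= 1.0

    def test_monotone_in_mean_gap(self):
        vals = [adp_single(0, 2, d, 3) for d in np.linspace(0, 20, 40)]
        assert np.all(np.diff(vals) >= -1e-12)


class TestAdpCombined:
    def test_constant_geometric_mean(self):
        # both samples have the same per-sample distance -> that distance
        delta = 2 * norm.ppf(0.75)  # equal-variance adp of 0.5 at sigma=1
        p1 = CoverageProfile("a", [5.0, 5.0], [1.0, 1.0])
        p2 = CoverageProfile("b", [5.0 + delta, 5.0 + delta], [1.0, 1.0])
        val, n = adp_combined(p1, p2)
        assert n == 2
        assert val == pytest.approx(0.5, abs=1e-12)

    def test_two_value_geometric_mean(self):
        d_90 = 2 * norm.ppf(0.95)   # adp 0.9
        d_10 = 2 * norm.ppf(0.55)   # adp 0.1
        p1 = CoverageProfile("a", [5.0, 5.0], [1.0, 1.0])
        p2 = CoverageProfile("b", [5.0 + d_90, 5.0 + d_10], [1.0, 1.0])
        val, n = adp_combined(p1, p2)
        assert n == 2
        assert val == pytest.approx(math.sqrt(0.09), abs=1e-12)

    def test_matches_explicit_product(self):
        rng = np.random.default_rng(3)
        means1 = rng.uniform(2, 30, 6)
        means2 = rng.uniform(2, 30, 6)
        v1, v2 = 5 * means1, 5 * means2
        p1 = CoverageProfile("a", means1, v1)
        p2 = CoverageProfile("b", means2, v2)
        val, n = adp_combined(p1, p2)
        singles = [adp_single(means1[i], v1[i], means2[i], v2[i]) for i in range(6)]
        assert n == 6
        assert val == pytest.approx(np.prod(singles) ** (1 / 6), rel=1e-10)

    def test_no_informative_samples(self):
        p1 = CoverageProfile("a", [0.5, 0.2], [0.5, 0.2])
        p2 = CoverageProfile("b", [0.1, 0.9], [0.1, 0.9])
        val, n = adp_combined(p1, p2)
        assert n == 0
        assert math.isnan(val)

    def test_uninformative_samples_excluded(self):
        delta = 2 * norm.ppf(0.75)
        p1 = CoverageProfile("a", [5.0, 0.1], [1.0, 0.1])
        p2 = CoverageProfile("b", [5.0 + delta, 0.2], [1.0, 0.2])
        val, n = adp_combined(p1, p2)
        assert n == 1
        assert val == pytest.approx(0.5, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adp_combined(
                CoverageProfile("a", [1.0], [1.0]),
                CoverageProfile("b", [1.0, 2.0], [1.0, 2.0]),
            )

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        m1, m2 = rng.uniform(2, 20, 8), rng.uniform(2, 20, 8)
        perm = rng.permutation(8)
        a = adp_combined(CoverageProfile("a", m1, 2 * m1), CoverageProfile("b", m2, 2 * m2))
        b = adp_combined(
            CoverageProfile("a", m1[perm], 2 * m1[perm]),
            CoverageProfile("b", m2[perm], 2 * m2[perm]),
        )
        assert a == pytest.approx(b, rel=1e-12)


class TestAbundanceWeight:
    def test_ten_sample_worked_example(self):
        w = abundance_weight(10)
        assert w == pytest.approx(math.log(11) / math.log(101))
        assert round(w, 1) == 0.5  # "about 0.5"

    def test_cap_at_alpha(self):
        assert abundance_weight(100) == 0.9
        assert abundance_weight(10_000) == 0.9

    def test_single_sample(self):
        assert abundance_weight(1) == pytest.approx(math.log(2) / math.log(101))

    def test_zero_samples(self):
        assert abundance_weight(0) == 0.0

    def test_monotone(self):
        ws = [abundance_weight(n) for n in range(0, 200)]
        assert np.all(np.diff(ws) >= 0)
        assert max(ws) <= 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AbundanceConfig(weight_alpha=1.5)
        with pytest.raises(ValueError):
            AbundanceConfig(weight_m=0)
        with pytest.raises(ValueError):
            AbundanceConfig(min_cv=-1)


class TestDepthTable:
    def test_single_sample_row(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "contigName\tcontigLen\ttotalAvgDepth\ts1.bam\ts1.bam-var\n"
            "c1\t3000\t2.0\t2.0\t1.5\n"
        )
        (prof,) = read_depth_table(p)
        assert prof.contig_id == "c1"
        assert prof.means.tolist() == [2.0]
        assert prof.variances.tolist() == [1.5]

    def test_two_sample_row(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "contigName\tcontigLen\ttotalAvgDepth\ts1\ts1-var\ts2\ts2-var\n"
            "c1\t3000\t2.0\t2.0\t1.5\t4.0\t8.0\n"
        )
        (prof,) = read_depth_table(p)
        assert prof.n_samples == 2
        assert prof.means.tolist() == [2.0, 4.0]
        assert prof.variances.tolist() == [1.5, 8.0]

    def test_odd_sample_columns_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("contigName\tcontigLen\ttotalAvgDepth\ts1\n" "c1\t3000\t2.0\t2.0\n")
        with pytest.raises(ValueError, match="pairs"):
            read_depth_table(p)

    def test_non_numeric_cell_located(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "contigName\tcontigLen\ttotalAvgDepth\ts1\ts1-var\n"
            "c1\t3000\t2.0\toops\t1.5\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_depth_table(p)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("name\tlen\tavg\n")
        with pytest.raises(ValueError):
            read_depth_table(p)

    def test_write_read_roundtrip(self, tmp_path):
        profiles = [
            CoverageProfile("c1", [2.0, 4.0], [3.0, 9.0]),
            CoverageProfile("c2", [1.5, 0.5], [2.25, 0.75]),
        ]
        path = tmp_path / "d.tsv"
        write_depth_table(path, profiles, {"c1": 3000, "c2": 2500})
        back = read_depth_table(path)
        assert [p.contig_id for p in back] == ["c1", "c2"]
        assert np.allclose(back[0].means, [2.0, 4.0])
        assert np.allclose(back[1].variances, [2.25, 0.75])


def _make_bam(tmp_path, name, sam_body):
    import pysam

    header = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:c1\tLN:10\n@SQ\tSN:c2\tLN:10\n"
    sam = tmp_path / f"{name}.sam"
    sam.write_text(header + sam_body)
    bam = tmp_path / f"{name}.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return bam


class TestDepthsFromBam:
    contigs = [ContigRecord("c1", "A" * 10), ContigRecord("c2", "A" * 10)]

    def test_uniform_full_coverage(self, tmp_path):
        bam = _make_bam(
            tmp_path, "s1", "r1\t0\tc1\t1\t60\t10M\t*\t0\t0\t" + "A" * 10 + "\t*\n"
        )
        prof = depths_from_bam([bam], self.contigs)
        assert prof[0].means[0] == 1.0
        assert prof[0].variances[0] == 0.0

    def test_half_coverage_population_variance(self, tmp_path):
        bam = _make_bam(
            tmp_path, "s1", "r1\t0\tc1\t1\t60\t5M\t*\t0\t0\tAAAAA\t*\n"
        )
        prof = depths_from_bam([bam], self.contigs)
        assert prof[0].means[0] == 0.5
        assert prof[0].variances[0] == 0.25

    def test_no_reads(self, tmp_path):
        bam = _make_bam(
            tmp_path, "s1", "r1\t0\tc1\t1\t60\t10M\t*\t0\t0\t" + "A" * 10 + "\t*\n"
        )
        prof = depths_from_bam([bam], self.contigs)
        assert prof[1].means[0] == 0.0
        assert prof[1].variances[0] == 0.0

    def test_secondary_and_duplicate_excluded(self, tmp_path):
        body = (
            "r1\t0\tc1\t1\t60\t10M\t*\t0\t0\t" + "A" * 10 + "\t*\n"
            "r2\t256\tc1\t1\t60\t10M\t*\t0\t0\t" + "A" * 10 + "\t*\n"  # secondary
            "r3\t1024\tc1\t1\t60\t10M\t*\t0\t0\t" + "A" * 10 + "\t*\n"  # duplicate
        )
        bam = _make_bam(tmp_path, "s1", body)
        prof = depths_from_bam([bam], self.contigs)
        assert prof[0].means[0] == 1.0

    def test_missing_contig_is_hard_error(self, tmp_path):
        bam = _make_bam(
            tmp_path, "s1", "r1\t0\tc1\t1\t60\t10M\t*\t0\t0\t" + "A" * 10 + "\t*\n"
        )
        with pytest.raises(ValueError, match="c3"):
            depths_from_bam([bam], self.contigs + [ContigRecord("c3", "A" * 10)])

    def test_multiple_samples(self, tmp_path):
        bam1 = _make_bam(
            tmp_path, "s1", "r1\t0\tc1\t1\t60\t10M\t*\t0\t0\t" + "A" * 10 + "\t*\n"
        )
        bam2 = _make_bam(
            tmp_path, "s2", "r1\t0\tc1\t1\t60\t5M\t*\t0\t0\tAAAAA\t*\n"
        )
        prof = depths_from_bam([bam1, bam2], self.contigs)
        assert prof[0].means.tolist() == [1.0, 0.5]
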