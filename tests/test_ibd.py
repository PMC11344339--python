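"""Method-of-moments IBD estimation and the windowed founder scan."""

import warnings

import numpy as np
import pytest

from foundersplice.ibd import (
    MISSING,
    FounderScan,
    GenotypePanel,
    control_curves,
    estimate_freqs,
    ibd_mom_estimate,
    read_pedmap_panel,
    read_vcf_panel,
    shared_segment_call,
    windowed_scan,
    write_vcf_panel,
)
from foundersplice.simulate import gen_cohort_fixture, write_pedmap

from _oracles import hw_pair, naive_ibd, parent_offspring_pair


def small_panel(rng, n_samples=6, n_snps=400, chrom="chr1"):
    p = np.clip(rng.beta(2, 2, n_snps), 0.05, 0.95)
    g = ((rng.random((n_samples, n_snps)) < p).astype(np.int8)
         + (rng.random((n_samples, n_snps)) < p).astype(np.int8))
    pos = np.cumsum(rng.integers(500, 2000, n_snps))
    return GenotypePanel([f"S{i}" for i in range(n_samples)],
                         np.array([chrom] * n_snps, dtype=object), pos,
                         [f"rs{i}" for i in range(n_snps)], g, freqs=p)


class TestEstimateFreqs:
    def test_simple_arithmetic(self):
        panel = GenotypePanel(["a", "b", "c"], np.array(["1"], dtype=object),
                              np.array([100]), ["s1"],
                              np.array([[0], [1], [2]], dtype=np.int8))
        f, mono = estimate_freqs(panel)
        assert f[0] == pytest.approx(0.5)
        assert not mono[0]

    def test_monomorphic_flagged(self):
        panel = GenotypePanel(["a", "b"], np.array(["1"], dtype=object),
                              np.array([100]), ["s1"],
                              np.array([[0], [0]], dtype=np.int8))
        _, mono = estimate_freqs(panel)
        assert mono[0]

    def test_missing_excluded_from_denominator(self):
        # dosages 2, 1, missing, missing over 4 samples → 3 / (2·2) = 0.75
        panel = GenotypePanel(["a", "b", "c", "d"], np.array(["1"], dtype=object),
                              np.array([100]), ["s1"],
                              np.array([[2], [1], [MISSING], [MISSING]], dtype=np.int8))
        f, mono = estimate_freqs(panel)
        assert f[0] == pytest.approx(0.75)

    def test_all_missing_flagged(self):
        panel = GenotypePanel(["a", "b"], np.array(["1"], dtype=object),
                              np.array([100]), ["s1"],
                              np.array([[MISSING], [MISSING]], dtype=np.int8))
        f, mono = estimate_freqs(panel)
        assert mono[0] and not np.isfinite(f[0])


class TestMomEstimator:
    def test_identical_vectors_give_exactly_one(self, rng):
        p = np.clip(rng.beta(2, 2, 1000), 0.05, 0.95)
        g = ((rng.random(1000) < p) + (rng.random(1000) < p)).astype(np.int8)
        est = ibd_mom_estimate(g, g.copy(), p)
        assert est.pi_hat == 1.0
        assert (est.z0, est.z1, est.z2) == (0.0, 0.0, 1.0)

    def test_unrelated_near_zero(self, rng):
        p = np.clip(rng.beta(2, 2, 5000), 0.05, 0.95)
        pis = [ibd_mom_estimate(*hw_pair(rng, p), p).pi_hat for _ in range(20)]
        assert abs(np.mean(pis)) <= 0.05

    def test_parent_offspring_near_half(self, rng):
        p = np.clip(rng.beta(2, 2, 5000), 0.05, 0.95)
        for _ in range(5):
            a, b = parent_offspring_pair(rng, p)
            assert ibd_mom_estimate(a, b, p).pi_hat == pytest.approx(0.5, abs=0.05)

    def test_symmetry_exact(self, rng):
        p = np.clip(rng.beta(2, 2, 300), 0.05, 0.95)
        a, b = hw_pair(rng, p)
        e1, e2 = ibd_mom_estimate(a, b, p), ibd_mom_estimate(b, a, p)
        assert (e1.z0, e1.z1, e1.z2, e1.pi_hat) == (e2.z0, e2.z1, e2.z2, e2.pi_hat)

    def test_matches_naive_loop_oracle(self, rng):
        """Vectorized estimator equals the per-SNP loop on small panels to 1e-9."""
        for _ in range(30):
            n = int(rng.integers(5, 51))
            p = np.clip(rng.beta(2, 2, n), 0.02, 0.98)
            a, b = hw_pair(rng, p)
            if rng.random() < 0.3:            # sprinkle missing calls
                a[rng.integers(0, n, 3)] = MISSING
            est = ibd_mom_estimate(a, b, p, min_informative=1)
            z0, z1, z2, pi = naive_ibd(a, b, p)
            if np.isnan(pi):
                assert np.isnan(est.pi_hat)
            else:
                assert est.pi_hat == pytest.approx(pi, abs=1e-9)
                assert est.z0 == pytest.approx(z0, abs=1e-9)

    def test_simplex_constraints_hold(self, rng):
        for _ in range(50):
            p = np.clip(rng.beta(0.5, 0.5, 60), 0.01, 0.99)
            a, b = hw_pair(rng, p)
            est = ibd_mom_estimate(a, b, p)
            assert 0.0 <= est.pi_hat <= 1.0
            assert est.z0 + est.z1 + est.z2 == pytest.approx(1.0, abs=1e-12)
            assert min(est.z0, est.z1, est.z2) >= 0.0

    def test_low_confidence_flag(self, rng):
        p = np.full(10, 0.5)
        a, b = hw_pair(rng, p)
        assert ibd_mom_estimate(a, b, p, min_informative=20).low_confidence

    def test_monomorphic_snps_excluded(self, rng):
        p = np.concatenate([np.full(100, 0.5), [0.0, 1.0, np.nan]])
        a = np.zeros(103, np.int8)
        b = np.zeros(103, np.int8)
        est = ibd_mom_estimate(a, b, p)
        assert est.n_snps_used == 100


class TestWindowedScan:
    def test_planted_identical_segment_recovered(self):
        """Carriers homozygous for the founder haplotype across ±200 SNPs:
        PI_HAT ≈ 1 while the window sits inside the segment, then erodes."""
        fx = gen_cohort_fixture(seed=7, n_samples=40, n_chrom=1, snps_per_chrom=3000,
                                founder={"n_carriers": 4, "segment_snps": 401,
                                         "chrom": "chr1", "copies": 2})
        tr = fx.truth["founder"]
        sc = windowed_scan(fx.panel, (tr["chrom"], tr["index_pos"]), tr["carriers"])
        h = sc.half_widths
        assert np.all(sc.mean_pihat[h <= 200] >= 0.9)
        tail = sc.mean_pihat[h >= 250]
        assert np.all(np.diff(tail) < 0)                   # strict erosion beyond

    def test_no_sharing_stays_at_baseline(self):
        fx = gen_cohort_fixture(seed=8, n_samples=40, n_chrom=2, snps_per_chrom=2500)
        panel = fx.panel
        carriers = panel.samples[:4]
        idx = panel.nearest_snp("chr1", int(panel.pos[1250]))
        sc = windowed_scan(panel, ("chr1", int(panel.pos[1250])), carriers)
        ctrl = control_curves(panel, carriers, n_intervals=30, seed=5,
                              exclude_snp=idx)
        assert np.all(sc.mean_pihat <= ctrl.mean_curve + 2.5 * ctrl.sd_curve + 0.05)

    def test_chromosome_end_truncation(self, rng):
        panel = small_panel(rng, n_snps=700)
        sc = windowed_scan(panel, ("chr1", int(panel.pos[10])), panel.samples[:3],
                           max_flank=500, step=50)
        assert sc.n_snps[-1] < 1001                        # effective window reduced
        assert np.all(np.isfinite(sc.mean_pihat))

    def test_fewer_than_two_carriers_raises(self, rng):
        panel = small_panel(rng)
        with pytest.raises(ValueError):
            windowed_scan(panel, ("chr1", int(panel.pos[100])), panel.samples[:1])

    def test_absent_chromosome_raises(self, rng):
        panel = small_panel(rng)
        with pytest.raises(KeyError):
            windowed_scan(panel, ("chr9", 1000), panel.samples[:2])


class TestControlCurves:
    def test_deterministic_under_seed(self, rng):
        panel = small_panel(rng, n_snps=2000)
        c1 = control_curves(panel, panel.samples[:3], n_intervals=10,
                            max_flank=100, step=50, seed=42)
        c2 = control_curves(panel, panel.samples[:3], n_intervals=10,
                            max_flank=100, step=50, seed=42)
        assert np.array_equal(c1.curves, c2.curves)
        assert np.array_equal(c1.interval_snps, c2.interval_snps)

    def test_zero_intervals_valid_empty(self, rng):
        panel = small_panel(rng)
        c = control_curves(panel, panel.samples[:3], n_intervals=0)
        assert c.n_intervals == 0 and c.curves.shape[0] == 0

    def test_insufficient_space_warns_and_reduces(self, rng):
        panel = small_panel(rng, n_snps=900)
        with pytest.warns(UserWarning, match="non-overlapping control intervals"):
            c = control_curves(panel, panel.samples[:3], n_intervals=50,
                               max_flank=200, step=100, seed=1)
        assert 0 < c.n_intervals < 50


class TestSegmentCall:
    def test_planted_275_snp_segment_extent(self):
        fx = gen_cohort_fixture(seed=1, n_samples=60, n_chrom=6, snps_per_chrom=15000,
                                founder={"n_carriers": 4, "segment_snps": 275,
                                         "chrom": "chr3"})
        tr = fx.truth["founder"]
        model = FounderScan(fx.panel, (tr["chrom"], tr["index_pos"]), tr["carriers"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = model.fit(n_controls=60, seed=2)
        assert res.segment.is_founder_compatible
        assert abs(res.segment.extent_snps - 275) <= 50
        # ≈ 6.25 Mb at the default array density
        assert 4.5 <= res.segment.span_mb <= 8.0

    def test_no_sharing_negative_decision(self):
        fx = gen_cohort_fixture(seed=2, n_samples=60, n_chrom=4, snps_per_chrom=4000)
        panel = fx.panel
        model = FounderScan(panel, ("chr2", int(panel.pos[6000])), panel.samples[:4])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = model.fit(n_controls=30, seed=3)
        assert res.segment.decision == "negative"

    def test_identical_twins_flagged_unbounded(self):
        fx = gen_cohort_fixture(seed=3, n_samples=30, n_chrom=2, snps_per_chrom=3000,
                                relatives=[("identical", 0, 1)])
        panel = fx.panel
        model = FounderScan(panel, ("chr1", int(panel.pos[1500])),
                            [panel.samples[0], panel.samples[1]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = model.fit(n_controls=20, seed=4)
        assert res.segment.unbounded
        assert res.segment.extent_snps == res.scan.n_snps[-1]

    def test_mismatched_grids_raise(self, rng):
        panel = small_panel(rng, n_snps=2000)
        sc = windowed_scan(panel, ("chr1", int(panel.pos[1000])), panel.samples[:3],
                           max_flank=200, step=50)
        ctrl = control_curves(panel, panel.samples[:3], n_intervals=5,
                              max_flank=200, step=100, seed=0)
        with pytest.raises(ValueError):
            shared_segment_call(sc, ctrl)


class TestMonotoneErosion:
    def test_replicate_mean_curve_non_increasing_beyond_segment(self):
        """Expected mean PI_HAT is non-increasing in h once the window exceeds
        the planted segment (averaged across replicates, not single draws)."""
        curves = []
        for seed in range(8):
            fx = gen_cohort_fixture(seed=100 + seed, n_samples=30, n_chrom=1,
                                    snps_per_chrom=2500,
                                    founder={"n_carriers": 4, "segment_snps": 275,
                                             "chrom": "chr1"})
            tr = fx.truth["founder"]
            sc = windowed_scan(fx.panel, (tr["chrom"], tr["index_pos"]),
                               tr["carriers"])
            curves.append(sc.mean_pihat)
        mean_curve = np.mean(curves, axis=0)
        beyond = mean_curve[2:]                 # h ≥ 150 > segment half-width
        assert np.all(np.diff(beyond) < 0.01)


class TestResultsObject:
    def test_summary_and_frame(self):
        fx = gen_cohort_fixture(seed=5, n_samples=30, n_chrom=2, snps_per_chrom=3000,
                                founder={"n_carriers": 3, "segment_snps": 201,
                                         "chrom": "chr1"})
        tr = fx.truth["founder"]
        model = FounderScan(fx.panel, (tr["chrom"], tr["index_pos"]), tr["carriers"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = model.fit(n_controls=10, seed=6, cohort_baseline_pairs=20)
        text = res.summary()
        assert "PI_HAT" in res.plot.__doc__ or "Founder" in text
        df = res.to_frame()
        assert {"half_width_snps", "mean_pihat", "control_mean",
                "control_sd", "cohort_mean"} <= set(df.columns)
        assert len(df) == len(res.scan.half_widths)

    def test_plot_writes_file(self, tmp_path):
        fx = gen_cohort_fixture(seed=6, n_samples=20, n_chrom=1, snps_per_chrom=2500)
        panel = fx.panel
        model = FounderScan(panel, ("chr1", int(panel.pos[1200])), panel.samples[:3])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = model.fit(n_controls=5, seed=7)
        out = tmp_path / "scan.png"
        res.plot(path=out)
        assert out.stat().st_size > 0


class TestIO:
    def test_vcf_round_trip(self, rng, tmp_path):
        panel = small_panel(rng, n_samples=4, n_snps=50)
        panel.genotypes[0, 5] = MISSING
        path = tmp_path / "panel.vcf"
        write_vcf_panel(panel, path)
        back = read_vcf_panel(path)
        assert back.samples == panel.samples
        assert np.array_equal(back.genotypes, panel.genotypes)
        assert np.array_equal(back.pos, panel.pos)

    def test_pedmap_round_trip_up_to_allele_orientation(self, rng, tmp_path):
        panel = small_panel(rng, n_samples=5, n_snps=40)
        panel.genotypes[2, 7] = MISSING
        write_pedmap(panel, tmp_path / "p")
        back = read_pedmap_panel(tmp_path / "p.ped", tmp_path / "p.map")
        assert back.samples == panel.samples
        a, b = panel.genotypes, back.genotypes
        for j in range(panel.n_snps):
            col_a, col_b = a[:, j], b[:, j]
            miss = col_a == MISSING
            assert np.array_equal(miss, col_b == MISSING)
            same = np.array_equal(col_a[~miss], col_b[~miss])
            flipped = np.array_equal(col_a[~miss], 2 - col_b[~miss])
            assert same or flipped

    def test_non_contiguous_chromosome_blocks_rejected(self):
        with pytest.raises(ValueError):
            GenotypePanel(["a"], np.array(["1", "2", "1"], dtype=object),
                          np.array([1, 2, 3]), ["x", "y", "z"],
                          np.zeros((1, 3), np.int8))
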