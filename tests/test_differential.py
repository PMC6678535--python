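import numpy as np
import pytest

from cnadiff import synthetic
from cnadiff.differential import (
    annotate_regions,
    differential_regions,
    profile_dynamics,
    scale_pair,
)
from cnadiff.normalization import compute_log2_profile
from cnadiff.probe_io import GenomeAnnotation
from cnadiff.segmentation import CbsParams, Segment

from conftest import make_profile

PARAMS = CbsParams(alpha=0.01, nperm=1000, seed=3)


class TestProfileDynamics:
    def test_quantile_arithmetic(self):
        prof = make_profile(np.arange(1.0, 101.0))
        assert profile_dynamics(prof) == pytest.approx(49.5)

    def test_constant_profile_zero(self):
        assert profile_dynamics(make_profile(np.full(10, 2.0))) == 0.0

    def test_scale_equivariance(self, rng):
        values = rng.normal(0, 1, 500)
        a = profile_dynamics(make_profile(values))
        b = profile_dynamics(make_profile(2 * values))
        assert b == pytest.approx(2 * a)


class TestScalePair:
    def test_noiseless_affine_pair_recovered_exactly(self, rng):
        base = rng.normal(0, 0.5, 1000)
        a = make_profile(base, sample_id="a")
        b = make_profile(2.0 * base + 0.1, sample_id="b")
        sa, sb, fit = scale_pair(a, b)
        assert fit.low_sample == "a" and fit.high_sample == "b"
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.1, abs=1e-9)
        assert np.allclose(sa.values, b.values)
        assert np.array_equal(sb.values, b.values)

    def test_identical_profiles_identity_fit(self, rng):
        base = rng.normal(0, 0.5, 500)
        sa, sb, fit = scale_pair(make_profile(base, sample_id="a"),
                                 make_profile(base, sample_id="b"))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_recovery(self):
        # equal probe noise on both members, as on a real paired hybridization
        r = np.random.default_rng(42)
        s = r.choice([0.0, 1.0, -1.0], p=[0.6, 0.2, 0.2], size=10_000)
        low = make_profile(s + r.normal(0, 0.2, 10_000), sample_id="low")
        high = make_profile(1.4 * s + 0.3 + r.normal(0, 0.2, 10_000), sample_id="high")
        _, _, fit = scale_pair(low, high)
        assert fit.slope == pytest.approx(1.4, abs=0.02)
        assert fit.intercept == pytest.approx(0.3, abs=0.01)

    def test_degenerate_constant_low_rejected(self, rng):
        a = make_profile(np.zeros(100), sample_id="a")
        b = make_profile(rng.normal(0, 1, 100), sample_id="b")
        with pytest.raises(ValueError, match="zero variance"):
            scale_pair(a, b)

    def test_mismatched_universes_intersected_or_rejected(self, rng):
        a = make_profile(rng.normal(0, 1, 100), sample_id="a")
        b = make_profile(rng.normal(0, 1, 100), sample_id="b")
        b.probes = b.probes.iloc[:98].reset_index(drop=True)  # 2% loss: allowed
        b.values = b.values[:98]
        sa, sb, _ = scale_pair(a, b)
        assert len(sa) == len(sb) == 98
        c = make_profile(rng.normal(0, 1, 100), sample_id="c")
        c.probes = c.probes.iloc[:80].reset_index(drop=True)  # 20% loss: rejected
        c.values = c.values[:80]
        with pytest.raises(ValueError, match="mismatched"):
            scale_pair(a, c)


class TestDifferentialRegions:
    def test_identical_profiles_yield_no_regions(self, rng):
        base = rng.normal(0, 0.2, 2000)
        res = differential_regions(make_profile(base, sample_id="t"),
                                   make_profile(base, sample_id="r"), cbs=PARAMS)
        assert res.regions == []

    def test_noiseless_acquired_gain_recovered_exactly(self, small_design):
        cna = synthetic.CnaSpec([
            synthetic.CnaRegion("chr2", 40_000_000, 80_000_000, 1.0, "resistant_only"),
        ])
        noise = synthetic.NoiseModel(probe_noise_sd=0.0, gc_bias_amplitude=0.0,
                                     dye_bias_amplitude=0.0, outlier_rate=0.0,
                                     baseline_log2_sd=0.0)
        parental, resistant, truth = synthetic.simulate_pair(small_design, cna,
                                                             noise=noise, seed=1)
        t = compute_log2_profile(resistant, require_dye_normalized=False)
        r = compute_log2_profile(parental, require_dye_normalized=False)
        res = differential_regions(t, r, cbs=PARAMS)
        assert len(res.regions) == 1
        region = res.regions[0]
        assert region.call == "gain"
        assert region.diff_l2r == pytest.approx(1.0, abs=1e-9)
        assert region.chrom == "chr2"

    def test_antisymmetry_under_swap(self, rng):
        base = rng.normal(0, 0.25, 3000)
        extra = np.zeros(3000)
        extra[1000:1150] += 1.2
        t = make_profile(base + extra, sample_id="t")
        r = make_profile(rng.normal(0, 0.25, 3000), sample_id="r")
        fwd = differential_regions(t, r, cbs=PARAMS)
        rev = differential_regions(r, t, cbs=PARAMS)
        assert np.allclose(fwd.diff_profile.values, -rev.diff_profile.values)
        assert [s.probe_index_range for s in fwd.called.segments] == \
               [s.probe_index_range for s in rev.called.segments]
        flip = {"gain": "loss", "loss": "gain", "neutral": "neutral"}
        assert [flip[c] for c in fwd.called.calls] == rev.called.calls
        assert [(re.chrom, re.start, -re.diff_l2r) for re in fwd.regions] == \
               [(re.chrom, re.start, re.diff_l2r) for re in rev.regions]

    def test_threshold_recomputed_on_difference(self, rng):
        s = np.zeros(4000)
        s[500:700] += 1.0
        s[2000:2200] -= 1.0
        t = make_profile(s + rng.normal(0, 0.4, 4000), sample_id="t")
        r = make_profile(s + rng.normal(0, 0.4, 4000), sample_id="r")
        res = differential_regions(t, r, cbs=PARAMS)
        # shared structure cancels; the difference is noise of sd 0.4*sqrt(2),
        # and the threshold must track the difference, not either input
        # (each input's own threshold would be ~0.4 * 0.2385)
        assert res.called.threshold.value == pytest.approx(0.4 * np.sqrt(2) * 0.2385,
                                                           rel=0.1)
        assert res.scaling.slope == pytest.approx(1.0, abs=0.1)

    def test_high_amplitude_acquired_gain(self):
        """A +4.7 acquired gain over ~150 probes is recovered at magnitude."""
        res, truth = _mini_pair(amp=4.7, seed=12)
        # ignore threshold-grazing noise blips; the aberration itself is huge
        gains = [r for r in res.regions if r.call == "gain" and r.diff_l2r > 0.5]
        assert len(gains) == 1
        assert 4.2 <= gains[0].diff_l2r <= 5.2


def _mini_pair(amp, seed):
    from cnadiff.calling import center_profile
    from cnadiff.normalization import normalize_probeset

    design = synthetic.generate_design(4_000, seed=seed)
    g = design.probes[design.probes.chrom == "chr1"]
    start = int(g.start.iloc[40])
    end = int(g.end.iloc[40 + 150])
    cna = synthetic.CnaSpec([synthetic.CnaRegion("chr1", start, end, amp, "resistant_only")])
    parental, resistant, truth = synthetic.simulate_pair(design, cna, seed=seed)
    profs = []
    for raw in (resistant, parental):
        p = normalize_probeset(raw)
        p, _, _ = center_profile(p)
        profs.append(p)
    return differential_regions(profs[0], profs[1],
                                cbs=CbsParams(nperm=1000, seed=seed)), truth


class TestAnnotateRegions:
    def _ann(self):
        from intervaltree import IntervalTree

        ann = GenomeAnnotation()
        genes = IntervalTree()
        genes.addi(87_133_178, 87_342_639, "ABCB1")
        genes.addi(10_000, 20_000, "OTHER")
        ann.genes["chr7"] = genes
        bands = IntervalTree()
        bands.addi(0, 50_000_000, "7p")
        bands.addi(50_000_000, 160_000_000, "7q")
        ann.cytobands["chr7"] = bands
        return ann

    def _segment(self, start, end, mean=1.0):
        return Segment("chr7", start, end, 10, mean, (0, 10))

    def test_gene_in_region(self):
        regions = annotate_regions([self._segment(86_259_619, 88_276_590)], ["gain"],
                                   self._ann())
        assert "ABCB1" in regions[0].genes
        assert "OTHER" not in regions[0].genes

    def test_region_inside_single_band(self):
        regions = annotate_regions([self._segment(60_000_000, 61_000_000)], ["gain"],
                                   self._ann())
        assert regions[0].cytobands == ("7q",)

    def test_region_spanning_band_boundary(self):
        regions = annotate_regions([self._segment(49_000_000, 51_000_000)], ["loss"],
                                   self._ann())
        assert set(regions[0].cytobands) == {"7p", "7q"}

    def test_neutral_segments_excluded_and_no_annotation_ok(self):
        regions = annotate_regions([self._segment(0, 10), self._segment(20, 30)],
                                   ["neutral", "gain"], None)
        assert len(regions) == 1
        assert regions[0].genes == ()

    def test_adjacent_same_level_segments_merged(self):
        a = Segment("chr7", 0, 1000, 10, 1.0, (0, 10))
        b = Segment("chr7", 1000, 2000, 10, 1.1, (10, 20))
        shoulder = Segment("chr7", 2000, 3000, 10, 0.2, (20, 30))
        regions = annotate_regions([a, b, shoulder], ["gain", "gain", "gain"], None)
        assert [(r.n_probes, round(r.diff_l2r, 3)) for r in regions] == [
            (20, 1.05), (10, 0.2),
        ]
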