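import io

import numpy as np
import pytest
from scipy.stats import hypergeom

from cnadiff.probe_io import GenomeAnnotation, read_annotation_bed
from cnadiff.profile_analysis import (
    cluster_profiles,
    cytoband_enrichment,
    map_genes_to_bands,
)

from conftest import make_profile


def _exact_corr_profiles(target_corr, n=400, seed=0):
    """Profiles whose *sample* correlation matrix equals target_corr exactly."""
    rng = np.random.default_rng(seed)
    k = target_corr.shape[0]
    X = rng.normal(size=(k, n))
    X -= X.mean(axis=1, keepdims=True)
    # whiten the sample covariance, then color with the target
    cov = X @ X.T / n
    L = np.linalg.cholesky(cov)
    W = np.linalg.solve(L, X)
    C = np.linalg.cholesky(target_corr)
    Y = C @ W
    return [make_profile(Y[i], sample_id=f"s{i}") for i in range(k)]


class TestClustering:
    def test_identical_pair_merges_first_at_zero_height(self, rng):
        base = rng.normal(0, 1, 300)
        profs = [
            make_profile(base, sample_id="a"),
            make_profile(base.copy(), sample_id="b"),
            make_profile(-base, sample_id="c"),
        ]
        res = cluster_profiles(profs)
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_ward_heights_match_lance_williams_hand_calculation(self):
        corr = np.array([[1.0, 0.9, 0.1],
                         [0.9, 1.0, 0.1],
                         [0.1, 0.1, 1.0]])
        res = cluster_profiles(_exact_corr_profiles(corr))
        # d(1,2)=0.1, d(1,3)=d(2,3)=0.9: merge (1,2) at 0.1, then
        # d({12},3) = sqrt((2*0.81 + 2*0.81 - 0.01) / 3)
        assert res.linkage[0, 2] == pytest.approx(0.1, abs=1e-9)
        expected = np.sqrt((2 * 0.81 + 2 * 0.81 - 0.01) / 3)
        assert res.linkage[1, 2] == pytest.approx(expected, abs=1e-9)

    def test_affine_rescaling_invariance(self, rng):
        profs = [make_profile(rng.normal(0, 1, 200), sample_id=f"s{i}") for i in range(4)]
        scaled = [make_profile(2.5 * p.values + 0.7, sample_id=p.sample_id) for p in profs]
        a = cluster_profiles(profs)
        b = cluster_profiles(scaled)
        assert np.allclose(a.linkage, b.linkage)

    def test_constant_profile_rejected_by_name(self, rng):
        profs = [make_profile(rng.normal(0, 1, 100), sample_id="ok1"),
                 make_profile(np.full(100, 0.5), sample_id="flatliner"),
                 make_profile(rng.normal(0, 1, 100), sample_id="ok2")]
        with pytest.raises(ValueError, match="flatliner"):
            cluster_profiles(profs)

    def test_fewer_than_three_profiles_rejected(self, rng):
        profs = [make_profile(rng.normal(0, 1, 50), sample_id=f"s{i}") for i in range(2)]
        with pytest.raises(ValueError):
            cluster_profiles(profs)

    def test_backgrounds_dominate_acquired_cnas(self):
        """Parental+resistant pairs from two genetic backgrounds group by
        background when background CNAs dwarf acquired ones."""
        from cnadiff.synthetic import NoiseModel, generate_design, random_cna_spec, simulate_pair
        from cnadiff.normalization import compute_log2_profile

        design = generate_design(3_000, seed=5)
        ok = 0
        for seed in range(3):
            profs, labels = [], []
            for bg in (0, 1):
                cna = random_cna_spec(design, n_shared=8, n_acquired=2,
                                      min_probes=60, max_probes=150,
                                      amplitudes=(1.0, 3.2), seed=100 * bg + seed)
                p, r, _ = simulate_pair(design, cna, seed=10 * bg + seed)
                for ps, who in ((p, "p"), (r, "r")):
                    ps.sample_id = f"bg{bg}-{who}"
                    profs.append(compute_log2_profile(ps, require_dye_normalized=False))
                    labels.append(bg)
            res = cluster_profiles(profs)
            cut = res.cut(2)
            ok += len({(l, c) for l, c in zip(labels, cut)}) == 2
        assert ok == 3

    def test_newick_round_trips_through_biopython(self, rng):
        from Bio import Phylo

        profs = [make_profile(rng.normal(0, 1, 100), sample_id=f"s{i}") for i in range(4)]
        nwk = cluster_profiles(profs).to_newick()
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["s0", "s1", "s2", "s3"]


def _band_annotation(n_bands=10, genes_per_band=5):
    lines, genes = [], []
    for b in range(n_bands):
        start = b * 1_000_000
        lines.append(f"chr1\t{start}\t{start + 1_000_000}\tband{b}")
        for g in range(genes_per_band):
            gs = start + 1000 + g * 100_000
            genes.append(f"chr1\t{gs}\t{gs + 1000}\tG{b}_{g}")
    ann = read_annotation_bed(io.StringIO("\n".join(lines)), "cytoband")
    return ann.merged_with(read_annotation_bed(io.StringIO("\n".join(genes)), "gene"))


class TestEnrichment:
    def test_closed_form_single_band(self):
        ann = _band_annotation(n_bands=10, genes_per_band=5)
        background = [f"G{b}_{g}" for b in range(10) for g in range(5)]
        query = [f"G0_{g}" for g in range(5)]
        df = cytoband_enrichment(query, background, ann)
        assert df.iloc[0]["cytoband"] == "band0"
        # k=K=5, n=5, N=50 -> p = 1 / C(50, 5)
        assert df.iloc[0]["p"] == pytest.approx(float(hypergeom.sf(4, 50, 5, 5)))
        assert df.iloc[0]["p"] == pytest.approx(1.0 / 2_118_760)

    def test_bh_adjustment_monotone_in_p_rank(self, rng):
        ann = _band_annotation(n_bands=10, genes_per_band=8)
        background = [f"G{b}_{g}" for b in range(10) for g in range(8)]
        query = list(rng.choice(background, size=20, replace=False))
        df = cytoband_enrichment(query, background, ann)
        assert (np.diff(df["p_adj"].to_numpy()) >= -1e-12).all()
        assert (df["p_adj"] >= df["p"] - 1e-12).all()

    def test_null_query_roughly_calibrated(self):
        ann = _band_annotation(n_bands=10, genes_per_band=100)
        background = [f"G{b}_{g}" for b in range(10) for g in range(100)]
        rng = np.random.default_rng(17)
        frac = []
        for _ in range(200):
            query = list(rng.choice(background, size=50, replace=False))
            df = cytoband_enrichment(query, background, ann)
            frac.append((df["p"] < 0.05).sum() / 10.0)
        assert abs(np.mean(frac) - 0.05) < 0.03

    def test_empty_query_empty_result(self):
        ann = _band_annotation()
        df = cytoband_enrichment([], [f"G{b}_{g}" for b in range(10) for g in range(5)], ann)
        assert df.empty

    def test_query_not_subset_rejected(self):
        ann = _band_annotation()
        with pytest.raises(ValueError, match="subset"):
            cytoband_enrichment(["NOT_THERE"], ["G0_0"], ann)

    def test_boundary_spanning_gene_counts_in_both_bands(self):
        bands = read_annotation_bed(
            io.StringIO("chr1\t0\t100\tp1\nchr1\t100\t200\tq1"), "cytoband")
        genes = read_annotation_bed(io.StringIO("chr1\t90\t110\tSPAN"), "gene")
        ann = bands.merged_with(genes)
        mapping = map_genes_to_bands(["SPAN"], ann)
        assert mapping["SPAN"] == {"p1", "q1"}
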