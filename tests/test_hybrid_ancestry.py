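"""SNP filtering, diagnostic loci, hybrid index and heterozygosity."""

import numpy as np
import pytest

from gorget.hybrid_ancestry import (
    FilterConfig,
    GenotypeMatrix,
    classify_hybrid,
    diagnostic_loci,
    filter_snps,
    hybrid_index,
    interspecific_heterozygosity,
    read_vcf,
)
from gorget.synthetic_data import CrossGenSpec, gen_cross, write_vcf


def toy_matrix(genotypes, depth=None, quality=None, samples=None, pops=None):
    g = np.array(genotypes, dtype=np.int8)
    L, S, _ = g.shape
    samples = samples or [f"s{i}" for i in range(S)]
    pops = pops or {}
    return GenotypeMatrix(
        genotypes=g,
        depth=np.full((L, S), 30.0) if depth is None else np.asarray(depth, float),
        quality=np.full((L, S), 99.0) if quality is None else np.asarray(quality, float),
        samples=samples,
        populations=pops or {s: "focal" for s in samples},
    )


class TestReadVCF:
    def test_round_trip_of_generated_cross(self, tmp_path):
        gm, _ = gen_cross(CrossGenSpec(n_loci=50, cross_type="F2", seed=1,
                                       missing_rate=0.1))
        path = tmp_path / "cross.vcf"
        write_vcf(gm, path)
        back = read_vcf(path, gm.populations)
        np.testing.assert_array_equal(
            np.sort(back.genotypes, axis=2), np.sort(gm.genotypes, axis=2)
        )
        assert back.samples == gm.samples

    def test_multiallelic_records_dropped(self, tmp_path):
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1",
            "1\t1\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1",
            "1\t2\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t1/2",
            "1\t3\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\t0/0",
        ]
        p = tmp_path / "multi.vcf"
        p.write_text("\n".join(lines) + "\n")
        gm = read_vcf(p, {"s0": "parent1", "s1": "parent2"})
        assert gm.n_loci == 2
        assert gm.n_multiallelic_dropped == 1

    def test_hand_written_dimensions(self, tmp_path):
        header = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc",
        ]
        body = [f"1\t{i+1}\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1" for i in range(10)]
        p = tmp_path / "ten.vcf"
        p.write_text("\n".join(header + body) + "\n")
        gm = read_vcf(p, {"a": "parent1", "b": "focal", "c": "parent2"})
        assert gm.genotypes.shape == (10, 3, 2)

    def test_unknown_sample_rejected(self, tmp_path):
        gm, _ = gen_cross(CrossGenSpec(n_loci=5, seed=0))
        p = tmp_path / "x.vcf"
        write_vcf(gm, p)
        with pytest.raises(ValueError, match="population map"):
            read_vcf(p, {"p1_0": "parent1"})


class TestFilterSNPs:
    def make(self, depth, quality):
        L = len(depth)
        g = [[[0, 0], [1, 1], [0, 1]]] * L
        return toy_matrix(
            g,
            depth=np.array(depth, float),
            quality=np.array(quality, float),
            samples=["p1", "p2", "f"],
            pops={"p1": "parent1", "p2": "parent2", "f": "focal"},
        )

    def test_depth_boundary_is_strict(self):
        gm = self.make([[5, 30, 30]], [[99, 99, 99]])
        assert filter_snps(gm).n_loci == 0  # parental depth 5 fails "> 5×"
        gm = self.make([[6, 30, 30]], [[99, 99, 99]])
        assert filter_snps(gm).n_loci == 1

    def test_quality_boundary_is_strict(self):
        gm = self.make([[30, 30, 30]], [[99, 20, 99]])
        assert filter_snps(gm).n_loci == 0
        gm = self.make([[30, 30, 30]], [[99, 21, 99]])
        assert filter_snps(gm).n_loci == 1

    def test_engineered_failures_counted(self):
        depth = [[30, 30, 30]] * 10
        quality = [[99, 99, 99]] * 10
        depth[2] = [4, 30, 30]
        quality[5] = [99, 15, 99]
        depth[8] = [30, 5, 30]
        gm = self.make(depth, quality)
        assert filter_snps(gm).n_loci == 7

    def test_focal_failure_becomes_missing_not_dropped(self):
        gm = self.make([[30, 30, 3]], [[99, 99, 99]])
        out = filter_snps(gm)
        assert out.n_loci == 1
        assert (out.genotypes[0, 2] == -1).all()


class TestDiagnosticLoci:
    def test_fixed_difference_kept(self):
        gm = toy_matrix(
            [[[0, 0], [1, 1]]],
            samples=["p1", "p2"],
            pops={"p1": "parent1", "p2": "parent2"},
        )
        assert diagnostic_loci(gm).n_loci == 1

    def test_heterozygous_parental_dropped(self):
        gm = toy_matrix(
            [[[0, 1], [1, 1]]],
            samples=["p1", "p2"],
            pops={"p1": "parent1", "p2": "parent2"},
        )
        assert diagnostic_loci(gm).n_loci == 0

    def test_matches_brute_force_scan(self, rng):
        L, n1, n2 = 60, 3, 3
        g = rng.integers(0, 2, size=(L, n1 + n2 + 1, 2)).astype(np.int8)
        samples = [f"p1_{i}" for i in range(n1)] + [f"p2_{i}" for i in range(n2)] + ["f"]
        pops = {s: ("parent1" if s.startswith("p1") else
                    "parent2" if s.startswith("p2") else "focal") for s in samples}
        gm = toy_matrix(g, samples=samples, pops=pops)
        kept = set(diagnostic_loci(gm).locus_ids)
        expected = set()
        for l in range(L):
            a1 = {tuple(g[l, i]) for i in range(n1)}
            a2 = {tuple(g[l, i]) for i in range(n1, n1 + n2)}
            if (
                len(a1) == 1 and len(a2) == 1
                and len(set(list(a1)[0])) == 1 and len(set(list(a2)[0])) == 1
                and list(a1)[0][0] != list(a2)[0][0]
            ):
                expected.add(f"locus{l}")
        assert kept == expected


class TestHybridIndex:
    def cross_estimates(self, cross_type, n_loci=200, seed=0):
        gm, truth = gen_cross(
            CrossGenSpec(n_loci=n_loci, cross_type=cross_type, seed=seed)
        )
        gm = diagnostic_loci(filter_snps(gm))
        est = hybrid_index(gm, "focal_0")
        het = interspecific_heterozygosity(gm, "focal_0")
        return est, het, truth

    def test_pure_parental(self):
        est, het, _ = self.cross_estimates("P1")
        assert (est.h, het) == (0.0, 0.0)
        assert est.ci_low == 0.0

    def test_f1_exact(self):
        est, het, _ = self.cross_estimates("F1")
        assert (est.h, het) == (0.5, 1.0)

    def test_profile_ci_matches_grid_oracle(self):
        # 25 parent2 alleles among 100: CI endpoints from a likelihood grid
        from gorget.hybrid_ancestry import _profile_likelihood_ci

        k, n = 25, 100
        lo, hi = _profile_likelihood_ci(k, n)
        p_grid = np.linspace(1e-6, 1 - 1e-6, 2_000_001)
        ll = k * np.log(p_grid) + (n - k) * np.log(1 - p_grid)
        inside = p_grid[ll >= ll.max() - 1.92]
        assert lo == pytest.approx(inside[0], abs=1e-4)
        assert hi == pytest.approx(inside[-1], abs=1e-4)
        assert est_contains(lo, hi, k / n)

    def test_bc1_recovery_over_replicates(self):
        hs, hets = [], []
        for i in range(200):
            gm, truth = gen_cross(
                CrossGenSpec(n_loci=1000, cross_type="BC1_P1", seed=i)
            )
            gm = diagnostic_loci(gm)
            est = hybrid_index(gm, "focal_0")
            hs.append(est.h)
            hets.append(est.heterozygosity)
        # Mendelian expectations: h = 0.25, het = 0.5
        se_h = np.std(hs, ddof=1) / np.sqrt(len(hs))
        se_t = np.std(hets, ddof=1) / np.sqrt(len(hets))
        assert abs(np.mean(hs) - 0.25) < 3 * se_h
        assert abs(np.mean(hets) - 0.5) < 3 * se_t

    def test_locus_order_and_ref_relabel_invariance(self):
        gm, _ = gen_cross(CrossGenSpec(n_loci=100, cross_type="F2", seed=9))
        gm = diagnostic_loci(gm)
        base = hybrid_index(gm, "focal_0")
        perm = np.random.default_rng(0).permutation(gm.n_loci)
        gm_perm = gm.subset_loci(perm)
        gm_perm.parent2_allele = gm.parent2_allele[perm]
        shuffled = hybrid_index(gm_perm, "focal_0")
        assert shuffled.h == base.h
        # flip REF/ALT labels at every locus
        gm_flip = gm.subset_loci(np.arange(gm.n_loci))
        gm_flip.genotypes = (1 - gm.genotypes).astype(np.int8)
        gm_flip.genotypes[gm.genotypes == -1] = -1
        gm_flip.parent2_allele = (1 - gm.parent2_allele).astype(np.int8)
        flipped = hybrid_index(gm_flip, "focal_0")
        assert flipped.h == base.h

    def test_parental_swap_mirrors_h(self):
        gm, _ = gen_cross(CrossGenSpec(n_loci=400, cross_type="BC1_P1", seed=3))
        gm = diagnostic_loci(gm)
        base = hybrid_index(gm, "focal_0")
        swapped_pops = {
            s: {"parent1": "parent2", "parent2": "parent1"}.get(p, p)
            for s, p in gm.populations.items()
        }
        gm_sw = gen_cross(CrossGenSpec(n_loci=400, cross_type="BC1_P1", seed=3))[0]
        gm_sw.populations = swapped_pops
        gm_sw = diagnostic_loci(gm_sw)
        swapped = hybrid_index(gm_sw, "focal_0")
        assert swapped.h == pytest.approx(1.0 - base.h)
        assert swapped.heterozygosity == base.heterozygosity


def est_contains(lo, hi, x):
    return lo <= x <= hi


class TestTriangle:
    def test_simulated_crosses_respect_triangle_constraint(self):
        for ct in ("P1", "P2", "F1", "F2", "BC1_P1", "BC2_P2", "BC3_P1"):
            for seed in range(5):
                _, truth = gen_cross(
                    CrossGenSpec(n_loci=500, cross_type=ct, seed=seed)
                )
                h, het = truth.loc[0, "h"], truth.loc[0, "het"]
                assert het <= 2 * min(h, 1 - h) + 1e-12

    def test_f1_classifies_as_f1(self):
        assert classify_hybrid(0.5, 1.0)[0] == "F1"

    def test_late_backcross_example(self):
        label, dists = classify_hybrid(0.163, 0.11)
        assert label.endswith("_P1") and label.startswith("BC")
        assert dists[label] < dists["P1"]

    def test_pure_parental_corner(self):
        assert classify_hybrid(0.0, 0.0)[0] == "P1"

    def test_outside_triangle_rejected(self):
        with pytest.raises(ValueError, match="triangle"):
            classify_hybrid(0.05, 0.9)

    def test_unknown_cross_type_rejected(self):
        with pytest.raises(ValueError, match="cross_type"):
            CrossGenSpec(cross_type="F3_P9")
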