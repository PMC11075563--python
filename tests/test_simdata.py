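"""Coalescent simulator: analytic expectations, determinism, fixture truth."""

import numpy as np
import pytest

from woodpop import simdata as sd


def harmonic(k):
    return sum(1.0 / j for j in range(1, k + 1))


def folded_eta(h, n_diploids):
    c = h.sum(axis=0)
    minor = np.minimum(c, 2 * n_diploids - c)
    minor = minor[minor > 0]
    return np.bincount(minor, minlength=n_diploids + 1)[1:n_diploids + 1]


class TestGenealogy:
    def test_pairwise_tmrca_constant(self):
        """E[T2] = 1 coalescent unit for a constant-size population."""
        rng = np.random.default_rng(1)
        t2 = []
        for _ in range(4000):
            _parent, times = sd.simulate_tree(2, sd.Constant(), rng)
            t2.append(times[-1])
        t2 = np.asarray(t2)
        se = t2.std() / np.sqrt(t2.size)
        assert abs(t2.mean() - 1.0) < 3 * se

    def test_too_few_lineages(self):
        with pytest.raises(ValueError):
            sd.simulate_tree(1, sd.Constant(), np.random.default_rng(0))

    @pytest.mark.parametrize("bad", [
        lambda: sd.ExponentialGrowth(-1.0),
        lambda: sd.TwoDeme(0.0),
        lambda: sd.TwoDeme(1.0, migration=0.5),
    ])
    def test_invalid_demography(self, bad):
        with pytest.raises(ValueError):
            bad()


class TestMutations:
    @pytest.mark.parametrize("n_diploids,theta", [(2, 1.0), (5, 2.0), (11, 10.0)])
    def test_watterson_consistency(self, n_diploids, theta):
        """Mean S per locus matches E[S] = theta * a_{2n-1} within 3 SE."""
        spec = sd.SimulationSpec(n_diploids=n_diploids, theta_per_locus=theta,
                                 n_loci=1500, seed=100 + n_diploids)
        s = np.array([sd.simulate_locus(spec, i).shape[1]
                      for i in range(spec.n_loci)], dtype=float)
        se = s.std() / np.sqrt(s.size)
        assert abs(s.mean() - theta * harmonic(2 * n_diploids - 1)) < 3 * se

    def test_pi_consistency(self):
        """Mean per-locus average pairwise difference matches theta."""
        theta = 2.0
        spec = sd.SimulationSpec(n_diploids=5, theta_per_locus=theta,
                                 n_loci=1500, seed=7)
        pis = []
        for i in range(spec.n_loci):
            h = sd.simulate_locus(spec, i)
            k = h.shape[0]
            j = h.sum(axis=0)
            pis.append(float(np.sum(2.0 * j * (k - j) / (k * (k - 1)))))
        pis = np.asarray(pis)
        se = pis.std() / np.sqrt(pis.size)
        assert abs(pis.mean() - theta) < 3 * se

    def test_theta_zero_no_sites(self):
        spec = sd.SimulationSpec(n_diploids=3, theta_per_locus=0.0, n_loci=20,
                                 seed=3)
        assert all(sd.simulate_locus(spec, i).shape == (6, 0)
                   for i in range(spec.n_loci))

    def test_seed_determinism(self):
        spec = sd.SimulationSpec(n_diploids=4, theta_per_locus=5.0, n_loci=3,
                                 seed=11)
        a = [sd.simulate_locus(spec, i) for i in range(3)]
        b = [sd.simulate_locus(spec, i) for i in range(3)]
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_growth_singleton_excess(self):
        """Expansion inflates the singleton class relative to constant size."""
        n, theta, loci = 11, 2.0, 800
        eta_c = np.zeros(n)
        eta_g = np.zeros(n)
        const = sd.SimulationSpec(n_diploids=n, theta_per_locus=theta,
                                  n_loci=loci, seed=21)
        growth = sd.SimulationSpec(n_diploids=n, theta_per_locus=theta,
                                   n_loci=loci, seed=22,
                                   demography=sd.ExponentialGrowth(20.0))
        for i in range(loci):
            eta_c += folded_eta(sd.simulate_locus(const, i), n)
            eta_g += folded_eta(sd.simulate_locus(growth, i), n)
        assert eta_g[0] / eta_g.sum() > eta_c[0] / eta_c.sum()


class TestCrossOracle:
    def test_sfs_matches_independent_simulator(self):
        """Folded SFS statistically indistinguishable from msprime (alpha=0.01)."""
        msprime = pytest.importorskip("msprime")
        from scipy.stats import chi2_contingency

        n, theta, loci = 5, 2.0, 1000
        spec = sd.SimulationSpec(n_diploids=n, theta_per_locus=theta,
                                 n_loci=loci, seed=9)
        eta_mine = np.zeros(n)
        for i in range(loci):
            eta_mine += folded_eta(sd.simulate_locus(spec, i), n)

        eta_ms = np.zeros(n)
        reps = msprime.sim_ancestry(samples=n, ploidy=2, population_size=0.5,
                                    num_replicates=loci, random_seed=5)
        rng = np.random.default_rng(6)
        for ts in reps:
            mts = msprime.sim_mutations(
                ts, rate=theta / 2.0, discrete_genome=False,
                random_seed=int(rng.integers(1, 2 ** 31)))
            xi = mts.allele_frequency_spectrum(polarised=True,
                                               span_normalise=False)[1:2 * n]
            eta_ms += np.array([xi[i - 1] + xi[2 * n - i - 1]
                                for i in range(1, n)] + [xi[n - 1]])
        _chi2, p, _dof, _ = chi2_contingency(np.array([eta_mine, eta_ms]))
        assert p > 0.01


class TestVcfOutput:
    def test_allele_counts_match_matrix(self, tmp_path):
        """Record alt-allele counts equal the haplotype column sums."""
        rng = np.random.default_rng(0)
        h = (rng.random((4, 3)) < 0.5).astype(np.int8)
        path = tmp_path / "x.vcf"
        sd.write_vcf([h], str(path), seed=1)
        body = [l for l in path.read_text().splitlines()
                if not l.startswith("#")]
        assert len(body) == 3
        counts = sorted(
            sum(int(a) for f in line.split("\t")[9:]
                for a in f.split(":")[0].split("|"))
            for line in body)
        assert counts == sorted(h.sum(axis=0).tolist())

    def test_sample_depths_sum_to_variant_depth(self, tmp_path):
        rng = np.random.default_rng(2)
        h = (rng.random((6, 4)) < 0.5).astype(np.int8)
        path = tmp_path / "x.vcf"
        sd.write_vcf([h], str(path), seed=3)
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            info_dp = int(fields[7].removeprefix("DP="))
            fmt_dp = sum(int(f.split(":")[1]) for f in fields[9:])
            assert fmt_dp == info_dp

    def test_odd_haplotypes_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="odd"):
            sd.write_vcf([np.zeros((3, 2), dtype=np.int8)],
                         str(tmp_path / "x.vcf"), seed=0)

    def test_no_sites_header_only(self, tmp_path):
        path = tmp_path / "x.vcf"
        n = sd.write_vcf([np.zeros((4, 0), dtype=np.int8)], str(path), seed=0)
        assert n == 0
        assert all(l.startswith("#") for l in path.read_text().splitlines())

    def test_positions_strictly_increasing(self, tmp_path):
        spec = sd.SimulationSpec(n_diploids=3, theta_per_locus=8.0, n_loci=4,
                                 seed=5, locus_length=200)
        path = tmp_path / "x.vcf"
        sd.write_vcf(sd.simulate_loci(spec), str(path), locus_length=200,
                     seed=5, chrom_labels={"chr1": [0, 1], "chr2": [2, 3]})
        seen: dict[str, list[int]] = {}
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                continue
            c, p = line.split("\t")[:2]
            seen.setdefault(c, []).append(int(p))
        for pos in seen.values():
            assert all(b > a for a, b in zip(pos, pos[1:]))

    def test_byte_identical_rerun(self, tmp_path):
        spec = sd.SimulationSpec(n_diploids=3, theta_per_locus=2.0, n_loci=5,
                                 seed=8)
        haps = sd.simulate_loci(spec)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        sd.write_vcf(haps, str(p1), seed=8)
        sd.write_vcf(haps, str(p2), seed=8)
        assert p1.read_bytes() == p2.read_bytes()


class TestDepthModel:
    def test_mean_without_outliers(self):
        """Empirical mean within 5% of mean_depth at 1e5 draws."""
        m = sd.DepthModel(mean_depth=22.7, outlier_fraction=0.0)
        dp = m.sample(100_000, np.random.default_rng(4))
        assert abs(dp.mean() - 22.7) / 22.7 < 0.05

    def test_outliers_create_heavy_tail(self):
        m = sd.DepthModel(mean_depth=22.7, outlier_fraction=0.02,
                          outlier_scale=6.0)
        dp = m.sample(100_000, np.random.default_rng(4))
        assert np.quantile(dp, 0.999) > 5 * np.median(dp)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            sd.DepthModel(mean_depth=0.0)
        with pytest.raises(ValueError):
            sd.DepthModel(outlier_fraction=1.0)


class TestCoords:
    def truth(self):
        return sd.RearrangementTruth({
            "scaf1": [("chr1", 1, 2_000_000, "+")],
            "scaf2": [("chr2", 1, 2_000_000, "-")],
        })

    def test_no_spurious_all_pairs_in_truth(self):
        df = sd.generate_coords(self.truth(), spurious_rate=0.0, seed=1)
        pairs = set(zip(df["query_chrom"], df["ref_chrom"]))
        assert pairs == {("scaf1", "chr1"), ("scaf2", "chr2")}

    def test_deterministic_bytes(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        sd.write_coords(sd.generate_coords(self.truth(), seed=2), str(a))
        sd.write_coords(sd.generate_coords(self.truth(), seed=2), str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_overlapping_truth_rejected(self):
        bad = sd.RearrangementTruth(
            {"q": [("chr1", 1, 1000, "+"), ("chr1", 500, 2000, "+")]})
        with pytest.raises(ValueError, match="overlap"):
            sd.generate_coords(bad, seed=0)

    def test_minus_strand_blocks_reverse_query_coords(self):
        df = sd.generate_coords(self.truth(), seed=3)
        minus = df[df["query_chrom"] == "scaf2"]
        assert (minus["query_start"] > minus["query_end"]).all()


class TestMitoAlignment:
    def test_theta_zero_identical(self):
        recs = sd.generate_mito_alignment(6, 0.0, 500, seed=1)
        seqs = {s for _n, s in recs}
        assert len(seqs) == 1

    def test_expected_segregating_sites(self):
        """Mean S over replicates within 3 SE of theta * a_{n-1}."""
        n, target = 12, 87.0
        theta = target / harmonic(n - 1)
        s_obs = []
        for rep in range(250):
            recs = sd.generate_mito_alignment(n, theta, 4000, seed=rep)
            arr = np.array([list(s) for _n2, s in recs])
            s_obs.append(sum(len(set(col)) > 1 for col in arr.T))
        s_obs = np.asarray(s_obs, dtype=float)
        se = s_obs.std() / np.sqrt(s_obs.size)
        assert abs(s_obs.mean() - target) < 3 * se

    def test_homopolymer_ranges_monomorphic(self):
        recs = sd.generate_mito_alignment(
            8, 30.0, 2000, seed=2, homopolymer_ranges=[(100, 150)])
        arr = np.array([list(s) for _n, s in recs])
        block = arr[:, 99:150]
        assert (block == "C").all()

    def test_equal_length_uppercase_acgt(self):
        recs = sd.generate_mito_alignment(5, 10.0, 300, seed=3)
        assert len({len(s) for _n, s in recs}) == 1
        assert set("".join(s for _n, s in recs)) <= set("ACGT")
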