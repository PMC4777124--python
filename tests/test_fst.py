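import numpy as np
import pytest

from breedscan.fst import (
    FstError,
    bootstrap_outlier_recovery,
    fst_scan,
    multilocus_theta,
    pairwise_fst,
    theta_track,
    wc_theta_haploid,
)
from breedscan.genodata import HOM_ALT, HOM_REF
from breedscan.simdata import PopulationSpec, SimConfig, simulate

from .conftest import make_matrix


def anova_theta_oracle(counts):
    """Independently coded textbook one-way ANOVA estimator on haploid calls.

    Expands counts into explicit 0/1 observations and computes the mean
    squares by definition, without reusing any package code.
    """
    groups = [
        [1.0] * int(x) + [0.0] * int(n - x) for x, n in counts if n > 0
    ]
    r = len(groups)
    if r < 2:
        return np.nan
    all_obs = [v for grp in groups for v in grp]
    n_tot = len(all_obs)
    grand = sum(all_obs) / n_tot
    ss_among = sum(len(grp) * (np.mean(grp) - grand) ** 2 for grp in groups)
    ss_within = sum((v - np.mean(grp)) ** 2 for grp in groups for v in grp)
    msp = ss_among / (r - 1)
    dof_within = sum(len(grp) - 1 for grp in groups)
    if dof_within == 0:
        msg = 0.0
    else:
        msg = ss_within / dof_within
    sizes = [len(grp) for grp in groups]
    n_c = (n_tot - sum(s**2 for s in sizes) / n_tot) / (r - 1)
    denom = msp + (n_c - 1) * msg
    if denom == 0:
        return np.nan
    return (msp - msg) / denom


class TestWcThetaHaploid:
    def test_fixed_difference_is_one(self):
        assert wc_theta_haploid([(10, 10), (0, 10)]).theta == pytest.approx(1.0)

    def test_equal_frequencies(self):
        assert wc_theta_haploid([(5, 10), (5, 10)]).theta == pytest.approx(-1 / 9)

    def test_point_eight_point_two(self):
        comp = wc_theta_haploid([(8, 10), (2, 10)])
        assert comp.msp == pytest.approx(1.8)
        assert comp.msg == pytest.approx(0.17777777777, abs=1e-9)
        assert comp.n_c == pytest.approx(10.0)
        assert comp.theta == pytest.approx(0.477124183, abs=1e-8)

    def test_single_population_undefined(self):
        comp = wc_theta_haploid([(3, 5), (0, 0)])
        assert np.isnan(comp.theta)
        assert comp.reason is not None

    def test_count_exceeding_size_errors(self):
        with pytest.raises(FstError):
            wc_theta_haploid([(6, 5), (1, 5)])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            counts = []
            for _ in range(rng.integers(2, 5)):
                n = int(rng.integers(2, 7))
                counts.append((int(rng.integers(0, n + 1)), n))
            mine = wc_theta_haploid(counts).theta
            oracle = anova_theta_oracle(counts)
            if np.isnan(oracle):
                assert np.isnan(mine)
            else:
                assert mine == pytest.approx(oracle, abs=1e-12)


def _two_group_matrix(seed=0, n_snps=400, n=20, p_shift=0.0):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.8, n_snps)
    ca = (rng.random((n, n_snps)) < p).astype(np.int8)
    cb = (rng.random((n, n_snps)) < np.clip(p + p_shift, 0, 1)).astype(np.int8)
    g = make_matrix(np.vstack([ca, cb]))
    groups = {"A": g.accession_ids[:n], "B": g.accession_ids[n:]}
    return g, groups


class TestFstScan:
    def test_outlier_fraction_matches_quantile(self):
        g, groups = _two_group_matrix(seed=1)
        scan = fst_scan(g, groups, quantile=0.975)
        defined = np.isfinite(scan.theta).sum()
        assert abs(len(scan.outliers) - 0.025 * defined) <= 1 + 1e-9

    def test_implanted_fixed_difference_is_outlier(self):
        g, groups = _two_group_matrix(seed=2)
        g.calls[:20, 0] = HOM_REF
        g.calls[20:, 0] = HOM_ALT
        scan = fst_scan(g, groups)
        assert g.snp_ids[0] in scan.outliers

    def test_no_differentiation_mean_near_zero(self):
        g, groups = _two_group_matrix(seed=3)
        scan = fst_scan(g, groups)
        assert abs(scan.mean_theta) < 0.02

    def test_permuted_labels_destroy_signal(self):
        g, groups = _two_group_matrix(seed=4, p_shift=0.2)
        scan_true = fst_scan(g, groups)
        rng = np.random.default_rng(0)
        ids = np.array(g.accession_ids)
        rng.shuffle(ids)
        permuted = {"A": list(ids[:20]), "B": list(ids[20:])}
        scan_perm = fst_scan(g, permuted)
        assert scan_perm.mean_theta < scan_true.mean_theta
        assert abs(scan_perm.mean_theta) < 0.02

    def test_too_few_groups_errors(self):
        g, groups = _two_group_matrix()
        with pytest.raises(FstError):
            fst_scan(g, {"A": groups["A"]})


class TestMultilocusTheta:
    @pytest.mark.parametrize("c", [0.05, 0.17, 0.23, 0.37])
    def test_recovers_balding_nichols_c(self, c):
        pops = [PopulationSpec(f"P{i}", 2, "spring", 50, c) for i in range(4)]
        cfg = SimConfig(
            populations=pops,
            snps_per_group={"1H": 1000, "2H": 1000},
            map_length_cm={"1H": 150.0, "2H": 150.0},
            c_habit=0.0,
            c_spike=0.0,
            selfing_generations=6,
            missing_rate=0.0,
            seed=101 + int(c * 100),
        )
        m, _, scheme, _, _ = simulate(cfg)
        groups = {p: scheme.members(p) for p in scheme.populations}
        assert multilocus_theta(m, groups) == pytest.approx(c, abs=0.02)


class TestPairwiseFst:
    def test_symmetric_with_zero_diagonal(self, small_bundle):
        matrix, _, scheme, _, _ = small_bundle
        groups = {p: scheme.members(p) for p in scheme.populations}
        mat = pairwise_fst(matrix, groups)
        np.testing.assert_allclose(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0)

    def test_duplicated_population_not_differentiated(self):
        g, groups = _two_group_matrix(seed=5)
        dup = {"X": groups["A"], "Y": groups["A"]}
        mat = pairwise_fst(g, dup)
        assert mat.loc["X", "Y"] <= 0

    def test_drift_ordering(self):
        pops = [
            PopulationSpec("A", 2, "spring", 40, 0.03),
            PopulationSpec("B", 2, "spring", 40, 0.03),
            PopulationSpec("C", 2, "spring", 40, 0.35),
        ]
        cfg = SimConfig(
            populations=pops,
            snps_per_group={"1H": 1200},
            map_length_cm={"1H": 150.0},
            c_habit=0.0,
            c_spike=0.0,
            selfing_generations=6,
            missing_rate=0.0,
            seed=7,
        )
        m, _, scheme, _, _ = simulate(cfg)
        groups = {p: scheme.members(p) for p in scheme.populations}
        mat = pairwise_fst(m, groups)
        assert mat.loc["A", "B"] < mat.loc["A", "C"]
        assert mat.loc["A", "B"] < mat.loc["B", "C"]


class TestBootstrap:
    def test_tiny_drop_fraction_full_recovery(self):
        g, groups = _two_group_matrix(seed=6, n_snps=200)
        rep = bootstrap_outlier_recovery(
            g, groups, mode="drop_snps", drop_fraction=1e-9, iterations=5, seed=1
        )
        assert rep.mean_recovery == pytest.approx(1.0)

    def test_strong_outliers_survive_sample_dropout(self):
        g, groups = _two_group_matrix(seed=7, n_snps=300)
        # implant fixed differences: rank-invariant extremes
        for j in range(5):
            g.calls[:20, j] = HOM_REF
            g.calls[20:, j] = HOM_ALT
        rep = bootstrap_outlier_recovery(
            g, groups, mode="drop_samples", drop_fraction=0.2, iterations=20, seed=2
        )
        base = fst_scan(g, groups)
        implanted = set(g.snp_ids[:5]) & set(base.outliers)
        assert len(implanted) == 5
        # fixed-difference SNPs keep theta=1 under any subsample, so overall
        # recovery must be at least their share of the outlier set
        assert rep.mean_recovery >= len(implanted) / len(base.outliers) - 1e-9

    def test_deterministic_under_seed(self):
        g, groups = _two_group_matrix(seed=8, n_snps=150)
        r1 = bootstrap_outlier_recovery(g, groups, iterations=10, seed=42)
        r2 = bootstrap_outlier_recovery(g, groups, iterations=10, seed=42)
        assert r1.recovery == r2.recovery

    def test_matches_independent_reranking_oracle(self):
        # 50-SNP instance: replay the same dropout draws and recompute the
        # surviving-outlier fraction from theta_track + quantile from scratch
        g, groups = _two_group_matrix(seed=9, n_snps=50)
        seed, iters = 3, 10
        rep = bootstrap_outlier_recovery(
            g, groups, mode="drop_snps", drop_fraction=0.2, iterations=iters, seed=seed
        )
        theta_full = theta_track(g, groups)
        thr_full = np.quantile(theta_full[np.isfinite(theta_full)], 0.975)
        original = {
            s for s, t in zip(g.snp_ids, theta_full) if np.isfinite(t) and t >= thr_full
        }
        rng = np.random.default_rng(seed)
        expected = []
        for _ in range(iters):
            dropped = set(rng.choice(g.n_snps, size=10, replace=False))
            keep_ids = [s for j, s in enumerate(g.snp_ids) if j not in dropped]
            sub = g.subset(snps=keep_ids)
            th = theta_track(sub, groups)
            thr = np.quantile(th[np.isfinite(th)], 0.975)
            out = {s for s, t in zip(keep_ids, th) if np.isfinite(t) and t >= thr}
            eligible = original & set(keep_ids)
            expected.append(len(out & eligible) / len(eligible) if eligible else 1.0)
        assert rep.recovery == pytest.approx(expected)

    def test_invalid_mode_errors(self):
        g, groups = _two_group_matrix(seed=10, n_snps=60)
        with pytest.raises(FstError):
            bootstrap_outlier_recovery(g, groups, mode="drop_everything")
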