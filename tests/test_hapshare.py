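import itertools

import numpy as np
import pytest

from breedscan.genodata import HET, HOM_ALT, HOM_REF, MISSING, GeneticMap
from breedscan.hapshare import (
    HaplotypeSet,
    HapShareError,
    collapse_to_haplotypes,
    ibs_sharing,
    ibs_windows,
    pair_sharing_lengths,
    phs_scan,
    sharing_length,
)

from .conftest import make_map, make_matrix


def hapset(rows, positions=None, groups=None):
    """Build a HaplotypeSet (and map) from nested allele lists (-1 missing)."""
    haps = np.asarray(rows, dtype=np.int8)
    n, s = haps.shape
    snp_ids = [f"snp{j}" for j in range(s)]
    gmap = GeneticMap(
        snp_ids=snp_ids,
        linkage_groups=groups or ["1H"] * s,
        positions_cm=np.asarray(positions if positions is not None else np.arange(s), dtype=float),
    )
    return HaplotypeSet(names=[f"h{i}" for i in range(n)], haplotypes=haps, snp_ids=snp_ids), gmap


def phs_oracle(h, gmap, min_freq=0.10, quantile=0.975):
    """Exhaustive double-loop PHS for tiny instances.

    Sharing length per pair and focal SNP by literal outward extension;
    pair standardization and the carrier/all-pairs contrast by explicit
    iteration over index pairs.
    """
    haps = h.haplotypes
    n, s = haps.shape
    pos = gmap.positions_cm
    grp = gmap.linkage_groups

    def share(i, j, x):
        a, b = haps[i], haps[j]
        if a[x] >= 0 and b[x] >= 0 and a[x] != b[x]:
            return 0.0
        shared = []
        for k in range(x, -1, -1):
            if grp[k] != grp[x]:
                break
            if a[k] < 0 or b[k] < 0:
                continue
            if a[k] != b[k]:
                break
            shared.append(k)
        for k in range(x + 1, s):
            if grp[k] != grp[x]:
                break
            if a[k] < 0 or b[k] < 0:
                continue
            if a[k] != b[k]:
                break
            shared.append(k)
        if not shared:
            return 0.0
        return float(pos[max(shared)] - pos[min(shared)])

    pairs = list(itertools.combinations(range(n), 2))
    d = {p: np.array([share(p[0], p[1], x) for x in range(s)]) for p in pairs}
    stats = {p: (d[p].mean(), d[p].std()) for p in pairs}
    valid = [p for p in pairs if stats[p][1] > 0]
    z = {p: (d[p] - stats[p][0]) / stats[p][1] for p in valid}
    rows = []
    for x in range(s):
        col = haps[:, x]
        typed = (col >= 0).sum()
        for allele in (0, 1):
            carriers = set(np.flatnonzero(col == allele))
            if len(carriers) < 2:
                continue
            car_pairs = [p for p in valid if p[0] in carriers and p[1] in carriers]
            if not car_pairs:
                continue
            phs = np.mean([z[p][x] for p in car_pairs]) - np.mean([z[p][x] for p in valid])
            rows.append((x, allele, phs, len(carriers) / typed))
    return rows


class TestCollapse:
    def test_lossless_for_homozygotes(self):
        g = make_matrix([[HOM_REF, HOM_ALT], [HOM_ALT, HOM_REF]])
        h = collapse_to_haplotypes(g)
        np.testing.assert_array_equal(h.haplotypes, [[0, 1], [1, 0]])

    def test_het_becomes_missing(self):
        g = make_matrix([[HET, HOM_REF], [HOM_REF, MISSING]])
        h = collapse_to_haplotypes(g)
        np.testing.assert_array_equal(h.haplotypes, [[-1, 0], [0, -1]])

    def test_reorders_to_map(self):
        g = make_matrix([[HOM_REF, HOM_ALT], [HOM_ALT, HOM_REF]])
        gmap = GeneticMap(
            snp_ids=["snp1", "snp0"], linkage_groups=["1H", "1H"], positions_cm=[0.0, 5.0]
        )
        h = collapse_to_haplotypes(g, gmap)
        assert h.snp_ids == ["snp1", "snp0"]


class TestSharingLength:
    def test_hand_enumerated_toy(self):
        # match at SNP ranks 1..3 (0-based) of five, focal rank 2 -> 3-1 = 2 cM
        h, gmap = hapset(
            [[0, 1, 1, 1, 0], [1, 1, 1, 1, 1]], positions=[0, 1, 2, 3, 4]
        )
        assert sharing_length(h, gmap, 0, 1, "snp2") == pytest.approx(2.0)

    def test_identical_haplotypes_full_length(self):
        h, gmap = hapset([[0, 1, 0, 1], [0, 1, 0, 1]], positions=[0.0, 50.0, 100.0, 139.6])
        assert sharing_length(h, gmap, 0, 1, "snp1") == pytest.approx(139.6)

    def test_mismatch_at_focal_is_zero(self):
        h, gmap = hapset([[0, 0, 0], [0, 1, 0]])
        assert sharing_length(h, gmap, 0, 1, "snp1") == 0.0

    def test_missing_skipped_not_breaking(self):
        h, gmap = hapset([[1, -1, 1, 1], [1, 0, 1, 1]], positions=[0, 1, 2, 3])
        # missing at rank 1 on hap0 is skipped; full span 0..3 shared
        assert sharing_length(h, gmap, 0, 1, "snp0") == pytest.approx(3.0)

    def test_stops_at_chromosome_end(self):
        h, gmap = hapset(
            [[1, 1, 0, 0], [1, 1, 0, 1]],
            positions=[0, 10, 0, 10],
            groups=["1H", "1H", "2H", "2H"],
        )
        assert sharing_length(h, gmap, 0, 1, "snp1") == pytest.approx(10.0)
        assert sharing_length(h, gmap, 0, 1, "snp2") == pytest.approx(0.0)

    def test_same_haplotype_errors(self):
        h, gmap = hapset([[0, 1], [1, 0]])
        with pytest.raises(HapShareError):
            pair_sharing_lengths(h, gmap, 1, 1)


class TestPhsScan:
    def test_allele_carried_by_all_scores_zero(self):
        rng = np.random.default_rng(2)
        haps = rng.integers(0, 2, size=(6, 25)).astype(np.int8)
        haps[:, 10] = 1  # fixed allele
        h, gmap = hapset(haps)
        scan = phs_scan(h, gmap)
        row = scan.table[(scan.table.snp_id == "snp10") & (scan.table.allele == 1)]
        assert row["phs"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.choice(
            np.array([0, 1, -1], dtype=np.int8), size=(7, 24), p=[0.45, 0.45, 0.1]
        )
        groups = ["1H"] * 12 + ["2H"] * 12
        h, gmap = hapset(haps, positions=list(range(12)) + list(range(12)), groups=groups)
        scan = phs_scan(h, gmap)
        oracle = phs_oracle(h, gmap)
        mine = {
            (r.snp_id, r.allele): r.phs for r in scan.table.itertuples()
        }
        assert len(mine) == len(oracle)
        for x, allele, phs, freq in oracle:
            assert mine[(f"snp{x}", allele)] == pytest.approx(phs, abs=1e-12)

    def test_implanted_segment_elevates_phs(self):
        rng = np.random.default_rng(13)
        haps = rng.integers(0, 2, size=(6, 20)).astype(np.int8)
        haps[0:3, 7:14] = haps[0, 7:14]  # three carriers share ranks 7..13
        h, gmap = hapset(haps)
        scan = phs_scan(h, gmap)
        inside = scan.table[scan.table.snp_id.isin([f"snp{j}" for j in range(8, 13)])]
        outside = scan.table[scan.table.snp_id.isin([f"snp{j}" for j in (0, 1, 18, 19)])]
        assert inside.phs.max() > outside.phs.max()

    def test_identical_pair_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(5, 30)).astype(np.int8)
        haps[1] = haps[0]
        h, gmap = hapset(haps)
        with pytest.warns(UserWarning, match="zero sharing variance"):
            scan = phs_scan(h, gmap)
        assert scan.excluded_pairs == 1

    def test_too_few_haplotypes_errors(self):
        h, gmap = hapset([[0, 1], [1, 0], [0, 0]])
        with pytest.raises(HapShareError):
            phs_scan(h, gmap)

    def test_outliers_respect_min_freq(self):
        rng = np.random.default_rng(4)
        haps = rng.integers(0, 2, size=(12, 40)).astype(np.int8)
        h, gmap = hapset(haps)
        scan = phs_scan(h, gmap, min_freq=0.10)
        flagged = scan.table[scan.table.outlier]
        assert (flagged.carrier_freq >= 0.10).all()


class TestIbsWindows:
    def test_half_overlap_tiling(self):
        wins = ibs_windows(200, 50)
        assert wins[0] == (0, 50)
        assert wins[1] == (25, 75)
        assert wins[-1][1] == 200

    def test_trailing_partial_merged(self):
        wins = ibs_windows(130, 50)
        assert wins[-1] == (75, 130)
        assert all(e - s >= 50 for s, e in wins)

    def test_short_group_single_window(self):
        assert ibs_windows(30, 50) == [(0, 30)]


class TestIbsSharing:
    def test_identical_populations_share_everywhere(self):
        rng = np.random.default_rng(5)
        haps = rng.integers(0, 2, size=(4, 120)).astype(np.int8)
        h, gmap = hapset(haps)
        track = ibs_sharing(h, h, gmap, window_snps=50, max_mismatch=0.10)
        assert (track.freq_a == 1.0).all()
        assert (track.freq_b == 1.0).all()

    def test_mismatch_boundary_inclusive(self):
        base = np.zeros((1, 50), dtype=np.int8)
        other = base.copy()
        other[0, :5] = 1  # exactly 10% mismatches
        ha, gmap = hapset(base)
        hb = HaplotypeSet(names=["x"], haplotypes=other, snp_ids=ha.snp_ids)
        track = ibs_sharing(ha, hb, gmap, window_snps=50, max_mismatch=0.10)
        assert track.freq_a.iloc[0] == 1.0

    def test_one_extra_mismatch_fails(self):
        base = np.zeros((1, 50), dtype=np.int8)
        other = base.copy()
        other[0, :6] = 1  # 12% mismatches
        ha, gmap = hapset(base)
        hb = HaplotypeSet(names=["x"], haplotypes=other, snp_ids=ha.snp_ids)
        track = ibs_sharing(ha, hb, gmap, window_snps=50, max_mismatch=0.10)
        assert track.freq_a.iloc[0] == 0.0

    def test_symmetry_under_population_swap(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 2, size=(5, 100)).astype(np.int8)
        b = rng.integers(0, 2, size=(7, 100)).astype(np.int8)
        ha, gmap = hapset(a)
        hb = HaplotypeSet(names=[f"b{i}" for i in range(7)], haplotypes=b, snp_ids=ha.snp_ids)
        t1 = ibs_sharing(ha, hb, gmap, window_snps=50)
        t2 = ibs_sharing(hb, ha, gmap, window_snps=50)
        np.testing.assert_allclose(t1.freq_a, t2.freq_b)
        np.testing.assert_allclose(t1.freq_b, t2.freq_a)

    def test_requires_half_window_jointly_typed(self):
        a = np.zeros((1, 50), dtype=np.int8)
        b = np.full((1, 50), -1, dtype=np.int8)
        b[0, :10] = 0  # only 20% jointly typed, though perfectly matching
        ha, gmap = hapset(a)
        hb = HaplotypeSet(names=["x"], haplotypes=b, snp_ids=ha.snp_ids)
        track = ibs_sharing(ha, hb, gmap, window_snps=50)
        assert track.freq_a.iloc[0] == 0.0

    def test_mismatched_snp_sets_error(self):
        ha, gmap = hapset([[0, 1]])
        hb = HaplotypeSet(names=["x"], haplotypes=np.zeros((1, 3), dtype=np.int8), snp_ids=["a", "b", "c"])
        with pytest.raises(HapShareError):
            ibs_sharing(ha, hb, gmap)


class TestConfigSwitches:
    def test_missing_breaks_shortens_sharing(self):
        h, gmap = hapset([[1, -1, 1, 1], [1, 0, 1, 1]], positions=[0, 1, 2, 3])
        assert sharing_length(h, gmap, 0, 1, "snp2") == pytest.approx(3.0)
        assert sharing_length(h, gmap, 0, 1, "snp2", missing_breaks=True) == pytest.approx(1.0)

    def test_per_chromosome_normalization_runs(self):
        rng = np.random.default_rng(9)
        haps = rng.integers(0, 2, size=(6, 40)).astype(np.int8)
        groups = ["1H"] * 20 + ["2H"] * 20
        h, gmap = hapset(haps, positions=list(range(20)) * 2, groups=groups)
        scan = phs_scan(h, gmap, per_chromosome=True)
        assert len(scan.table) > 0
        assert np.isfinite(scan.table.phs).all()
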