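"""Haplotype construction for inbreds, the pairwise haplotype sharing (PHS)
selection scan, and windowed identity-by-state sharing between populations.

Phased haplotypes are obtained by collapsing near-fully-inbred genotypes:
each accession yields one haploid allele string with heterozygous calls set
to missing. Sharing lengths are measured in cM on the genetic map; a missing
site in either haplotype neither extends nor breaks a shared segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import HET, MISSING, GeneticMap, GenotypeMatrix

__all__ = [
    "HaplotypeSet",
    "PhsScan",
    "collapse_to_haplotypes",
    "sharing_length",
    "pair_sharing_lengths",
    "phs_scan",
    "ibs_windows",
    "ibs_sharing",
]


class HapShareError(ValueError):
    pass


@dataclass
class HaplotypeSet:
    """One haploid 0/1/-1 allele string per accession, SNPs in map order."""

    names: list[str]
    haplotypes: np.ndarray  # (n_haplotypes, n_snps), int8, -1 = missing
    snp_ids: list[str]
    collapsed_inbred: bool = True

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.names), len(self.snp_ids)):
            raise HapShareError("haplotype matrix shape mismatch")

    @property
    def n_haplotypes(self) -> int:
        return len(self.names)

    def subset(self, names) -> "HaplotypeSet":
        lookup = {a: i for i, a in enumerate(self.names)}
        rows = [lookup[a] for a in names]
        return HaplotypeSet(
            names=list(names),
            haplotypes=self.haplotypes[rows].copy(),
            snp_ids=list(self.snp_ids),
            collapsed_inbred=self.collapsed_inbred,
        )


def collapse_to_haplotypes(g: GenotypeMatrix, gmap: GeneticMap | None = None) -> HaplotypeSet:
    """Collapse genotypes to one haplotype per accession (HET -> missing).

    If a map is given, SNPs are reordered to map order first.
    """
    if gmap is not None:
        gmap = gmap.aligned_to(g.snp_ids)
        g = g.subset(snps=gmap.snp_ids)
    haps = g.calls.copy()
    haps[haps == HET] = MISSING
    return HaplotypeSet(names=list(g.accession_ids), haplotypes=haps, snp_ids=list(g.snp_ids))


def _pair_lengths_one_group(
    a: np.ndarray, b: np.ndarray, pos: np.ndarray, missing_breaks: bool = False
) -> np.ndarray:
    """Sharing length at every focal SNP of one linkage group for one pair.

    Shared segments run between mismatches (sites where both haplotypes are
    typed and differ); missing sites are skipped by default, or treated as
    segment breaks when ``missing_breaks`` is set. The length at a focal SNP
    is cM(last matching site) - cM(first matching site) within its segment,
    and 0 at a mismatching focal SNP or in a segment with no matching site.
    """
    m = len(pos)
    both = (a >= 0) & (b >= 0)
    mismatch = (both & (a != b)) | (~both if missing_breaks else False)
    match = both & (a == b)
    # segment id = number of mismatches strictly before each position
    seg = np.concatenate(([0], np.cumsum(mismatch[:-1])))
    n_seg = int(mismatch.sum()) + 1
    first = np.full(n_seg, -1, dtype=int)
    last = np.full(n_seg, -1, dtype=int)
    match_idx = np.flatnonzero(match)
    if match_idx.size:
        segs = seg[match_idx]
        uniq, first_pos = np.unique(segs, return_index=True)
        first[uniq] = match_idx[first_pos]
        uniq_r, last_pos = np.unique(segs[::-1], return_index=True)
        last[uniq_r] = match_idx[::-1][last_pos]
    d_seg = np.zeros(n_seg)
    ok = first >= 0
    d_seg[ok] = pos[last[ok]] - pos[first[ok]]
    d = d_seg[seg]
    d[mismatch] = 0.0
    return d


def pair_sharing_lengths(
    h: HaplotypeSet, gmap: GeneticMap, i: int, j: int, missing_breaks: bool = False
) -> np.ndarray:
    """Vector of sharing lengths d_ijx (cM) over all focal SNPs, in map order."""
    if i == j:
        raise HapShareError("need two distinct haplotypes")
    gmap = gmap.aligned_to(h.snp_ids)
    order = {s: k for k, s in enumerate(h.snp_ids)}
    cols = np.array([order[s] for s in gmap.snp_ids])
    a, b = h.haplotypes[i, cols], h.haplotypes[j, cols]
    out = np.empty(len(cols))
    for sl in gmap.group_slices().values():
        out[sl] = _pair_lengths_one_group(a[sl], b[sl], gmap.positions_cm[sl], missing_breaks)
    return out


def sharing_length(
    h: HaplotypeSet, gmap: GeneticMap, i: int, j: int, focal_snp: str, missing_breaks: bool = False
) -> float:
    """Sharing length d_ijx at one focal SNP."""
    gmap = gmap.aligned_to(h.snp_ids)
    k = gmap.snp_ids.index(focal_snp)
    return float(pair_sharing_lengths(h, gmap, i, j, missing_breaks)[k])


@dataclass
class PhsScan:
    """Per (focal SNP, allele) PHS values with the empirical outlier threshold."""

    table: pd.DataFrame  # snp_id, allele, phs, carrier_freq, mean_share_cM, outlier
    threshold: float
    quantile: float
    min_freq: float
    excluded_pairs: int


def phs_scan(
    h: HaplotypeSet,
    gmap: GeneticMap,
    min_freq: float = 0.10,
    quantile: float = 0.975,
    missing_breaks: bool = False,
    per_chromosome: bool = False,
) -> PhsScan:
    """PHS selection scan over every (focal SNP, allele) with >= 2 carriers.

    For each haplotype pair the sharing lengths d_ijx are standardized
    genome-wide to Z_ijx = (d_ijx - mean_ij) / sd_ij; the PHS of allele A at
    focal SNP x is the mean Z over carrier pairs minus the mean Z over all
    pairs. Pairs with zero genome-wide sd (identical haplotypes) are excluded.
    Outliers are entries with carrier frequency >= ``min_freq`` whose PHS is
    at or above the ``quantile`` of eligible PHS values. Standardization is
    genome-wide by default; ``per_chromosome`` normalizes each pair within
    linkage groups instead.
    """
    n = h.n_haplotypes
    if n < 4:
        raise HapShareError("PHS needs >= 4 haplotypes")
    gmap = gmap.aligned_to(h.snp_ids)
    hs = h.subset(h.names)
    order = {s: k for k, s in enumerate(hs.snp_ids)}
    cols = np.array([order[s] for s in gmap.snp_ids])
    haps = hs.haplotypes[:, cols]
    n_snps = len(cols)

    pair_i, pair_j = np.triu_indices(n, k=1)
    d = np.empty((len(pair_i), n_snps))
    slices = list(gmap.group_slices().values())
    for p, (i, j) in enumerate(zip(pair_i, pair_j)):
        for sl in slices:
            d[p, sl] = _pair_lengths_one_group(
                haps[i, sl], haps[j, sl], gmap.positions_cm[sl], missing_breaks
            )

    if per_chromosome:
        z_full = np.empty_like(d)
        valid = np.ones(d.shape[0], dtype=bool)
        for sl in slices:
            dbar = d[:, sl].mean(axis=1)
            sd = d[:, sl].std(axis=1)
            valid &= sd > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                z_full[:, sl] = (d[:, sl] - dbar[:, None]) / sd[:, None]
    else:
        dbar = d.mean(axis=1)
        sd = d.std(axis=1)
        valid = sd > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            z_full = (d - dbar[:, None]) / sd[:, None]
    excluded = int((~valid).sum())
    if excluded:
        warnings.warn(f"{excluded} haplotype pair(s) with zero sharing variance excluded from PHS")
    if not valid.any():
        raise HapShareError("all haplotype pairs identical genome-wide")
    z = z_full[valid]
    vi, vj = pair_i[valid], pair_j[valid]
    z_all_mean = z.mean(axis=0)

    rows = []
    for x in range(n_snps):
        col = haps[:, x]
        n_typed = int((col >= 0).sum())
        if n_typed == 0:
            continue
        for allele in (0, 1):
            carriers = col == allele
            p_car = int(carriers.sum())
            if p_car < 2:
                continue
            mask = carriers[vi] & carriers[vj]
            if not mask.any():
                continue
            phs = float(z[mask, x].mean() - z_all_mean[x])
            rows.append(
                {
                    "snp_id": gmap.snp_ids[x],
                    "allele": allele,
                    "phs": phs,
                    "carrier_freq": p_car / n_typed,
                    "mean_share_cM": float(d[valid][mask, x].mean()),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise HapShareError("no (SNP, allele) entries with >= 2 carriers")
    eligible = table["carrier_freq"] >= min_freq
    if eligible.any():
        threshold = float(np.quantile(table.loc[eligible, "phs"], quantile))
        table["outlier"] = eligible & (table["phs"] >= threshold)
    else:
        threshold = np.nan
        table["outlier"] = False
    return PhsScan(
        table=table,
        threshold=threshold,
        quantile=quantile,
        min_freq=min_freq,
        excluded_pairs=excluded,
    )


def ibs_windows(n_snps_in_group: int, window_snps: int) -> list[tuple[int, int]]:
    """Half-overlapping window bounds tiling one linkage group.

    Step is ``window_snps // 2``; a trailing partial window is merged into the
    last full one. A group shorter than one window yields a single window.
    """
    if n_snps_in_group <= window_snps:
        return [(0, n_snps_in_group)]
    step = max(window_snps // 2, 1)
    starts = [s for s in range(0, n_snps_in_group - window_snps + 1, step)]
    wins = [(s, s + window_snps) for s in starts]
    wins[-1] = (wins[-1][0], n_snps_in_group)
    return wins


def ibs_sharing(
    h_a: HaplotypeSet,
    h_b: HaplotypeSet,
    gmap: GeneticMap,
    window_snps: int = 100,
    max_mismatch: float = 0.10,
    min_joint_fraction: float = 0.5,
) -> pd.DataFrame:
    """Windowed between-population IBS sharing frequencies.

    Two haplotypes are window-IBS when the mismatch fraction among jointly
    typed sites is <= ``max_mismatch`` and at least ``min_joint_fraction`` of
    the window is jointly typed. Per window the sharing frequency in each
    population is the fraction of its haplotypes that are window-IBS with at
    least one haplotype of the other population.
    """
    if h_a.snp_ids != h_b.snp_ids:
        raise HapShareError("populations must share the same SNP set")
    gmap = gmap.aligned_to(h_a.snp_ids)
    order = {s: k for k, s in enumerate(h_a.snp_ids)}
    cols = np.array([order[s] for s in gmap.snp_ids])
    ha = h_a.haplotypes[:, cols]
    hb = h_b.haplotypes[:, cols]

    rows = []
    for group, sl in gmap.group_slices().items():
        pos = gmap.positions_cm[sl]
        ga, gb = ha[:, sl], hb[:, sl]
        for w, (s, e) in enumerate(ibs_windows(sl.stop - sl.start, window_snps)):
            wa = ga[:, s:e][:, None, :]  # (nA, 1, w)
            wb = gb[:, s:e][None, :, :]  # (1, nB, w)
            joint = (wa >= 0) & (wb >= 0)
            mism = joint & (wa != wb)
            n_joint = joint.sum(axis=2)
            n_mism = mism.sum(axis=2)
            enough = n_joint >= min_joint_fraction * (e - s)
            with np.errstate(invalid="ignore"):
                frac = np.where(n_joint > 0, n_mism / np.maximum(n_joint, 1), np.inf)
            ibs = enough & (frac <= max_mismatch)
            rows.append(
                {
                    "linkage_group": group,
                    "window": w,
                    "start_cM": float(pos[s]),
                    "end_cM": float(pos[e - 1]),
                    "n_snps": int(e - s),
                    "freq_a": float(ibs.any(axis=1).mean()),
                    "freq_b": float(ibs.any(axis=0).mean()),
                }
            )
    return pd.DataFrame(rows)
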