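"""Per-population summary statistics: pairwise diversity, F_IS, private SNPs,
and sliding-window diversity profiles along the genetic map."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import HET, HOM_ALT, HOM_REF, MISSING, GeneticMap, GenotypeMatrix, PopulationScheme

__all__ = [
    "per_snp_diversity",
    "pairwise_diversity",
    "sliding_diversity",
    "inbreeding_coefficient",
    "private_snps",
    "diversity_table",
]


class DiversityError(ValueError):
    pass


def _haploid_counts(g: GenotypeMatrix, members) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (alt count, non-missing haploid sample size) from homozygous calls.

    Heterozygous and missing calls are dropped; each homozygote contributes one
    haploid-coded call.
    """
    rows = g.accession_index(members)
    sub = g.calls[rows]
    alt = np.sum(sub == HOM_ALT, axis=0)
    n = alt + np.sum(sub == HOM_REF, axis=0)
    return alt.astype(float), n.astype(float)


def per_snp_diversity(g: GenotypeMatrix, members, unbiased: bool = True) -> np.ndarray:
    """Per-SNP pairwise-difference probability 2p(1-p), optionally n/(n-1)-corrected.

    Returns NaN for SNPs monomorphic (or with n < 2) within the population.
    """
    alt, n = _haploid_counts(g, members)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        d = 2.0 * p * (1.0 - p)
        if unbiased:
            d = np.where(n > 1, d * n / np.maximum(n - 1.0, 1.0), np.nan)
    d[(n < 2) | (alt == 0) | (alt == n)] = np.nan
    return d


def pairwise_diversity(g: GenotypeMatrix, members, unbiased: bool = True) -> float:
    """Mean per-SNP pairwise diversity over SNPs polymorphic within the population."""
    if len(members) < 2:
        raise DiversityError("pairwise diversity needs at least 2 members")
    d = per_snp_diversity(g, members, unbiased=unbiased)
    ok = ~np.isnan(d)
    if not ok.any():
        raise DiversityError("no polymorphic SNP retained within the population")
    return float(np.mean(d[ok]))


def sliding_diversity(
    g: GenotypeMatrix,
    members,
    gmap: GeneticMap,
    window_snps: int = 10,
    step_snps: int = 5,
    unbiased: bool = True,
) -> pd.DataFrame:
    """Sliding-window mean of per-SNP diversity, windows confined to linkage groups.

    Each window is anchored at the mean cM of its SNPs. A linkage group shorter
    than one window yields a single truncated window.
    """
    gmap = gmap.aligned_to(g.snp_ids)
    sub = g.subset(snps=gmap.snp_ids)
    d = per_snp_diversity(sub, members, unbiased=unbiased)
    rows = []
    for group, sl in gmap.group_slices().items():
        vals = d[sl]
        pos = gmap.positions_cm[sl]
        m = len(vals)
        starts = list(range(0, max(m - window_snps, 0) + 1, step_snps)) or [0]
        for w, s in enumerate(starts):
            e = min(s + window_snps, m)
            window = vals[s:e]
            ok = ~np.isnan(window)
            rows.append(
                {
                    "linkage_group": group,
                    "window": w,
                    "cM": float(np.mean(pos[s:e])),
                    "n_snps": int(e - s),
                    "diversity": float(np.mean(window[ok])) if ok.any() else np.nan,
                }
            )
    return pd.DataFrame(rows)


def inbreeding_coefficient(
    g: GenotypeMatrix, members, per_snp_mean: bool = True
) -> float:
    """F_IS = 1 - H_o/H_e averaged over SNPs with expected heterozygosity > 0.

    Genotypes contribute two alleles each (heterozygotes half to each allele);
    ``per_snp_mean=False`` returns the ratio-of-means variant
    1 - mean(H_o)/mean(H_e) instead of the mean of per-SNP ratios.
    """
    if len(members) < 2:
        raise DiversityError("F_IS needs at least 2 members")
    rows = g.accession_index(members)
    sub = g.calls[rows]
    nonmiss = np.sum(sub != MISSING, axis=0).astype(float)
    het = np.sum(sub == HET, axis=0).astype(float)
    alt2 = 2.0 * np.sum(sub == HOM_ALT, axis=0) + het
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt2 / (2.0 * np.maximum(nonmiss, 1))
        h_exp = 2.0 * p * (1.0 - p)
        h_obs = het / np.maximum(nonmiss, 1)
    ok = (nonmiss > 0) & (h_exp > 0)
    if not ok.any():
        raise DiversityError("no SNP with expected heterozygosity > 0")
    if per_snp_mean:
        return float(np.mean(1.0 - h_obs[ok] / h_exp[ok]))
    return float(1.0 - np.mean(h_obs[ok]) / np.mean(h_exp[ok]))


def _polymorphic_mask(g: GenotypeMatrix, members) -> np.ndarray:
    alt, n = _haploid_counts(g, members)
    return (alt > 0) & (alt < n)


def private_snps(g: GenotypeMatrix, groups: dict[str, list[str]]) -> dict[str, int]:
    """Count SNPs polymorphic within exactly one group and monomorphic elsewhere.

    ``groups`` may be any partition of accessions (breeding populations, or
    coarser groupings such as spring vs winter).
    """
    if len(groups) < 2:
        raise DiversityError("private SNP counting needs >= 2 groups")
    names = sorted(groups)
    poly = np.stack([_polymorphic_mask(g, groups[k]) for k in names])
    n_poly = poly.sum(axis=0)
    return {k: int(np.sum(poly[i] & (n_poly == 1))) for i, k in enumerate(names)}


def diversity_table(
    g: GenotypeMatrix, scheme: PopulationScheme, unbiased: bool = True
) -> pd.DataFrame:
    """Per-population summary: sample size, polymorphic markers, diversity, F_IS, private SNPs."""
    groups = {p: scheme.members(p) for p in scheme.populations}
    privates = private_snps(g, groups) if len(groups) >= 2 else {p: 0 for p in groups}
    rows = []
    for pop in scheme.populations:
        members = groups[pop]
        poly = int(_polymorphic_mask(g, members).sum())
        try:
            div = pairwise_diversity(g, members, unbiased=unbiased)
        except DiversityError:
            div = np.nan
        try:
            fis = inbreeding_coefficient(g, members)
        except DiversityError:
            fis = np.nan
        rows.append(
            {
                "population": pop,
                "n_accessions": len(members),
                "n_polymorphic": poly,
                "avg_pairwise_diversity": div,
                "mean_F_IS": fis,
                "private_snps": privates[pop],
            }
        )
    return pd.DataFrame(rows)
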