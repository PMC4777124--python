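"""Haploid Weir–Cockerham theta, empirical outlier scans, pairwise population
F_ST matrices, and dropout-bootstrap robustness of outlier sets.

Heterozygous calls are treated as missing throughout; each homozygote
contributes one haploid allele copy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import HOM_ALT, HOM_REF, GenotypeMatrix

__all__ = [
    "wc_theta_haploid",
    "theta_track",
    "multilocus_theta",
    "fst_scan",
    "pairwise_fst",
    "bootstrap_outlier_recovery",
    "FstComponents",
    "FstScan",
    "BootstrapReport",
]


class FstError(ValueError):
    pass


@dataclass
class FstComponents:
    """ANOVA components of the haploid theta estimator at one SNP."""

    r: int
    n_i: np.ndarray
    p_i: np.ndarray
    n_bar: float
    n_c: float
    msp: float
    msg: float
    theta: float  # NaN when undefined
    reason: str | None = None  # why theta is undefined, if it is


def wc_theta_haploid(counts) -> FstComponents:
    """Haploid ANOVA theta from per-population (allele count, sample size) pairs.

    ``counts`` is a sequence of (x_i, n_i): x_i copies of the reference-coded
    allele among n_i non-missing haploid calls. With p_bar the weighted mean
    frequency,

        MSP = sum n_i (p_i - p_bar)^2 / (r - 1)
        MSG = sum n_i p_i (1 - p_i) / sum (n_i - 1)
        n_c = (sum n_i - sum n_i^2 / sum n_i) / (r - 1)
        theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

    Theta is NaN (with a reason) when fewer than 2 populations carry data or
    when the denominator vanishes (e.g. the SNP is monomorphic overall).
    """
    arr = np.asarray([(x, n) for x, n in counts], dtype=float)
    keep = arr[:, 1] > 0
    x, n = arr[keep, 0], arr[keep, 1]
    r = int(keep.sum())
    if np.any(x > n) or np.any(x < 0):
        raise FstError("allele count exceeds sample size")
    if r < 2:
        return FstComponents(r, n, np.full_like(n, np.nan), np.nan, np.nan, np.nan, np.nan, np.nan, "fewer than 2 populations with data")
    p = x / n
    n_tot = n.sum()
    n_bar = n_tot / r
    p_bar = (n * p).sum() / n_tot
    msp = (n * (p - p_bar) ** 2).sum() / (r - 1)
    # with all n_i = 1 the within mean square is 0/0; its numerator is always
    # 0 there, so MSG = 0 by convention
    denom_g = (n - 1).sum()
    msg = (n * p * (1 - p)).sum() / denom_g if denom_g > 0 else 0.0
    n_c = (n_tot - (n**2).sum() / n_tot) / (r - 1)
    denom = msp + (n_c - 1) * msg
    if not np.isfinite(denom) or denom == 0:
        reason = "monomorphic" if p_bar in (0.0, 1.0) else "zero denominator"
        theta, reason_out = np.nan, reason
    else:
        theta, reason_out = (msp - msg) / denom, None
    return FstComponents(r, n, p, n_bar, n_c, msp, msg, float(theta), reason_out)


def _group_counts(g: GenotypeMatrix, groups: dict[str, list[str]]) -> tuple[np.ndarray, np.ndarray]:
    """Stacked per-group (ref allele counts, haploid sample sizes), shape (k, S)."""
    xs, ns = [], []
    for name in sorted(groups):
        rows = g.accession_index(groups[name])
        sub = g.calls[rows]
        ref = np.sum(sub == HOM_REF, axis=0).astype(float)
        alt = np.sum(sub == HOM_ALT, axis=0).astype(float)
        xs.append(ref)
        ns.append(ref + alt)
    return np.stack(xs), np.stack(ns)


def _theta_components_vec(x: np.ndarray, n: np.ndarray):
    """Vectorized per-SNP (MSP, MSG, n_c, defined mask) over all SNPs at once."""
    with np.errstate(divide="ignore", invalid="ignore"):
        has = n > 0
        r = has.sum(axis=0)
        n_tot = n.sum(axis=0)
        p = np.where(has, x / np.maximum(n, 1), 0.0)
        p_bar = np.where(n_tot > 0, (n * p).sum(axis=0) / np.maximum(n_tot, 1), np.nan)
        msp = (n * (p - p_bar) ** 2 * has).sum(axis=0) / np.maximum(r - 1, 1)
        denom_g = (np.maximum(n - 1, 0)).sum(axis=0)
        msg = (n * p * (1 - p)).sum(axis=0) / np.maximum(denom_g, 1)
        n_c = (n_tot - (n**2).sum(axis=0) / np.maximum(n_tot, 1)) / np.maximum(r - 1, 1)
        denom = msp + (n_c - 1) * msg
        defined = (r >= 2) & np.isfinite(denom) & (denom != 0)
    return msp, msg, n_c, denom, defined


def theta_track(g: GenotypeMatrix, groups: dict[str, list[str]]) -> np.ndarray:
    """Per-SNP haploid theta across the given groups; NaN where undefined."""
    x, n = _group_counts(g, groups)
    msp, msg, n_c, denom, defined = _theta_components_vec(x, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(defined, (msp - msg) / denom, np.nan)
    return theta


def multilocus_theta(g: GenotypeMatrix, groups: dict[str, list[str]]) -> float:
    """Ratio-of-sums multi-locus theta: components summed over SNPs before the ratio."""
    x, n = _group_counts(g, groups)
    msp, msg, n_c, denom, defined = _theta_components_vec(x, n)
    num = (msp - msg)[defined].sum()
    den = denom[defined].sum()
    if den == 0:
        raise FstError("multilocus theta undefined (zero denominator)")
    return float(num / den)


@dataclass
class FstScan:
    """Per-SNP theta scan with an empirical outlier threshold."""

    snp_ids: list[str]
    theta: np.ndarray
    quantile: float
    threshold: float
    outliers: list[str]
    mean_theta: float

    def to_frame(self, gmap=None) -> pd.DataFrame:
        df = pd.DataFrame({"snp_id": self.snp_ids, "theta": self.theta})
        df["outlier"] = [s in set(self.outliers) for s in self.snp_ids]
        if gmap is not None:
            aligned = gmap.aligned_to(self.snp_ids)
            pos = dict(zip(aligned.snp_ids, aligned.positions_cm))
            grp = dict(zip(aligned.snp_ids, aligned.linkage_groups))
            df["linkage_group"] = [grp[s] for s in self.snp_ids]
            df["cM"] = [pos[s] for s in self.snp_ids]
        return df


def fst_scan(
    g: GenotypeMatrix, groups: dict[str, list[str]], quantile: float = 0.975
) -> FstScan:
    """Empirical-quantile outlier scan over per-SNP theta values.

    The threshold is the ``quantile`` of defined thetas; outliers are SNPs at
    or above it (ties included). Negative thetas are retained so the quantile
    is taken on the full distribution.
    """
    if len(groups) < 2:
        raise FstError("scan needs >= 2 groups")
    theta = theta_track(g, groups)
    defined = np.isfinite(theta)
    if defined.sum() < 2:
        raise FstError("fewer than 2 SNPs with defined theta")
    vals = theta[defined]
    threshold = float(np.quantile(vals, quantile))
    out = [s for s, t in zip(g.snp_ids, theta) if np.isfinite(t) and t >= threshold]
    return FstScan(
        snp_ids=list(g.snp_ids),
        theta=theta,
        quantile=quantile,
        threshold=threshold,
        outliers=out,
        mean_theta=float(np.mean(vals)),
    )


def pairwise_fst(g: GenotypeMatrix, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Symmetric population x population matrix of multi-locus theta (diagonal 0)."""
    names = sorted(groups)
    if len(names) < 2:
        raise FstError("pairwise F_ST needs >= 2 populations")
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            v = multilocus_theta(g, {a: groups[a], b: groups[b]})
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


@dataclass
class BootstrapReport:
    """Outlier recovery under random dropout of SNPs or samples."""

    mode: str
    drop_fraction: float
    iterations: int
    seed: int
    recovery: list[float]
    n_original_outliers: int

    @property
    def mean_recovery(self) -> float:
        return float(np.mean(self.recovery))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "drop_fraction": self.drop_fraction,
            "iterations": self.iterations,
            "seed": self.seed,
            "n_original_outliers": self.n_original_outliers,
            "mean_recovery": self.mean_recovery,
            "recovery": self.recovery,
        }


def bootstrap_outlier_recovery(
    g: GenotypeMatrix,
    groups: dict[str, list[str]],
    mode: str = "drop_snps",
    drop_fraction: float = 0.20,
    iterations: int = 100,
    quantile: float = 0.975,
    seed: int = 0,
) -> BootstrapReport:
    """Fraction of original scan outliers that stay outliers under dropout.

    ``drop_snps`` removes a uniform random fraction of SNPs per iteration and
    scores recovery among retained original outliers; ``drop_samples`` removes
    accessions stratified by group (at least one kept per group) and rescans
    the full SNP set.
    """
    if mode not in ("drop_snps", "drop_samples"):
        raise FstError(f"unknown bootstrap mode {mode!r}")
    if not 0 < drop_fraction < 1:
        raise FstError("drop_fraction must be in (0, 1)")
    base = fst_scan(g, groups, quantile)
    original = set(base.outliers)
    rng = np.random.default_rng(seed)
    recovery: list[float] = []
    for _ in range(iterations):
        if mode == "drop_snps":
            n_drop = int(round(drop_fraction * g.n_snps))
            dropped = set(rng.choice(g.n_snps, size=n_drop, replace=False))
            keep = [s for j, s in enumerate(g.snp_ids) if j not in dropped]
            scan = fst_scan(g.subset(snps=keep), groups, quantile)
            eligible = original & set(keep)
        else:
            sub_groups = {}
            for name, members in groups.items():
                n_drop = int(round(drop_fraction * len(members)))
                n_drop = min(n_drop, len(members) - 1)  # never empty a group
                dropped = set(rng.choice(len(members), size=n_drop, replace=False))
                sub_groups[name] = [m for i, m in enumerate(members) if i not in dropped]
            keep_acc = [a for ms in sub_groups.values() for a in ms]
            scan = fst_scan(g.subset(accessions=keep_acc), sub_groups, quantile)
            eligible = original
        if not eligible:
            recovery.append(1.0)
            continue
        recovered = eligible & set(scan.outliers)
        recovery.append(len(recovered) / len(eligible))
    return BootstrapReport(
        mode=mode,
        drop_fraction=drop_fraction,
        iterations=iterations,
        seed=seed,
        recovery=recovery,
        n_original_outliers=len(original),
    )
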