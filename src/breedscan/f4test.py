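"""Four-population test for gene flow with block-jackknife standard errors.

f4(A,B; C,D) is the mean over SNPs of (p_A - p_B)(p_C - p_D). A nonzero value
in all three distinct pairings of four populations is inconsistent with any
tree and indicates gene flow. Standard errors come from a delete-one
block jackknife over consecutive-SNP blocks in map order (blocks never span
linkage groups), robust to linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genodata import HOM_ALT, HOM_REF, GeneticMap, GenotypeMatrix

__all__ = ["F4Result", "MigrationVerdict", "f4_statistic", "f4_from_genotypes", "three_topologies", "test_migration"]


class F4Error(ValueError):
    pass


@dataclass
class F4Result:
    topology: tuple[str, str, str, str]
    f4: float
    se: float
    z: float
    p_value: float
    n_snps: int
    block_size: int

    def label(self) -> str:
        a, b, c, d = self.topology
        return f"({a},{b};{c},{d})"


@dataclass
class MigrationVerdict:
    quadruple: tuple[str, str, str, str]
    results: list[F4Result]
    alpha: float
    verdict: str  # gene_flow | no_gene_flow

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "quadruple": ",".join(self.quadruple),
                "topology": r.label(),
                "f4": r.f4,
                "se": r.se,
                "z": r.z,
                "p": r.p_value,
                "verdict": self.verdict,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def _block_bounds(n_snps: int, block_size: int, group_labels=None) -> list[tuple[int, int]]:
    """Consecutive-SNP blocks of ~block_size that never span linkage groups."""
    if group_labels is None:
        group_labels = ["_"] * n_snps
    bounds = []
    start = 0
    for i in range(1, n_snps + 1):
        if i == n_snps or group_labels[i] != group_labels[start]:
            for s in range(start, i, block_size):
                bounds.append((s, min(s + block_size, i)))
            start = i
    return bounds


def f4_statistic(
    freqs: np.ndarray,
    names: tuple[str, str, str, str] = ("A", "B", "C", "D"),
    block_size: int = 75,
    group_labels=None,
) -> F4Result:
    """f4 with delete-one block-jackknife SE from per-SNP frequencies.

    ``freqs`` is (n_snps, 4) with columns in topology order (A, B; C, D); SNPs
    containing NaN in any column are dropped. The jackknife uses the weighted
    delete-m_j form, so unequal trailing blocks are handled exactly.
    """
    freqs = np.asarray(freqs, dtype=float)
    ok = ~np.isnan(freqs).any(axis=1)
    if group_labels is not None:
        group_labels = [g for g, k in zip(group_labels, ok) if k]
    freqs = freqs[ok]
    n = freqs.shape[0]
    terms = (freqs[:, 0] - freqs[:, 1]) * (freqs[:, 2] - freqs[:, 3])
    bounds = _block_bounds(n, block_size, group_labels)
    gblocks = len(bounds)
    if gblocks < 2:
        raise F4Error("need >= 2 jackknife blocks")
    est = float(terms.mean())
    total = terms.sum()
    block_sums = np.array([terms[s:e].sum() for s, e in bounds])
    block_m = np.array([e - s for s, e in bounds], dtype=float)
    loo = (total - block_sums) / (n - block_m)  # leave-one-block-out estimates
    h = n / block_m
    theta_j = gblocks * est - ((1.0 - block_m / n) * loo).sum()
    tau = h * est - (h - 1.0) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / gblocks
    se = float(np.sqrt(var))
    z = est / se if se > 0 else (0.0 if est == 0 else np.inf * np.sign(est))
    p = float(2.0 * norm.sf(abs(z)))
    return F4Result(
        topology=tuple(names), f4=est, se=se, z=float(z), p_value=p, n_snps=n, block_size=block_size
    )


def _haploid_freqs(g: GenotypeMatrix, groups: dict[str, list[str]], names) -> np.ndarray:
    cols = []
    for name in names:
        rows = g.accession_index(groups[name])
        sub = g.calls[rows]
        ref = np.sum(sub == HOM_REF, axis=0).astype(float)
        alt = np.sum(sub == HOM_ALT, axis=0).astype(float)
        n = ref + alt
        with np.errstate(invalid="ignore"):
            cols.append(np.where(n > 0, alt / np.maximum(n, 1), np.nan))
    return np.stack(cols, axis=1)


def f4_from_genotypes(
    g: GenotypeMatrix,
    groups: dict[str, list[str]],
    topology: tuple[str, str, str, str],
    gmap: GeneticMap | None = None,
    block_size: int = 75,
) -> F4Result:
    """f4 for a named topology from genotype data (haploid-coded frequencies)."""
    if len(set(topology)) != 4:
        raise F4Error("topology populations must be distinct")
    labels = None
    if gmap is not None:
        gmap = gmap.aligned_to(g.snp_ids)
        g = g.subset(snps=gmap.snp_ids)
        labels = gmap.linkage_groups
    freqs = _haploid_freqs(g, groups, topology)
    return f4_statistic(freqs, names=topology, block_size=block_size, group_labels=labels)


def three_topologies(a, b, c, d) -> list[tuple]:
    """The three distinct unrooted pairings of four populations."""
    return [(a, b, c, d), (a, c, b, d), (a, d, b, c)]


def test_migration(
    g: GenotypeMatrix,
    groups: dict[str, list[str]],
    quadruple: tuple[str, str, str, str],
    gmap: GeneticMap | None = None,
    block_size: int = 75,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> MigrationVerdict:
    """All-three-topologies migration rule for one quadruple.

    Gene flow is inferred only when every one of the three pairings deviates
    significantly from zero at ``alpha``; a single non-significant pairing
    means some tree fits the data. ``bonferroni`` divides alpha by the three
    tested pairings (off by default).
    """
    if len(set(quadruple)) != 4:
        raise F4Error("overlapping populations in quadruple")
    results = [
        f4_from_genotypes(g, groups, topo, gmap=gmap, block_size=block_size)
        for topo in three_topologies(*quadruple)
    ]
    level = alpha / 3 if bonferroni else alpha
    significant = all(r.p_value < level for r in results)
    return MigrationVerdict(
        quadruple=tuple(quadruple),
        results=results,
        alpha=alpha,
        verdict="gene_flow" if significant else "no_gene_flow",
    )


def iterate_migration_tests(
    g: GenotypeMatrix,
    groups: dict[str, list[str]],
    base_pairs: tuple[tuple[str, str], tuple[str, str]],
    substitutions: dict[str, list[str]] | None = None,
    gmap: GeneticMap | None = None,
    block_size: int = 75,
    alpha: float = 0.05,
) -> list[MigrationVerdict]:
    """Iterate the migration test over configured substitutions.

    ``base_pairs`` is ((A, B), (C, D)); any slot whose name appears in
    ``substitutions`` is replaced by each candidate in turn, skipping
    candidates that collide with the other three populations.
    """
    substitutions = substitutions or {}
    (a, b), (c, d) = base_pairs
    slots = [a, b, c, d]
    quads: list[tuple[str, str, str, str]] = []

    def expand(i, current):
        if i == 4:
            if len(set(current)) == 4:
                quads.append(tuple(current))
            return
        name = slots[i]
        for cand in substitutions.get(name, [name]):
            expand(i + 1, current + [cand])

    expand(0, [])
    return [
        test_migration(g, groups, q, gmap=gmap, block_size=block_size, alpha=alpha)
        for q in quads
    ]
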