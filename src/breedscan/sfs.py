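"""Outgroup polarization and derived site-frequency spectra.

Inbred accessions are haploid-coded: each homozygote contributes one
chromosome, heterozygous and missing calls are dropped per SNP. Spectra can be
projected down to a common sample size with the hypergeometric law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genodata import GenotypeMatrix

__all__ = [
    "POLARIZED",
    "AMBIGUOUS",
    "TRANS_SPECIFIC",
    "OTHER_ALLELE",
    "AncestralStates",
    "SfsResult",
    "polarize",
    "derived_counts",
    "derived_sfs",
    "joint_derived_sfs",
    "neutral_equilibrium_sfs",
    "fold_sfs",
]

POLARIZED = "polarized"
AMBIGUOUS = "ambiguous"
TRANS_SPECIFIC = "trans_specific"
OTHER_ALLELE = "other_allele"

_NUCLEOTIDES = frozenset("ACGT")


class SfsError(ValueError):
    pass


@dataclass
class AncestralStates:
    """Per-SNP outgroup allele ('A'..'T', 'A/G' for a segregating outgroup, or None)."""

    outgroup_allele: dict[str, str | None]

    @classmethod
    def read_tsv(cls, path) -> "AncestralStates":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        out = {}
        for sid, allele in zip(df["snp_id"], df["outgroup_allele"]):
            out[str(sid)] = None if allele in ("", "NA", "N") else allele
        return cls(out)

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "snp_id": list(self.outgroup_allele),
                "outgroup_allele": [a if a is not None else "NA" for a in self.outgroup_allele.values()],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class Polarization:
    """Per-SNP polarization outcome: derived allele state index and status."""

    snp_ids: list[str]
    status: list[str]
    derived_state: np.ndarray  # 1 if ALT is derived, 0 if REF is derived, -1 excluded

    def exclusion_counts(self) -> dict[str, int]:
        out = {AMBIGUOUS: 0, TRANS_SPECIFIC: 0, OTHER_ALLELE: 0}
        for s in self.status:
            if s in out:
                out[s] += 1
        return out


def polarize(g: GenotypeMatrix, anc: AncestralStates) -> Polarization:
    """Assign the derived allele per SNP from the outgroup state.

    The derived allele is the ingroup allele not matching the outgroup allele.
    SNPs with an ambiguous outgroup call, an outgroup segregating for both
    ingroup alleles (trans-specific), or an outgroup allele absent from the
    ingroup pair are excluded.
    """
    status: list[str] = []
    derived = np.full(g.n_snps, -1, dtype=np.int8)
    for j, sid in enumerate(g.snp_ids):
        out = anc.outgroup_allele.get(sid)
        ref, alt = g.alleles[j]
        if out is None or out not in _NUCLEOTIDES and "/" not in out:
            status.append(AMBIGUOUS)
            continue
        if "/" in out:
            parts = set(out.split("/"))
            if parts == {ref, alt}:
                status.append(TRANS_SPECIFIC)
            else:
                status.append(OTHER_ALLELE)
            continue
        if out == ref:
            derived[j] = 1
            status.append(POLARIZED)
        elif out == alt:
            derived[j] = 0
            status.append(POLARIZED)
        else:
            status.append(OTHER_ALLELE)
    return Polarization(snp_ids=list(g.snp_ids), status=status, derived_state=derived)


@dataclass
class SfsResult:
    """1-D or joint derived spectrum.

    For 1-D spectra ``counts[i]`` holds the weight of derived-count bin i for
    i in 0..n (bins 0 and n are the fixed classes, reported separately by
    :meth:`proportions`). For joint spectra ``counts[i, j]`` spans the
    (nA+1) x (nB+1) grid.
    """

    projection_n: int | tuple[int, int]
    counts: np.ndarray

    def proportions(self) -> np.ndarray:
        """Polymorphic-bin proportions (1..n-1), summing to 1."""
        poly = self.counts[1:-1]
        total = poly.sum()
        if total == 0:
            raise SfsError("no mass in polymorphic bins")
        return poly / total

    def to_frame(self) -> pd.DataFrame:
        if self.counts.ndim == 1:
            return pd.DataFrame(
                {"derived_count": np.arange(len(self.counts)), "weight": self.counts}
            )
        idx = [f"A{i}" for i in range(self.counts.shape[0])]
        cols = [f"B{j}" for j in range(self.counts.shape[1])]
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def derived_counts(
    g: GenotypeMatrix, members, pol: Polarization
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (derived haploid count, haploid sample size); -1 count where excluded."""
    from .genodata import HOM_ALT, HOM_REF

    rows = g.accession_index(members)
    sub = g.calls[rows]
    alt = np.sum(sub == HOM_ALT, axis=0)
    ref = np.sum(sub == HOM_REF, axis=0)
    n = (alt + ref).astype(int)
    der = np.where(pol.derived_state == 1, alt, ref).astype(int)
    der[pol.derived_state < 0] = -1
    return der, n


def _project_weights(k: int, n: int, m: int) -> np.ndarray:
    """Hypergeometric weights over derived counts 0..m when sampling m of n chromosomes."""
    return hypergeom.pmf(np.arange(m + 1), n, k, m)


def derived_sfs(
    g: GenotypeMatrix,
    members,
    anc: AncestralStates,
    projection_n: int | None = None,
    project: bool = True,
) -> SfsResult:
    """Derived SFS over polarized SNPs, optionally down-projected to ``projection_n``.

    Without projection, only SNPs whose haploid sample size equals
    ``projection_n`` (default: the maximum observed) contribute. With
    projection, each SNP with n >= projection_n contributes its hypergeometric
    bin weights.
    """
    pol = polarize(g, anc)
    der, n = derived_counts(g, members, pol)
    usable = (pol.derived_state >= 0) & (n >= 2)
    if not usable.any():
        raise SfsError("no polarized SNPs with data")
    if projection_n is None:
        projection_n = int(n[usable].max())
    m = int(projection_n)
    counts = np.zeros(m + 1)
    for k, nn in zip(der[usable], n[usable]):
        if nn < m:
            continue
        if nn == m:
            counts[k] += 1.0
        elif project:
            counts += _project_weights(int(k), int(nn), m)
    if counts[1:-1].sum() == 0:
        raise SfsError("no polarized polymorphic SNPs after projection")
    return SfsResult(projection_n=m, counts=counts)


def joint_derived_sfs(
    g: GenotypeMatrix,
    members_a,
    members_b,
    anc: AncestralStates,
    n_a: int | None = None,
    n_b: int | None = None,
    project: bool = True,
) -> SfsResult:
    """Joint (2-D) derived SFS over SNPs polarized and with data in both partitions."""
    if set(members_a) & set(members_b):
        raise SfsError("partitions must be disjoint")
    if not members_a or not members_b:
        raise SfsError("empty partition")
    pol = polarize(g, anc)
    der_a, na = derived_counts(g, members_a, pol)
    der_b, nb = derived_counts(g, members_b, pol)
    usable = (pol.derived_state >= 0) & (na >= 1) & (nb >= 1)
    if not usable.any():
        raise SfsError("no polarized SNPs with data in both partitions")
    if n_a is None:
        n_a = int(na[usable].max())
    if n_b is None:
        n_b = int(nb[usable].max())
    counts = np.zeros((n_a + 1, n_b + 1))
    for ka, nna, kb, nnb in zip(der_a[usable], na[usable], der_b[usable], nb[usable]):
        if nna < n_a or nnb < n_b:
            continue
        wa = _project_weights(int(ka), int(nna), n_a) if (project and nna > n_a) else None
        wb = _project_weights(int(kb), int(nnb), n_b) if (project and nnb > n_b) else None
        if wa is None and nna != n_a:
            continue
        if wb is None and nnb != n_b:
            continue
        va = wa if wa is not None else np.eye(n_a + 1)[int(ka)]
        vb = wb if wb is not None else np.eye(n_b + 1)[int(kb)]
        counts += np.outer(va, vb)
    return SfsResult(projection_n=(n_a, n_b), counts=counts)


def neutral_equilibrium_sfs(n: int) -> np.ndarray:
    """Equilibrium-neutral expected proportions over derived counts 1..n-1 (~1/i)."""
    if n < 2:
        raise SfsError("n must be >= 2")
    i = np.arange(1, n)
    w = 1.0 / i
    return w / w.sum()


def fold_sfs(proportions: np.ndarray) -> np.ndarray:
    """Fold polymorphic-bin weights (length n-1) into minor-allele bins 1..floor(n/2)."""
    p = np.asarray(proportions, dtype=float)
    n = len(p) + 1
    folded = np.zeros(n // 2)
    for i in range(1, n):
        j = min(i, n - i)
        folded[j - 1] += p[i - 1] if 2 * i != n else 0.0
    if n % 2 == 0:
        folded[n // 2 - 1] += p[n // 2 - 1]
    return folded
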