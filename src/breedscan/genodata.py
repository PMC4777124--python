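"""Core data model, file I/O and quality-control filters.

Genotype calls for inbred accessions are stored as a dense int8 matrix with
four states (:data:`HOM_REF`, :data:`HOM_ALT`, :data:`HET`, :data:`MISSING`).
Readers are provided for diploid VCF and for a tab-delimited accession x SNP
matrix of two-nucleotide diplotype calls ("AA", "AG", "NN", ...) as exported
by germplasm genotype databases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HOM_REF",
    "HOM_ALT",
    "HET",
    "MISSING",
    "GenotypeMatrix",
    "GeneticMap",
    "PopulationScheme",
    "QcReport",
    "read_genotypes",
    "write_matrix_tsv",
    "read_genetic_map",
    "write_genetic_map",
    "read_population_scheme",
    "write_population_scheme",
    "apply_qc",
    "selfing_het_expectation",
]

HOM_REF = np.int8(0)
HOM_ALT = np.int8(1)
HET = np.int8(2)
MISSING = np.int8(-1)

_VALID_STATES = frozenset({0, 1, 2, -1})
_NUCLEOTIDES = frozenset("ACGT")


class GenotypeDataError(ValueError):
    """Raised for malformed genotype input."""


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs call matrix with per-SNP allele labels.

    Parameters
    ----------
    accession_ids : list of str
        Unique accession identifiers (rows).
    snp_ids : list of str
        Unique SNP identifiers (columns), in map order.
    calls : ndarray of int8, shape (n_accessions, n_snps)
        Call states: 0 HOM_REF, 1 HOM_ALT, 2 HET, -1 MISSING.
    alleles : list of (str, str)
        Per-SNP (ref, alt) nucleotides; must be distinct.
    """

    accession_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    alleles: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise GenotypeDataError("duplicate accession ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise GenotypeDataError("duplicate SNP ids")
        if self.calls.shape != (len(self.accession_ids), len(self.snp_ids)):
            raise GenotypeDataError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.snp_ids)} SNPs"
            )
        if len(self.alleles) != len(self.snp_ids):
            raise GenotypeDataError("alleles list length does not match SNP count")
        bad = set(np.unique(self.calls)) - _VALID_STATES
        if bad:
            raise GenotypeDataError(f"invalid call states: {sorted(bad)}")
        for sid, (ref, alt) in zip(self.snp_ids, self.alleles):
            if ref == alt:
                raise GenotypeDataError(f"SNP {sid}: ref and alt alleles identical")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def accession_index(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown accession {e.args[0]!r}") from None

    def snp_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown SNP {e.args[0]!r}") from None

    def subset(self, accessions=None, snps=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the named accessions/SNPs (order kept)."""
        arow = self.accession_index(accessions) if accessions is not None else np.arange(self.n_accessions)
        acol = self.snp_index(snps) if snps is not None else np.arange(self.n_snps)
        return GenotypeMatrix(
            accession_ids=[self.accession_ids[i] for i in arow],
            snp_ids=[self.snp_ids[j] for j in acol],
            calls=self.calls[np.ix_(arow, acol)].copy(),
            alleles=[self.alleles[j] for j in acol],
        )

    def canonicalize(self) -> "GenotypeMatrix":
        """Recode allele orientation to the matrix_tsv reader's convention.

        The TSV dialect carries no ref/alt labels, so the reader orients each
        SNP deterministically (ref = alphabetically first nucleotide observed,
        padding unobserved alleles from 'ACGT'). Applying the same convention
        here makes write -> read round trips exact.
        """
        calls = self.calls.copy()
        alleles = list(self.alleles)
        for j, (ref, alt) in enumerate(self.alleles):
            col = calls[:, j]
            observed = set()
            if np.any((col == HOM_REF) | (col == HET)):
                observed.add(ref)
            if np.any((col == HOM_ALT) | (col == HET)):
                observed.add(alt)
            nucs = sorted(observed)
            while len(nucs) < 2:
                nucs.append(next(n for n in "ACGT" if n not in nucs))
                nucs.sort()
            new_ref, new_alt = nucs[0], nucs[1]
            if (new_ref, new_alt) == (ref, alt):
                continue
            if new_ref == alt or new_alt == ref:  # orientation swapped
                remap = np.array([MISSING, HOM_ALT, HOM_REF, HET], dtype=np.int8)
                calls[:, j] = remap[col + 1]
            # otherwise only the padded (unobserved) allele label changed
            alleles[j] = (new_ref, new_alt)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            snp_ids=list(self.snp_ids),
            calls=calls,
            alleles=alleles,
        )

    def haploid_codes(self, rows=None) -> np.ndarray:
        """Calls with HET recoded to MISSING: inbred haploid coding (0/1/-1)."""
        sub = self.calls if rows is None else self.calls[rows]
        out = sub.copy()
        out[out == HET] = MISSING
        return out


@dataclass
class GeneticMap:
    """Per-SNP linkage-group labels and cM positions, sorted by (group, cM)."""

    snp_ids: list[str]
    linkage_groups: list[str]
    positions_cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise GenotypeDataError("duplicate SNP ids in genetic map")
        if not (len(self.snp_ids) == len(self.linkage_groups) == len(self.positions_cm)):
            raise GenotypeDataError("genetic map column lengths differ")
        if np.any(self.positions_cm < 0):
            raise GenotypeDataError("negative cM position")
        prev_group, prev_pos = None, -np.inf
        seen = set()
        for g, p in zip(self.linkage_groups, self.positions_cm):
            if g != prev_group:
                if g in seen:
                    raise GenotypeDataError(f"linkage group {g} not contiguous")
                seen.add(g)
                prev_pos = -np.inf
            if p < prev_pos:
                raise GenotypeDataError(f"positions not sorted within group {g}")
            prev_group, prev_pos = g, p

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def group_slices(self) -> dict[str, slice]:
        """Contiguous index slice per linkage group, in map order."""
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, self.n_snps + 1):
            if i == self.n_snps or self.linkage_groups[i] != self.linkage_groups[start]:
                out[self.linkage_groups[start]] = slice(start, i)
                start = i
        return out

    def aligned_to(self, snp_ids) -> "GeneticMap":
        """Restrict to ``snp_ids``; every id must be present exactly once."""
        wanted = set(snp_ids)
        missing = wanted - set(self.snp_ids)
        if missing:
            raise GenotypeDataError(f"SNPs absent from map: {sorted(missing)[:5]}")
        keep = [i for i, s in enumerate(self.snp_ids) if s in wanted]
        return GeneticMap(
            snp_ids=[self.snp_ids[i] for i in keep],
            linkage_groups=[self.linkage_groups[i] for i in keep],
            positions_cm=self.positions_cm[keep],
        )


@dataclass
class PopulationScheme:
    """Accession -> population mapping plus per-population metadata."""

    assignments: dict[str, str]
    spike_type: dict[str, int] = field(default_factory=dict)
    growth_habit: dict[str, str] = field(default_factory=dict)
    program: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, st in self.spike_type.items():
            if st not in (2, 6):
                raise GenotypeDataError(f"population {pop}: spike type must be 2 or 6")
        for pop, gh in self.growth_habit.items():
            if gh not in ("spring", "winter"):
                raise GenotypeDataError(f"population {pop}: growth habit must be spring/winter")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def members(self, population: str) -> list[str]:
        return [a for a, p in self.assignments.items() if p == population]

    def restricted_to(self, accessions) -> "PopulationScheme":
        keep = set(accessions)
        return PopulationScheme(
            assignments={a: p for a, p in self.assignments.items() if a in keep},
            spike_type=dict(self.spike_type),
            growth_habit=dict(self.growth_habit),
            program=dict(self.program),
        )

    def partition(self, by: str) -> dict[str, list[str]]:
        """Group accessions by 'population', 'spike_type' or 'growth_habit'."""
        groups: dict[str, list[str]] = {}
        for acc, pop in self.assignments.items():
            if by == "population":
                key = pop
            elif by == "spike_type":
                key = str(self.spike_type[pop])
            elif by == "growth_habit":
                key = self.growth_habit[pop]
            else:
                raise ValueError(f"unknown partition {by!r}")
            groups.setdefault(key, []).append(acc)
        return groups


@dataclass
class QcReport:
    """Reason-tagged record of SNPs and accessions removed by :func:`apply_qc`."""

    removed_snps: dict[str, str]
    removed_accessions: dict[str, str]
    max_missing: float
    max_het: float
    strict_missing: bool = True

    def summary(self) -> dict:
        snp_reasons: dict[str, int] = {}
        for r in self.removed_snps.values():
            snp_reasons[r] = snp_reasons.get(r, 0) + 1
        acc_reasons: dict[str, int] = {}
        for r in self.removed_accessions.values():
            acc_reasons[r] = acc_reasons.get(r, 0) + 1
        return {
            "thresholds": {
                "max_missing": self.max_missing,
                "max_het": self.max_het,
                "strict_missing": self.strict_missing,
            },
            "n_snps_removed": len(self.removed_snps),
            "n_accessions_removed": len(self.removed_accessions),
            "snp_reasons": snp_reasons,
            "accession_reasons": acc_reasons,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"id": list(self.removed_snps), "reason": list(self.removed_snps.values())}
        ).to_csv(out / "removed_snps.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"id": list(self.removed_accessions), "reason": list(self.removed_accessions.values())}
        ).to_csv(out / "removed_accessions.tsv", sep="\t", index=False)
        (out / "qc_summary.json").write_text(json.dumps(self.summary(), indent=2))


# ---------------------------------------------------------------------------
# I/O


_MISSING_TOKENS = frozenset({"NN", "N", "--", "NA", ""})


def _read_matrix_tsv(path) -> GenotypeMatrix:
    # dialect convention: ref allele = alphabetically first nucleotide observed
    # at the SNP, so write -> read round trips are exact
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise GenotypeDataError(f"empty genotype matrix in {path}")
    accession_ids = [str(a) for a in df.index]
    snp_ids = [str(s) for s in df.columns]
    if len(set(accession_ids)) != len(accession_ids):
        raise GenotypeDataError("duplicate accession ids")
    calls = np.full(df.shape, MISSING, dtype=np.int8)
    alleles: list[tuple[str, str]] = []
    raw = df.to_numpy()
    for j, sid in enumerate(snp_ids):
        col = [str(raw[i, j]).strip().upper() for i in range(len(accession_ids))]
        observed: set[str] = set()
        for token in col:
            if token in _MISSING_TOKENS:
                continue
            if len(token) != 2 or any(ch not in _NUCLEOTIDES for ch in token):
                raise GenotypeDataError(f"SNP {sid}: unknown call token {token!r}")
            observed.update(token)
        if len(observed) > 2:
            raise GenotypeDataError(f"SNP {sid}: more than 2 alleles observed")
        nucs = sorted(observed)
        while len(nucs) < 2:  # pad so (ref, alt) stays a distinct pair
            nucs.append(next(n for n in "ACGT" if n not in nucs))
            nucs.sort()
        ref, alt = nucs[0], nucs[1]
        state = {
            ref + ref: int(HOM_REF),
            alt + alt: int(HOM_ALT),
            ref + alt: int(HET),
            alt + ref: int(HET),
        }
        for i, token in enumerate(col):
            if token not in _MISSING_TOKENS:
                calls[i, j] = state[token]
        alleles.append((ref, alt))
    return GenotypeMatrix(accession_ids, snp_ids, calls, alleles)


def _read_vcf(path) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        accession_ids = list(vcf.header.samples)
        snp_ids, alleles, rows = [], [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise GenotypeDataError(f"SNP {rec.id}: expected exactly one ALT allele")
            snp_ids.append(rec.id if rec.id else f"{rec.chrom}:{rec.pos}")
            alleles.append((rec.ref, rec.alts[0]))
            row = np.full(len(accession_ids), MISSING, dtype=np.int8)
            for i, sample in enumerate(accession_ids):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                s = sum(gt)
                if len(gt) != 2 or not all(a in (0, 1) for a in gt):
                    raise GenotypeDataError(f"SNP {snp_ids[-1]}: unsupported genotype {gt}")
                row[i] = HOM_REF if s == 0 else (HOM_ALT if s == 2 else HET)
            rows.append(row)
    if not snp_ids:
        raise GenotypeDataError(f"no variant records in {path}")
    return GenotypeMatrix(accession_ids, snp_ids, np.array(rows, dtype=np.int8).T, alleles)


def read_genotypes(path, format: str = "matrix_tsv") -> GenotypeMatrix:
    """Read genotypes from ``matrix_tsv`` (diplotype tokens) or ``vcf`` (diploid GT)."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise GenotypeDataError(f"empty or missing genotype file: {path}")
    if format == "matrix_tsv":
        return _read_matrix_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


_STATE_TO_PAIR = {int(HOM_REF): (0, 0), int(HOM_ALT): (1, 1), int(HET): (0, 1)}


def write_matrix_tsv(g: GenotypeMatrix, path) -> None:
    """Write the diplotype-token TSV dialect read by :func:`read_genotypes`."""
    tokens = np.empty((g.n_accessions, g.n_snps), dtype=object)
    for j, (ref, alt) in enumerate(g.alleles):
        col = g.calls[:, j]
        mapped = np.array(["NN", ref + ref, alt + alt, ref + alt], dtype=object)
        tokens[:, j] = mapped[col + 1]  # -1,0,1,2 -> 0,1,2,3
    pd.DataFrame(tokens, index=g.accession_ids, columns=g.snp_ids).to_csv(
        path, sep="\t", index_label="accession"
    )


def write_vcf(g: GenotypeMatrix, gmap: GeneticMap, path) -> None:
    """Write a minimal diploid VCF (cM positions scaled to integer POS)."""
    gmap = gmap.aligned_to(g.snp_ids)
    order = g.snp_index(gmap.snp_ids)
    gt_tok = {int(HOM_REF): "0/0", int(HOM_ALT): "1/1", int(HET): "0/1", int(MISSING): "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for grp in dict.fromkeys(gmap.linkage_groups):
            fh.write(f"##contig=<ID={grp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.accession_ids)
            + "\n"
        )
        for k, j in enumerate(order):
            ref, alt = g.alleles[j]
            pos = int(round(gmap.positions_cm[k] * 10000)) + 1
            calls = "\t".join(gt_tok[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{gmap.linkage_groups[k]}\t{pos}\t{g.snp_ids[j]}\t{ref}\t{alt}"
                f"\t.\t.\t.\tGT\t{calls}\n"
            )


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "linkage_group": str})
    df = df.sort_values(["linkage_group", "cM"], kind="stable")
    return GeneticMap(
        snp_ids=df["snp_id"].tolist(),
        linkage_groups=df["linkage_group"].tolist(),
        positions_cm=df["cM"].to_numpy(dtype=float),
    )


def write_genetic_map(gmap: GeneticMap, path) -> None:
    pd.DataFrame(
        {"snp_id": gmap.snp_ids, "linkage_group": gmap.linkage_groups, "cM": gmap.positions_cm}
    ).to_csv(path, sep="\t", index=False)


def read_population_scheme(path) -> PopulationScheme:
    df = pd.read_csv(path, sep="\t", dtype=str)
    assignments = dict(zip(df["accession"], df["population"]))
    spike, habit = {}, {}
    if "spike_type" in df.columns:
        for pop, st in zip(df["population"], df["spike_type"]):
            spike[pop] = int(st)
    if "growth_habit" in df.columns:
        for pop, gh in zip(df["population"], df["growth_habit"]):
            habit[pop] = gh
    return PopulationScheme(assignments=assignments, spike_type=spike, growth_habit=habit)


def write_population_scheme(scheme: PopulationScheme, path) -> None:
    rows = [
        {
            "accession": acc,
            "population": pop,
            "spike_type": scheme.spike_type.get(pop, ""),
            "growth_habit": scheme.growth_habit.get(pop, ""),
        }
        for acc, pop in scheme.assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC


def _is_monomorphic(col: np.ndarray) -> bool:
    # monomorphic = fewer than two distinct homozygous states among
    # non-missing, non-heterozygous calls
    hom = col[(col == HOM_REF) | (col == HOM_ALT)]
    return np.unique(hom).size < 2


def apply_qc(
    g: GenotypeMatrix,
    scheme: PopulationScheme | None = None,
    max_missing: float = 0.25,
    max_het: float = 0.0625,
    strict_missing: bool = True,
    exclude_accessions=(),
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the quality-control filters in a fixed, documented order.

    Order of removal: (1) curated exclusion list, (2) monomorphic SNPs,
    (3) SNPs above the missingness threshold, (4) accessions above the
    missingness threshold, (5) accessions above the heterozygosity threshold
    (fraction of heterozygous calls among non-missing calls), (6) accessions
    whose population retains fewer than 2 members. The pass sequence is
    repeated until no further removal occurs, so the filter is idempotent
    (dropping accessions can render further SNPs monomorphic).

    ``strict_missing`` selects between the strict ``> max_missing`` rule and
    the inclusive ``>= max_missing`` reading.
    """
    if not (0 <= max_missing <= 1 and 0 <= max_het <= 1):
        raise ValueError("thresholds must lie in [0, 1]")

    removed_snps: dict[str, str] = {}
    removed_accessions: dict[str, str] = {}

    def exceeds(frac: float) -> bool:
        return frac > max_missing if strict_missing else frac >= max_missing

    for acc in exclude_accessions:
        if acc in g.accession_ids:
            removed_accessions[acc] = "curated_exclusion"
    keep_acc = [a for a in g.accession_ids if a not in removed_accessions]
    work = g.subset(accessions=keep_acc) if removed_accessions else g

    while True:
        n_removed_before = len(removed_snps) + len(removed_accessions)

        for j, sid in enumerate(work.snp_ids):
            if _is_monomorphic(work.calls[:, j]):
                removed_snps[sid] = "monomorphic"
        keep = [s for s in work.snp_ids if s not in removed_snps]
        work = work.subset(snps=keep)

        if work.n_snps:
            miss_frac = np.mean(work.calls == MISSING, axis=0)
            for j, sid in enumerate(work.snp_ids):
                if exceeds(miss_frac[j]):
                    removed_snps[sid] = "missing"
            keep = [s for s in work.snp_ids if s not in removed_snps]
            work = work.subset(snps=keep)
        if work.n_snps == 0:
            raise GenotypeDataError("QC removed all SNPs")

        miss_frac = np.mean(work.calls == MISSING, axis=1)
        for i, acc in enumerate(work.accession_ids):
            if exceeds(miss_frac[i]):
                removed_accessions[acc] = "missing"
        keep_acc = [a for a in work.accession_ids if a not in removed_accessions]
        work = work.subset(accessions=keep_acc)

        if work.n_accessions:
            nonmiss = np.sum(work.calls != MISSING, axis=1)
            het = np.sum(work.calls == HET, axis=1)
            with np.errstate(invalid="ignore"):
                het_frac = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), 0.0)
            for i, acc in enumerate(work.accession_ids):
                if het_frac[i] > max_het:
                    removed_accessions[acc] = "heterozygosity"
            keep_acc = [a for a in work.accession_ids if a not in removed_accessions]
            work = work.subset(accessions=keep_acc)

        if scheme is not None:
            counts: dict[str, int] = {}
            for acc in work.accession_ids:
                pop = scheme.assignments.get(acc)
                if pop is not None:
                    counts[pop] = counts.get(pop, 0) + 1
            for acc in work.accession_ids:
                pop = scheme.assignments.get(acc)
                if pop is None or counts[pop] < 2:
                    removed_accessions[acc] = "population_too_small"
            keep_acc = [a for a in work.accession_ids if a not in removed_accessions]
            work = work.subset(accessions=keep_acc)

        if work.n_accessions == 0:
            raise GenotypeDataError("QC removed all accessions")
        if len(removed_snps) + len(removed_accessions) == n_removed_before:
            break

    report = QcReport(
        removed_snps=removed_snps,
        removed_accessions=removed_accessions,
        max_missing=max_missing,
        max_het=max_het,
        strict_missing=strict_missing,
    )
    return work, report


def selfing_het_expectation(generations: int) -> float:
    """Expected heterozygous fraction after ``generations`` rounds of selfing.

    Starting from a fully heterozygous individual every locus stays
    heterozygous with probability 1/2 per generation, so the expectation is
    (1/2)**generations (0.0625 after four generations).
    """
    if generations < 0 or int(generations) != generations:
        raise ValueError("generations must be a non-negative integer")
    return 0.5 ** int(generations)
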