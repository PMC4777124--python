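"""Synthetic genotype data for hierarchically structured, selfed breeding
germplasm, with exact machine-readable ground truth.

The generator draws ancestral frequencies, applies two-stage hierarchical
drift (growth-habit/spike-type level, then population level), builds founder
haplotypes at linkage equilibrium, implants selective sweeps (long shared
homozygous haplotypes) and migrant chromosome segments, and produces residual
heterozygosity by selfing each accession from a heterozygous founder cross.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genodata import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    PopulationScheme,
    write_genetic_map,
    write_matrix_tsv,
    write_population_scheme,
    write_vcf,
)
from .sfs import AncestralStates

__all__ = [
    "PopulationSpec",
    "SweepSpec",
    "MigrationSpec",
    "SimConfig",
    "SimTruth",
    "simulate",
    "emulate_paper_shape",
    "write_bundle",
]


class SimError(ValueError):
    pass


@dataclass
class PopulationSpec:
    name: str
    spike_type: int
    growth_habit: str
    n_accessions: int
    c_pop: float  # drift of the population from its type-level frequencies


@dataclass
class SweepSpec:
    population: str
    linkage_group: str
    center_cm: float
    length_cm: float
    frequency: float  # carrier fraction among accessions
    # probability that the implanted haplotype takes the minor allele at each
    # site; > 0 makes the swept haplotype distinctive against the background,
    # as a recently selected haplotype is
    minor_bias: float = 0.0
    # when set, the sweep emulates selection on a haplotype novel to the
    # population (e.g. introduced by a cross): background frequencies of the
    # swept alleles at core sites are re-drawn uniformly below this value
    novel_freq: float | None = None


@dataclass
class MigrationSpec:
    donor: str
    recipient: str
    linkage_group: str
    start_cm: float
    end_cm: float
    frequency: float  # recipient carrier fraction


@dataclass
class SimConfig:
    populations: list[PopulationSpec]
    snps_per_group: dict[str, int]
    map_length_cm: dict[str, float]
    c_habit: float = 0.1
    c_spike: float = 0.1
    selfing_generations: int = 4
    ancestral_beta: tuple[float, float] = (1.4, 1.4)
    missing_rate: float = 0.02
    drift_law: str = "beta"  # beta | censored_normal
    sweeps: list[SweepSpec] = field(default_factory=list)
    migrations: list[MigrationSpec] = field(default_factory=list)
    outgroup_flip_rate: float = 0.02
    outgroup_ambiguous_rate: float = 0.03
    outgroup_trans_rate: float = 0.02
    outgroup_other_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise SimError("duplicate population names")
        for p in self.populations:
            if not 0 <= p.c_pop < 1:
                raise SimError(f"{p.name}: c_pop must be in [0, 1)")
        for sw in self.sweeps + self.migrations:
            if not 0 < sw.frequency <= 1:
                raise SimError("sweep/migration frequency must be in (0, 1]")
        for sw in self.sweeps:
            if sw.linkage_group not in self.map_length_cm:
                raise SimError(f"sweep on unknown linkage group {sw.linkage_group}")
            lo, hi = sw.center_cm - sw.length_cm / 2, sw.center_cm + sw.length_cm / 2
            if lo < 0 or hi > self.map_length_cm[sw.linkage_group]:
                raise SimError(f"sweep on {sw.linkage_group} exceeds map bounds")
        for mg in self.migrations:
            if mg.linkage_group not in self.map_length_cm:
                raise SimError(f"migration on unknown linkage group {mg.linkage_group}")
            if not 0 <= mg.start_cm < mg.end_cm <= self.map_length_cm[mg.linkage_group]:
                raise SimError("migration segment outside map bounds")
        by_pop: dict[tuple, list] = {}
        for sw in self.sweeps:
            by_pop.setdefault((sw.population, sw.linkage_group), []).append(sw)
        for specs in by_pop.values():
            specs = sorted(specs, key=lambda s: s.center_cm)
            for a, b in zip(specs, specs[1:]):
                if a.center_cm + a.length_cm / 2 > b.center_cm - b.length_cm / 2:
                    raise SimError("overlapping sweeps in the same population")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ancestral_beta"] = list(self.ancestral_beta)
        return d


@dataclass
class SimTruth:
    """Exact record of everything the generator realized."""

    ancestral_freq: np.ndarray
    type_freq: dict[str, np.ndarray]
    population_freq: dict[str, np.ndarray]
    realized_drift_total: dict[str, float]  # vs ancestral
    realized_drift_pop: dict[str, float]  # vs own type-level frequencies
    sweep_carriers: list[dict]
    migrant_carriers: list[dict]
    ancestral_allele_index: np.ndarray  # 0 ref / 1 alt, before outgroup noise

    def to_json_dict(self) -> dict:
        return {
            "ancestral_freq": self.ancestral_freq.tolist(),
            "type_freq": {k: v.tolist() for k, v in self.type_freq.items()},
            "population_freq": {k: v.tolist() for k, v in self.population_freq.items()},
            "realized_drift_total": self.realized_drift_total,
            "realized_drift_pop": self.realized_drift_pop,
            "sweep_carriers": self.sweep_carriers,
            "migrant_carriers": self.migrant_carriers,
            "ancestral_allele_index": self.ancestral_allele_index.tolist(),
        }


def _drift(p: np.ndarray, c: float, rng: np.random.Generator, law: str) -> np.ndarray:
    """One stage of allele-frequency drift at magnitude c from frequencies p."""
    if c <= 0:
        return p.copy()
    if law == "beta":
        a = p * (1.0 - c) / c
        b = (1.0 - p) * (1.0 - c) / c
        out = rng.beta(np.maximum(a, 1e-8), np.maximum(b, 1e-8))
    elif law == "censored_normal":
        out = np.clip(rng.normal(p, np.sqrt(c * p * (1.0 - p))), 0.0, 1.0)
    else:
        raise SimError(f"unknown drift law {law!r}")
    return out


# ref is always 'A' so the matrix_tsv reader's alphabetical orientation
# matches the simulated one even at SNPs where only one allele is observed
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T")]


def simulate(config: SimConfig):
    """Run the generator.

    Returns (GenotypeMatrix, GeneticMap, PopulationScheme, AncestralStates,
    SimTruth). Bit-identical for the same config (seed included).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- genetic map ---
    snp_ids: list[str] = []
    groups: list[str] = []
    pos_all: list[float] = []
    for grp in sorted(config.snps_per_group):
        m = config.snps_per_group[grp]
        pos = np.sort(rng.uniform(0.0, config.map_length_cm[grp], size=m))
        for k in range(m):
            snp_ids.append(f"{grp}_{k:05d}")
        groups.extend([grp] * m)
        pos_all.extend(pos.tolist())
    gmap = GeneticMap(snp_ids=snp_ids, linkage_groups=groups, positions_cm=np.array(pos_all))
    S = gmap.n_snps
    alleles = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=S)]

    # --- hierarchical frequencies ---
    a0, b0 = config.ancestral_beta
    pi = np.clip(rng.beta(a0, b0, size=S), 0.02, 0.98)
    # spike-type drift is the outer stage (shared across growth habits), so
    # pooling habits leaves the spike signal intact while habit-level noise
    # partially cancels -- matching the observed ordering of partition thetas
    spike_freq: dict[int, np.ndarray] = {}
    for spike in sorted({p.spike_type for p in config.populations}):
        spike_freq[spike] = _drift(pi, config.c_spike, rng, config.drift_law)
    type_freq: dict[str, np.ndarray] = {}
    for habit, spike in sorted({(p.growth_habit, p.spike_type) for p in config.populations}):
        type_freq[f"{habit}_{spike}"] = _drift(
            spike_freq[spike], config.c_habit, rng, config.drift_law
        )
    pop_freq: dict[str, np.ndarray] = {}
    for p in config.populations:
        pop_freq[p.name] = _drift(
            type_freq[f"{p.growth_habit}_{p.spike_type}"], p.c_pop, rng, config.drift_law
        )

    # --- founder haplotypes (linkage-equilibrium background) ---
    h1: dict[str, np.ndarray] = {}
    h2: dict[str, np.ndarray] = {}
    acc_names: dict[str, list[str]] = {}
    for p in config.populations:
        f = pop_freq[p.name]
        h1[p.name] = (rng.random((p.n_accessions, S)) < f).astype(np.int8)
        h2[p.name] = (rng.random((p.n_accessions, S)) < f).astype(np.int8)
        acc_names[p.name] = [f"{p.name}_{i:04d}" for i in range(p.n_accessions)]

    slice_of = gmap.group_slices()
    pos_arr = gmap.positions_cm

    def segment_cols(group: str, lo: float, hi: float) -> np.ndarray:
        sl = slice_of[group]
        local = np.flatnonzero((pos_arr[sl] >= lo) & (pos_arr[sl] <= hi))
        return local + sl.start

    # --- implant sweeps: one founder haplotype copied into both chromosomes ---
    sweep_truth: list[dict] = []
    for sw in config.sweeps:
        cols = segment_cols(sw.linkage_group, sw.center_cm - sw.length_cm / 2, sw.center_cm + sw.length_cm / 2)
        n_acc = len(acc_names[sw.population])
        n_car = max(int(round(sw.frequency * n_acc)), 2)
        if n_car > n_acc:
            raise SimError("sweep frequency infeasible for population size")
        carriers = np.sort(rng.choice(n_acc, size=n_car, replace=False))
        f_seg = pop_freq[sw.population][cols]
        if sw.novel_freq is not None:
            # the swept haplotype is all-alt at core sites and those alleles
            # are rare in the background: re-draw background founders there
            bg = rng.uniform(0.01, sw.novel_freq, size=len(cols))
            pop_freq[sw.population][cols] = bg
            h1[sw.population][:, cols] = (rng.random((n_acc, len(cols))) < bg).astype(np.int8)
            h2[sw.population][:, cols] = (rng.random((n_acc, len(cols))) < bg).astype(np.int8)
            donor_hap = np.ones(len(cols), dtype=np.int8)
        else:
            donor_hap = (rng.random(len(cols)) < f_seg).astype(np.int8)
            if sw.minor_bias > 0:
                minor = (f_seg < 0.5).astype(np.int8)
                take_minor = rng.random(len(cols)) < sw.minor_bias
                donor_hap = np.where(take_minor, minor, donor_hap).astype(np.int8)
        for acc in carriers:
            h1[sw.population][acc, cols] = donor_hap
            h2[sw.population][acc, cols] = donor_hap
        sweep_truth.append(
            {
                "population": sw.population,
                "linkage_group": sw.linkage_group,
                "center_cm": sw.center_cm,
                "length_cm": sw.length_cm,
                "snp_cols": cols.tolist(),
                "carriers": [acc_names[sw.population][i] for i in carriers],
                "haplotype": donor_hap.tolist(),
            }
        )

    # --- selfing from the heterozygous founder cross ---
    g = config.selfing_generations
    p_het = 0.5**g
    pop_calls: dict[str, np.ndarray] = {}
    for p in config.populations:
        a, b = h1[p.name], h2[p.name]
        het0 = a != b
        stays_het = het0 & (rng.random(a.shape) < p_het)
        pick_b = rng.random(a.shape) < 0.5
        resolved = np.where(het0 & ~stays_het & pick_b, b, a)
        pop_calls[p.name] = np.where(
            stays_het, HET, np.where(resolved == 1, HOM_ALT, HOM_REF)
        ).astype(np.int8)

    # --- implant migrant segments: recipients inherit the donor line's
    # resolved (post-selfing) genotype over the segment ---
    migrant_truth: list[dict] = []
    for mg in config.migrations:
        cols = segment_cols(mg.linkage_group, mg.start_cm, mg.end_cm)
        n_acc = len(acc_names[mg.recipient])
        n_car = max(int(round(mg.frequency * n_acc)), 1)
        carriers = np.sort(rng.choice(n_acc, size=n_car, replace=False))
        donor_idx = int(rng.integers(0, len(acc_names[mg.donor])))
        donor_seg = pop_calls[mg.donor][donor_idx, cols].copy()
        for acc in carriers:
            pop_calls[mg.recipient][acc, cols] = donor_seg
        migrant_truth.append(
            {
                "donor": mg.donor,
                "recipient": mg.recipient,
                "linkage_group": mg.linkage_group,
                "start_cm": mg.start_cm,
                "end_cm": mg.end_cm,
                "snp_cols": cols.tolist(),
                "carriers": [acc_names[mg.recipient][i] for i in carriers],
                "donor_accession": acc_names[mg.donor][donor_idx],
                "segment_calls": donor_seg.tolist(),
            }
        )

    calls_rows: list[np.ndarray] = []
    all_names: list[str] = []
    assignments: dict[str, str] = {}
    for p in config.populations:
        calls = pop_calls[p.name]
        if config.missing_rate > 0:
            calls[rng.random(calls.shape) < config.missing_rate] = MISSING
        calls_rows.append(calls)
        all_names.extend(acc_names[p.name])
        for nm in acc_names[p.name]:
            assignments[nm] = p.name

    matrix = GenotypeMatrix(
        accession_ids=all_names,
        snp_ids=list(gmap.snp_ids),
        calls=np.vstack(calls_rows),
        alleles=alleles,
    ).canonicalize()
    scheme = PopulationScheme(
        assignments=assignments,
        spike_type={p.name: p.spike_type for p in config.populations},
        growth_habit={p.name: p.growth_habit for p in config.populations},
    )

    # --- outgroup states: ancestral-majority allele with configured noise ---
    anc_idx = (pi >= 0.5).astype(np.int8)  # 1 when the alt allele is ancestral
    u = rng.random(S)
    r_flip = config.outgroup_flip_rate
    r_amb = r_flip + config.outgroup_ambiguous_rate
    r_trans = r_amb + config.outgroup_trans_rate
    r_other = r_trans + config.outgroup_other_rate
    outgroup: dict[str, str | None] = {}
    for j, sid in enumerate(gmap.snp_ids):
        ref, alt = alleles[j]
        anc_allele = alt if anc_idx[j] == 1 else ref
        der_allele = ref if anc_idx[j] == 1 else alt
        if u[j] < r_flip:
            outgroup[sid] = der_allele
        elif u[j] < r_amb:
            outgroup[sid] = None
        elif u[j] < r_trans:
            outgroup[sid] = f"{ref}/{alt}"
        elif u[j] < r_other:
            outgroup[sid] = next(n for n in "ACGT" if n not in (ref, alt))
        else:
            outgroup[sid] = anc_allele
    anc = AncestralStates(outgroup_allele=outgroup)

    denom = pi * (1.0 - pi)
    truth = SimTruth(
        ancestral_freq=pi,
        type_freq=type_freq,
        population_freq=pop_freq,
        realized_drift_total={
            p.name: float(np.mean((pop_freq[p.name] - pi) ** 2 / denom))
            for p in config.populations
        },
        realized_drift_pop={
            p.name: float(
                np.mean(
                    (pop_freq[p.name] - type_freq[f"{p.growth_habit}_{p.spike_type}"]) ** 2
                    / np.maximum(
                        type_freq[f"{p.growth_habit}_{p.spike_type}"]
                        * (1 - type_freq[f"{p.growth_habit}_{p.spike_type}"]),
                        1e-12,
                    )
                )
            )
            for p in config.populations
        },
        sweep_carriers=sweep_truth,
        migrant_carriers=migrant_truth,
        ancestral_allele_index=anc_idx,
    )
    return matrix, gmap, scheme, anc, truth


# Drift settings calibrated so the realized haploid multi-locus thetas land
# near 0.17 (spring vs winter), 0.23 (two- vs six-rowed) and 0.37 (among
# populations) on the default preset.
_PRESET_C_HABIT = 0.30
_PRESET_C_SPIKE = 0.042
_PRESET_C_POP = 0.137


def emulate_paper_shape(seed: int = 0, scale: float = 1.0) -> SimConfig:
    """Preset: 16 populations in a 2x2 spike-type x growth-habit hierarchy,
    ~2,500 SNPs on 7 linkage groups of ~150 cM, four selfing generations.

    ``scale`` < 1 shrinks accession counts proportionally (minimum 10) for
    quick runs.
    """
    # cell totals follow a product form (habit share x spike share), so each
    # habit pool has the same spike composition and vice versa; this keeps the
    # two partition thetas separately tunable
    sizes_spring2 = [120, 90, 60, 45, 45]
    sizes_spring6 = [180, 120, 90, 90, 60]
    sizes_winter2 = [40, 40, 40]
    sizes_winter6 = [60, 60, 60]
    pops: list[PopulationSpec] = []

    def add(prefix, habit, spike, sizes):
        for k, n in enumerate(sizes):
            pops.append(
                PopulationSpec(
                    name=f"{prefix}{k + 1}",
                    spike_type=spike,
                    growth_habit=habit,
                    n_accessions=max(int(round(n * scale)), 10),
                    c_pop=_PRESET_C_POP,
                )
            )

    add("SP2_", "spring", 2, sizes_spring2)
    add("SP6_", "spring", 6, sizes_spring6)
    add("WI2_", "winter", 2, sizes_winter2)
    add("WI6_", "winter", 6, sizes_winter6)
    groups = {f"{i}H": 357 + (1 if i <= 1 else 0) for i in range(1, 8)}
    return SimConfig(
        populations=pops,
        snps_per_group=groups,
        map_length_cm={g: 150.0 for g in groups},
        c_habit=_PRESET_C_HABIT,
        c_spike=_PRESET_C_SPIKE,
        selfing_generations=4,
        seed=seed,
    )


def write_bundle(out_dir, matrix, gmap, scheme, anc, truth, config: SimConfig) -> None:
    """Emit the full text bundle: matrix TSV + VCF, map, populations, ancestral
    states, ground truth JSON and the config as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(matrix, out / "genotypes.tsv")
    write_vcf(matrix, gmap, out / "genotypes.vcf")
    write_genetic_map(gmap, out / "map.tsv")
    write_population_scheme(scheme, out / "populations.tsv")
    anc.write_tsv(out / "ancestral.tsv")
    (out / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=2))
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
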