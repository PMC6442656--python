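"""Synthetic multi-region tumour sequencing data with known ground truth.

Emulates the sampling design of a multi-region glioblastoma study: several
high-purity tumour-mass samples (T), a low-purity infiltrative-margin sample
(M, 5–10% tumour cells), a sub-ventricular-zone sample (SVZ, ~22% purity) and
a germline blood sample, sequenced by whole exome (~x157) plus two deep
targeted panels (~x4050 amplicon, ~x1128 capture). Clonal evolution is a
random rooted clone tree with Poisson mutation counts per edge; each sample
is a Dirichlet mixture of clones concentrated on a dominant clone; read
counts follow a beta-binomial around the purity/copy-number-expected VAF with
negative-binomial depths. The ``ancestral_margin`` scenario pins the margin's
dominant clone to an ancestor of every tumour-mass clone, so a slice of the
putative truncal mutations is genuinely absent from the margin — the
situation the absence test exists to detect.

All randomness flows from a single seeded generator; datasets are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    Assay,
    CopyNumberSegment,
    Observation,
    RegionClass,
    SampleMeta,
    Timepoint,
    VariantRecord,
    make_variant_id,
    write_cn_table,
    write_multisample_vcf,
    write_readcount_table,
    write_sample_sheet,
)

__all__ = [
    "DepthModel",
    "SampleSpec",
    "SimConfig",
    "CloneTruth",
    "SimulatedDataset",
    "default_design",
    "simulate_clone_tree",
    "compose_samples",
    "simulate_read_counts",
    "simulate_dataset",
    "write_dataset",
]

# simple genome model: ten chromosomes; chr7 clonally gained, chr10 clonally
# lost, everything else diploid-heterozygous — a caricature of recurrent
# glioblastoma copy-number events that keeps several CN states in play
_CHROM_LENGTH = 100_000_000
_CHROMS = [f"chr{i}" for i in range(1, 11)]
_CN_PROFILE: dict[str, tuple[int, int]] = {c: (2, 1) for c in _CHROMS}
_CN_PROFILE["chr7"] = (3, 2)
_CN_PROFILE["chr10"] = (1, 1)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DepthModel:
    """Negative-binomial depth: mean and size (None means fixed depth)."""

    mean: float
    size: float | None = 60.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.mean <= 0:
            raise ValueError("depth mean must be > 0")
        if self.size is None:
            return np.full(n, int(round(self.mean)), dtype=np.int64)
        p = self.size / (self.size + self.mean)
        return rng.negative_binomial(self.size, p, size=n).astype(np.int64)


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    region_class: RegionClass
    purity_range: tuple[float, float]
    assays: Mapping[Assay, DepthModel]
    timepoint: Timepoint = Timepoint.PRIMARY
    dominant_clone: int | None = None  # None -> assigned by compose_samples


def default_design(
    n_t: int = 4,
    wes_depth: float = 157.0,
    tes1_depth: float = 4050.0,
    tes2_depth: float = 1128.0,
) -> list[SampleSpec]:
    """The study's sampling design: T1..Tn, one margin, one SVZ, blood.

    Tumour-mass purities are drawn around a median of ~58%, SVZ around ~22%,
    and the margin from 5–10%; the margin and SVZ carry both deep panels.
    """
    wes = DepthModel(wes_depth)
    tes1 = DepthModel(tes1_depth)
    tes2 = DepthModel(tes2_depth)
    design = [
        SampleSpec(f"T{i + 1}", RegionClass.T, (0.45, 0.72),
                   {Assay.WES: wes, Assay.TES1: tes1})
        for i in range(n_t)
    ]
    design.append(SampleSpec("SVZ1", RegionClass.SVZ, (0.18, 0.26),
                             {Assay.WES: wes, Assay.TES1: tes1, Assay.TES2: tes2}))
    design.append(SampleSpec("M1", RegionClass.M, (0.05, 0.10),
                             {Assay.WES: wes, Assay.TES1: tes1, Assay.TES2: tes2}))
    design.append(SampleSpec("BLOOD", RegionClass.BLOOD, (0.0, 0.0), {Assay.WES: wes}))
    return design


@dataclass
class SimConfig:
    patient_id: str = "SIM01"
    n_clones: int = 6                      # includes the germline clone 0
    truncal_mutations_mean: float = 40.0   # Poisson mean on the trunk edge
    mutations_per_edge_mean: float = 15.0  # Poisson mean on subclonal edges
    exact_mutations: Mapping[int, int] | None = None  # clone -> exact count override
    dominance: float = 200.0               # Dirichlet mass on the dominant clone
    background_concentration: float = 0.05
    rho: float = 5e-4                      # per-assay beta-binomial overdispersion
    ancestral_margin: bool = False
    normal_cn: int = 2
    samples: Sequence[SampleSpec] | None = None
    mutation_chroms: Sequence[str] | None = None  # restrict SNV placement

    def design(self) -> list[SampleSpec]:
        return list(self.samples) if self.samples is not None else default_design()


@dataclass
class CloneTruth:
    """Ground truth: clone tree, mutation placement, sample composition."""

    parents: tuple[int | None, ...]                  # parents[0] is None (germline)
    mutations_on_edge: dict[int, tuple[str, ...]]    # child clone -> variant ids
    variant_defs: dict[str, tuple[str, int, str, str]]
    mixtures: dict[str, np.ndarray] = field(default_factory=dict)  # over all clones
    purity: dict[str, float] = field(default_factory=dict)
    dominant_clone: dict[str, int | None] = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return len(self.parents)

    def ancestry(self, clone: int) -> list[int]:
        """Path germline -> clone, inclusive."""
        path = [clone]
        while self.parents[path[-1]] is not None:
            path.append(self.parents[path[-1]])
        return path[::-1]

    def mutation_set(self, clone: int) -> frozenset[str]:
        muts: set[str] = set()
        for c in self.ancestry(clone):
            muts.update(self.mutations_on_edge.get(c, ()))
        return frozenset(muts)

    @property
    def trunk_variants(self) -> frozenset[str]:
        return frozenset(self.mutations_on_edge.get(1, ()))

    @property
    def variant_ids(self) -> list[str]:
        out: list[str] = []
        for c in sorted(self.mutations_on_edge):
            out.extend(self.mutations_on_edge[c])
        return out

    def carrier_fraction(self, sample_id: str, variant_id: str) -> float:
        """Fraction of the sample's tumour cells carrying the mutation."""
        w = self.mixtures[sample_id]
        total = 0.0
        for clone in range(1, self.n_clones):
            if w[clone] > 0 and variant_id in self.mutation_set(clone):
                total += w[clone]
        return total

    def true_vaf(self, sample_id: str, variant_id: str,
                 total_cn: int, normal_cn: int = 2, multiplicity: int = 1) -> float:
        pi = self.purity[sample_id]
        if pi == 0:
            return 0.0
        frac = self.carrier_fraction(sample_id, variant_id)
        denom = pi * total_cn + (1.0 - pi) * normal_cn
        return pi * multiplicity * frac / denom

    def children(self, clone: int) -> list[int]:
        return [c for c in range(1, self.n_clones) if self.parents[c] == clone]

    def leaf_clones(self) -> list[int]:
        return [c for c in range(1, self.n_clones) if not self.children(c)]

    def to_newick(self) -> str:
        def sub(clone: int) -> str:
            kids = self.children(clone)
            label = f"clone{clone}"
            if not kids:
                return label
            return "(" + ",".join(sub(k) for k in kids) + ")" + label
        return sub(0) + ";" if self.n_clones == 1 else "(" + sub(1) + ")germline;"


def cn_state_at(chrom: str) -> tuple[int, int]:
    return _CN_PROFILE.get(chrom, (2, 1))


def simulate_clone_tree(config: SimConfig, seed_or_rng) -> CloneTruth:
    """Random rooted clone tree (sequential attachment) with mutations per edge.

    Attachment is restricted to clones with fewer than two children, so the
    clone tree is binary. Under ``ancestral_margin`` the first two tumour
    clones form a trunk chain (germline -> clone1 -> clone2) and later clones
    attach strictly below clone2; clone1 is then a true ancestor of every
    tumour-mass clone and serves as the margin's dominant clone.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    if config.n_clones < 2:
        raise ValueError("need n_clones >= 2 (germline plus one tumour clone)")
    parents: list[int | None] = [None, 0]
    for clone in range(2, config.n_clones):
        if config.ancestral_margin:
            candidates = [1] if clone == 2 else [
                c for c in range(2, clone) if parents.count(c) < 2
            ]
        else:
            candidates = [c for c in range(1, clone) if parents.count(c) < 2]
        parents.append(int(candidates[rng.integers(len(candidates))]))

    chroms = list(config.mutation_chroms) if config.mutation_chroms else _CHROMS
    unknown = set(chroms) - set(_CHROMS)
    if unknown:
        raise ValueError(f"mutation_chroms outside the genome model: {sorted(unknown)}")
    mutations: dict[int, tuple[str, ...]] = {}
    variant_defs: dict[str, tuple[str, int, str, str]] = {}
    for clone in range(1, config.n_clones):
        if config.exact_mutations is not None and clone in config.exact_mutations:
            count = int(config.exact_mutations[clone])
        else:
            mean = (config.truncal_mutations_mean if clone == 1
                    else config.mutations_per_edge_mean)
            count = int(rng.poisson(mean))
        vids = []
        for _ in range(count):
            while True:
                chrom = chroms[rng.integers(len(chroms))]
                pos = int(rng.integers(1, _CHROM_LENGTH + 1))
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                vid = make_variant_id(chrom, pos, str(ref), str(alt))
                if vid not in variant_defs:
                    break
            variant_defs[vid] = (chrom, pos, str(ref), str(alt))
            vids.append(vid)
        mutations[clone] = tuple(vids)
    return CloneTruth(parents=tuple(parents), mutations_on_edge=mutations,
                      variant_defs=variant_defs)


def compose_samples(truth: CloneTruth, config: SimConfig, seed_or_rng) -> CloneTruth:
    """Draw per-sample purity and clone-mixture weights for the design.

    Mixtures are Dirichlet over tumour clones with mass ``dominance`` on the
    dominant clone and ``background_concentration`` elsewhere; infinite
    dominance yields pure single-clone samples.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    design = config.design()
    leaves = truth.leaf_clones()
    truth = replace(truth, mixtures={}, purity={}, dominant_clone={})

    t_index = 0
    for spec in design:
        lo, hi = spec.purity_range
        purity = float(lo if lo == hi else rng.uniform(lo, hi))
        if spec.region_class is RegionClass.BLOOD:
            truth.purity[spec.sample_id] = 0.0
            truth.mixtures[spec.sample_id] = np.zeros(truth.n_clones)
            truth.dominant_clone[spec.sample_id] = None
            continue
        dominant = spec.dominant_clone
        if dominant is None:
            if spec.region_class is RegionClass.T:
                dominant = leaves[t_index % len(leaves)]
                t_index += 1
            elif spec.region_class is RegionClass.M and config.ancestral_margin:
                dominant = 1
            elif spec.region_class is RegionClass.SVZ and config.ancestral_margin:
                dominant = 2 if truth.n_clones > 2 else 1
            else:
                dominant = leaves[rng.integers(len(leaves))]
        if not 1 <= dominant < truth.n_clones:
            raise ValueError(
                f"{spec.sample_id}: dominant clone {dominant} not in the clone tree"
            )
        n_tumour = truth.n_clones - 1
        weights = np.zeros(truth.n_clones)
        if math.isinf(config.dominance) or n_tumour == 1:
            weights[dominant] = 1.0
        else:
            alpha = np.full(n_tumour, config.background_concentration)
            alpha[dominant - 1] = config.dominance
            weights[1:] = rng.dirichlet(alpha)
        truth.purity[spec.sample_id] = purity
        truth.mixtures[spec.sample_id] = weights
        truth.dominant_clone[spec.sample_id] = int(dominant)
    return truth


def simulate_read_counts(
    truth: CloneTruth, config: SimConfig, seed_or_rng
) -> tuple[list[VariantRecord], dict[str, SampleMeta], list[CopyNumberSegment]]:
    """Draw depths and alt counts for every (variant, sample, assay).

    Depths are negative-binomial around the assay mean; alt counts are
    beta-binomial around the true VAF with overdispersion ``config.rho``
    (``rho = 0`` is binomial). Also builds the sample sheet and the clonal
    copy-number table the pipeline consumes.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    design = config.design()
    variant_ids = truth.variant_ids
    records = [
        VariantRecord(vid, *truth.variant_defs[vid]) for vid in variant_ids
    ]
    n_var = len(records)

    for spec in design:
        vafs = np.array([
            truth.true_vaf(
                spec.sample_id, vid,
                cn_state_at(truth.variant_defs[vid][0])[0], config.normal_cn,
            )
            for vid in variant_ids
        ])
        for assay in sorted(spec.assays, key=lambda a: a.value):
            depths = spec.assays[assay].draw(rng, n_var)
            alts = _draw_alt_counts(rng, depths, vafs, config.rho)
            for rec, d, a in zip(records, depths, alts):
                rec.add_observation(spec.sample_id, assay, Observation(int(d), int(a)))

    metas = {
        spec.sample_id: SampleMeta(
            sample_id=spec.sample_id,
            patient_id=config.patient_id,
            region_class=spec.region_class,
            timepoint=spec.timepoint,
            purity=truth.purity[spec.sample_id],
            assays=frozenset(spec.assays),
        )
        for spec in design
    }
    segments = [
        CopyNumberSegment(spec.sample_id, chrom, 1, _CHROM_LENGTH, *cn_state_at(chrom))
        for spec in design if spec.region_class is not RegionClass.BLOOD
        for chrom in _CHROMS
    ]
    return records, metas, segments


def _draw_alt_counts(rng: np.random.Generator, depths: np.ndarray,
                     vafs: np.ndarray, rho: float) -> np.ndarray:
    alts = np.zeros_like(depths)
    positive = (vafs > 0) & (depths > 0)
    if not np.any(positive):
        return alts
    if rho <= 0:
        alts[positive] = rng.binomial(depths[positive], vafs[positive])
        return alts
    s = (1.0 - rho) / rho
    p = rng.beta(vafs[positive] * s, (1.0 - vafs[positive]) * s)
    alts[positive] = rng.binomial(depths[positive], p)
    return alts


@dataclass
class SimulatedDataset:
    variants: list[VariantRecord]
    samples: dict[str, SampleMeta]
    segments: list[CopyNumberSegment]
    truth: CloneTruth
    config: SimConfig


def simulate_dataset(config: SimConfig, seed: int) -> SimulatedDataset:
    """Full generator chain with one seeded RNG: tree, mixtures, read counts."""
    rng = np.random.default_rng(seed)
    truth = simulate_clone_tree(config, rng)
    truth = compose_samples(truth, config, rng)
    variants, samples, segments = simulate_read_counts(truth, config, rng)
    return SimulatedDataset(variants, samples, segments, truth, config)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the pipeline's input dialects, plus truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    sample_ids = sorted(dataset.samples)
    paths = {
        "vcf": outdir / "variants.vcf",
        "tes1": outdir / "readcounts_tes1.tsv",
        "tes2": outdir / "readcounts_tes2.tsv",
        "cn": outdir / "copy_number.tsv",
        "sample_sheet": outdir / "samples.tsv",
        "clone_tree": truth_dir / "clone_tree.nwk",
        "mutation_edges": truth_dir / "mutation_edges.tsv",
        "mixtures": truth_dir / "mixtures.tsv",
    }
    write_multisample_vcf(dataset.variants, sample_ids, paths["vcf"])
    write_readcount_table(dataset.variants, paths["tes1"], assays=[Assay.TES1])
    write_readcount_table(dataset.variants, paths["tes2"], assays=[Assay.TES2])
    write_cn_table(dataset.segments, paths["cn"])
    write_sample_sheet(dataset.samples, paths["sample_sheet"])

    paths["clone_tree"].write_text(dataset.truth.to_newick() + "\n")
    with open(paths["mutation_edges"], "w") as fh:
        fh.write("variant_id\tclone\n")
        for clone in sorted(dataset.truth.mutations_on_edge):
            for vid in dataset.truth.mutations_on_edge[clone]:
                fh.write(f"{vid}\t{clone}\n")
    with open(paths["mixtures"], "w") as fh:
        fh.write("sample_id\tpurity\tdominant_clone\t"
                 + "\t".join(f"clone{c}" for c in range(dataset.truth.n_clones)) + "\n")
        for sid in sample_ids:
            w = dataset.truth.mixtures[sid]
            dom = dataset.truth.dominant_clone[sid]
            fh.write(
                f"{sid}\t{dataset.truth.purity[sid]:.6f}\t"
                f"{'' if dom is None else dom}\t"
                + "\t".join(f"{x:.6f}" for x in w) + "\n"
            )
    return paths
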