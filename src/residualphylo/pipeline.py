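"""Per-patient orchestration: load -> CCF -> fit -> absence test -> tree.

Stages run in a fixed order; every parameter and the seed are echoed to the
run log, and the whole run is deterministic given identical inputs and
config. Patients are analysed independently — batching is a loop over
configs, never statistical pooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import absence, ccf, io_formats, phylo
from .absence import BetaBinomialFit, DetectionRule
from .io_formats import Assay, RegionClass, SampleMeta

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "PatientResult", "run_patient"]

_STAGES = ("truncal", "test", "tree")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    sample_sheet: Path
    cn: Path
    outdir: Path
    vcf: Path | None = None
    readcounts: dict[Assay, Path] = field(default_factory=dict)
    ccf_threshold: float = 0.8
    pi_star: float = 0.01
    alpha: float = 0.05
    n_bootstrap: int = 1000
    min_training: int = 10
    detection_min_alt: int = 2
    detection_frac: float = 5e-4
    normal_cn: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.sample_sheet = Path(self.sample_sheet)
        self.cn = Path(self.cn)
        self.outdir = Path(self.outdir)
        self.vcf = Path(self.vcf) if self.vcf is not None else None
        self.readcounts = {Assay(a): Path(p) for a, p in self.readcounts.items()}
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.ccf_threshold <= 1.0:
            raise ValueError(f"ccf_threshold {self.ccf_threshold} outside (0, 1]")
        if not 0.0 < self.pi_star <= 1.0:
            raise ValueError(f"pi_star {self.pi_star} outside (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.min_training < 3:
            raise ValueError("min_training must be >= 3")
        if self.vcf is None and not self.readcounts:
            raise ValueError("need a VCF and/or read-count tables")

    @property
    def detection_rule(self) -> DetectionRule:
        return DetectionRule(self.detection_min_alt, self.detection_frac)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        kwargs = dict(raw)
        for key in ("sample_sheet", "cn", "outdir", "vcf"):
            if kwargs.get(key) is not None:
                kwargs[key] = resolve(kwargs[key])
        kwargs["readcounts"] = {
            Assay(a): resolve(p) for a, p in (raw.get("readcounts") or {}).items()
        }
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "sample_sheet": str(self.sample_sheet),
            "cn": str(self.cn),
            "outdir": str(self.outdir),
            "vcf": None if self.vcf is None else str(self.vcf),
            "readcounts": {a.value: str(p) for a, p in sorted(self.readcounts.items())},
            "ccf_threshold": self.ccf_threshold,
            "pi_star": self.pi_star,
            "alpha": self.alpha,
            "n_bootstrap": self.n_bootstrap,
            "min_training": self.min_training,
            "detection_min_alt": self.detection_min_alt,
            "detection_frac": self.detection_frac,
            "normal_cn": self.normal_cn,
            "seed": self.seed,
        }


@dataclass
class PatientResult:
    config: PipelineConfig
    samples: dict[str, SampleMeta]
    variants: list
    truncal_set: ccf.TruncalSet | None = None
    fits: list[BetaBinomialFit] = field(default_factory=list)
    absence_results: list = field(default_factory=list)
    matrix: phylo.PresenceMatrix | None = None
    tree: phylo.PhyloTree | None = None
    paths: dict[str, Path] = field(default_factory=dict)


def run_patient(config: PipelineConfig, upto: str = "tree") -> PatientResult:
    """Run the per-patient analysis up to the given stage.

    Stages: ``truncal`` (load, CN annotation, CCF, truncal selection),
    ``test`` (beta-binomial fit and absence test), ``tree`` (presence matrix,
    parsimony tree, bootstrap). Outputs are written under ``config.outdir``;
    identical inputs and config give byte-identical outputs.
    """
    if upto not in _STAGES:
        raise ValueError(f"unknown stage {upto!r}; choose from {_STAGES}")
    upto_i = _STAGES.index(upto)
    config.outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config.{k} = {v}" for k, v in sorted(config.to_dict().items())]

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrap

    # --- load ---------------------------------------------------------------
    run = stage("load")
    samples = run(io_formats.read_sample_sheet, config.sample_sheet)
    variants = []
    if config.vcf is not None:
        variants = run(io_formats.read_multisample_vcf, config.vcf, set(samples))
    for assay, path in sorted(config.readcounts.items()):
        variants = run(io_formats.read_readcount_table, path, assay, variants)
    segments = run(io_formats.read_cn_table, config.cn)
    log_lines.append(f"loaded {len(variants)} SNVs, {len(samples)} samples, "
                     f"{len(segments)} CN segments")

    # --- CN annotation + CCF + truncal selection ----------------------------
    run = stage("truncal")
    assignments = run(io_formats.annotate_copy_number, variants, segments)
    truncal = run(
        ccf.select_putative_truncal,
        variants, samples, assignments,
        threshold=config.ccf_threshold, normal_cn=config.normal_cn,
    )
    log_lines.append(f"putative truncal SNVs: {len(truncal)} "
                     f"(threshold {config.ccf_threshold})")
    result = PatientResult(config, samples, variants, truncal_set=truncal)
    result.paths["truncal"] = config.outdir / "truncal.tsv"
    _write_truncal(truncal, result.paths["truncal"])
    if upto_i < 1:
        _finish(result, log_lines, config)
        return result

    # --- beta-binomial fit + absence test -----------------------------------
    run = stage("test")
    training_sample = max(
        (s for s in samples.values() if s.region_class is RegionClass.T),
        key=lambda s: (s.purity, s.sample_id),
    ).sample_id
    grouped = _training_observations(variants, truncal, training_sample)
    fits = run(absence.fit_betabinomial, grouped, training_sample, config.min_training)
    for f in fits:
        log_lines.append(
            f"fit cn_state={f.cn_state} mu={f.mu:.4f} rho={f.rho:.3g} "
            f"n={f.n_training} pooled={f.pooled} (training sample {training_sample})"
        )
    targets = sorted(
        (s for s in samples.values()
         if s.region_class in (RegionClass.M, RegionClass.SVZ)),
        key=lambda s: s.sample_id,
    )
    results = run(
        absence.run_absence_test,
        variants, truncal, fits, targets,
        pi_star=config.pi_star, alpha=config.alpha,
        detection_rule=config.detection_rule, normal_cn=config.normal_cn,
    )
    n_absent = sum(1 for r in results if r.decision == "ABSENT")
    log_lines.append(
        f"absence test: {len(results)} rows over {len(targets)} target samples, "
        f"{n_absent} ABSENT at alpha={config.alpha}, pi*={config.pi_star}"
    )
    result.fits = fits
    result.absence_results = results
    result.paths["absence"] = config.outdir / "absence_test.tsv"
    io_formats.write_results_table([r.to_row() for r in results], result.paths["absence"])
    if upto_i < 2:
        _finish(result, log_lines, config)
        return result

    # --- presence matrix + tree ---------------------------------------------
    run = stage("tree")
    matrix = run(
        phylo.build_presence_matrix,
        variants, samples, results, config.detection_rule,
    )
    tree = run(phylo.parsimony_tree, matrix)
    tree = run(
        phylo.bootstrap_support,
        matrix, config.n_bootstrap, config.seed, tree,
    )
    log_lines.append(
        f"parsimony tree: score {tree.score}, "
        f"{config.n_bootstrap} bootstrap replicates (seed {config.seed})"
    )
    result.matrix = matrix
    result.tree = tree
    result.paths["matrix"] = config.outdir / "presence_matrix.tsv"
    matrix.to_frame().to_csv(result.paths["matrix"], sep="\t")
    result.paths["tree"] = config.outdir / "tree.nwk"
    io_formats.write_newick(tree, result.paths["tree"])
    result.paths["branch_mutations"] = config.outdir / "branch_mutations.tsv"
    _write_branch_mutations(tree, result.paths["branch_mutations"])
    _finish(result, log_lines, config)
    return result


def _finish(result: PatientResult, log_lines: list[str], config: PipelineConfig) -> None:
    result.paths["log"] = config.outdir / "run_log.txt"
    text = "\n".join(log_lines) + "\n"
    result.paths["log"].write_text(text)
    for line in log_lines:
        logger.info(line)


def _training_observations(variants, truncal, training_sample):
    """Truncal read counts in the training sample, grouped by CN state.

    Uses the deepest assay available per locus; variants whose CN state fell
    back to the default are excluded from training (but remain testable).
    """
    by_id = {v.variant_id: v for v in variants}
    grouped: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for vid in sorted(truncal.variant_ids):
        tv = truncal.variants[vid]
        if tv.cn_is_default:
            continue
        v = by_id[vid]
        obs = [
            o for (sid, _a), o in v.observations.items()
            if sid == training_sample and o.depth > 0
        ]
        if not obs:
            continue
        best = max(obs, key=lambda o: o.depth)
        grouped.setdefault(tv.cn_state, []).append((best.alt_count, best.depth))
    return grouped


def _write_truncal(truncal: ccf.TruncalSet, path: Path) -> None:
    t_samples = list(truncal.tumour_samples)
    with open(path, "w") as fh:
        header = ["variant_id", "total_cn", "major_cn", "multiplicity", "cn_is_default"]
        header += [f"ccf_{s}" for s in t_samples]
        fh.write("\t".join(header) + "\n")
        for vid in sorted(truncal.variant_ids):
            tv = truncal.variants[vid]
            row = [vid, str(tv.cn_state[0]), str(tv.cn_state[1]),
                   str(tv.multiplicity), str(tv.cn_is_default)]
            row += [f"{tv.ccf_by_sample[s]:.4f}" for s in t_samples]
            fh.write("\t".join(row) + "\n")


def _write_branch_mutations(tree: phylo.PhyloTree, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("edge\tvariant_id\tchange\n")
        for node in tree.root.walk():
            if node is tree.root:
                continue
            label = node.name if node.is_leaf else "|".join(sorted(node.leaf_names()))
            for vid, change in sorted(node.mutations):
                fh.write(f"{label}\t{vid}\t{change}\n")
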