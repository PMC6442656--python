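"""Readers and writers for the formats the residual-disease pipeline touches.

Conventions used throughout the package:

* VCF positions are 1-based (the VCF convention).
* Copy-number segments are 1-based and **closed** on both ends, so a segment
  ``[start, end]`` contains position ``pos`` iff ``start <= pos <= end``.
* Read-count tables are TSV with columns
  ``variant_id  sample_id  assay  depth  alt_count``.
* Sample sheets are TSV with columns
  ``sample_id  patient_id  region_class  timepoint  purity  assays``
  (``assays`` comma-separated).
"""

from __future__ import annotations

import bisect
import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "Assay",
    "RegionClass",
    "Timepoint",
    "Observation",
    "VariantRecord",
    "SampleMeta",
    "CopyNumberSegment",
    "CNAssignment",
    "read_multisample_vcf",
    "write_multisample_vcf",
    "read_readcount_table",
    "write_readcount_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_cn_table",
    "write_cn_table",
    "annotate_copy_number",
    "write_results_table",
    "write_newick",
    "RESULTS_COLUMNS",
]


class Assay(str, Enum):
    """Sequencing assay: whole exome, amplicon panel, capture panel."""

    WES = "WES"
    TES1 = "TES1"
    TES2 = "TES2"


class RegionClass(str, Enum):
    """Anatomical compartment of a sample."""

    T = "T"          # tumour mass
    M = "M"          # infiltrative margin
    SVZ = "SVZ"      # sub-ventricular zone
    BLOOD = "BLOOD"  # germline reference


class Timepoint(str, Enum):
    PRIMARY = "primary"
    RECURRENCE = "recurrence"


class Observation(NamedTuple):
    """Read counts for one variant in one (sample, assay)."""

    depth: int
    alt_count: int


@dataclass
class VariantRecord:
    """One somatic SNV with per-sample, per-assay read counts.

    ``observations`` maps ``(sample_id, assay)`` to an :class:`Observation`.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    observations: dict[tuple[str, Assay], Observation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.variant_id}: ref/alt must be single nucleotides")
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref == alt")
        for key, obs in self.observations.items():
            self._check_obs(key, obs)

    def _check_obs(self, key: tuple[str, Assay], obs: Observation) -> None:
        if obs.depth < 0 or obs.alt_count < 0 or obs.alt_count > obs.depth:
            raise ValueError(
                f"{self.variant_id} {key}: need 0 <= alt_count <= depth, "
                f"got alt={obs.alt_count} depth={obs.depth}"
            )

    def add_observation(self, sample_id: str, assay: Assay, obs: Observation) -> None:
        self._check_obs((sample_id, assay), obs)
        self.observations[(sample_id, Assay(assay))] = obs

    def observation(self, sample_id: str, assay: Assay) -> Observation | None:
        return self.observations.get((sample_id, Assay(assay)))

    def assays_for(self, sample_id: str) -> list[Assay]:
        return [a for (s, a) in self.observations if s == sample_id]


def make_variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def parse_variant_id(variant_id: str) -> tuple[str, int, str, str]:
    chrom, pos, change = variant_id.rsplit(":", 2)
    ref, alt = change.split(">")
    return chrom, int(pos), ref, alt


@dataclass
class SampleMeta:
    """Region class, timepoint, purity and assays of one sample."""

    sample_id: str
    patient_id: str
    region_class: RegionClass
    timepoint: Timepoint
    purity: float
    assays: frozenset[Assay]

    def __post_init__(self) -> None:
        self.region_class = RegionClass(self.region_class)
        self.timepoint = Timepoint(self.timepoint)
        self.assays = frozenset(Assay(a) for a in self.assays)
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"{self.sample_id}: purity {self.purity} outside [0, 1]")
        if self.region_class is RegionClass.BLOOD and self.purity != 0.0:
            raise ValueError(f"{self.sample_id}: BLOOD sample must have purity 0")


@dataclass(frozen=True)
class CopyNumberSegment:
    """Clonal copy-number state over a 1-based closed genomic interval."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: int
    major_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.sample_id} {self.chrom}: start > end")
        if self.total_cn < 0 or self.major_cn < 0 or self.major_cn > self.total_cn:
            raise ValueError(
                f"{self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                f"need 0 <= major_cn <= total_cn"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


class CNAssignment(NamedTuple):
    """Copy-number state assigned to one (variant, sample).

    ``is_default`` flags positions outside every segment that fell back to the
    default diploid-heterozygous state.
    """

    total_cn: int
    major_cn: int
    is_default: bool

    @property
    def state(self) -> tuple[int, int]:
        return (self.total_cn, self.major_cn)


DEFAULT_CN_STATE = (2, 1)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_multisample_vcf(
    path: str | Path,
    known_samples: Iterable[str] | None = None,
) -> list[VariantRecord]:
    """Read a multi-sample VCF into :class:`VariantRecord` objects.

    Each biallelic SNV row becomes one record; multiallelic rows are split by
    ALT allele; indels/MNVs are skipped with a logged count. Per-sample counts
    come from the ``AD`` FORMAT field, falling back to ``DP`` times the site
    ``AF`` (rounded) when ``AD`` is absent. All observations are tagged
    ``assay=WES``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if known_samples is not None:
        unknown = set(samples) - set(known_samples)
        if unknown:
            raise ValueError(
                f"VCF samples absent from sample sheet: {sorted(unknown)}"
            )
    records: list[VariantRecord] = []
    n_skipped = 0
    for v in vcf:
        ad = v.format("AD")
        dp = v.format("DP")
        af = v.INFO.get("AF")
        if af is not None and not isinstance(af, (tuple, list)):
            af = (af,)
        for ai, alt in enumerate(v.ALT):
            if len(v.REF) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            rec = VariantRecord(
                variant_id=make_variant_id(v.CHROM, v.POS, v.REF, alt),
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
            )
            for si, sample in enumerate(samples):
                depth, alt_count = _sample_counts(v, ad, dp, af, si, ai, sample)
                rec.add_observation(sample, Assay.WES, Observation(depth, alt_count))
            records.append(rec)
    if n_skipped:
        logger.info("read_multisample_vcf: skipped %d non-SNV alleles", n_skipped)
    return records


def _sample_counts(v, ad, dp, af, si: int, ai: int, sample: str) -> tuple[int, int]:
    """Extract (depth, alt_count) for one sample/allele, with fallbacks."""
    site = f"{v.CHROM}:{v.POS}"
    dp_val = None
    if dp is not None:
        d = int(np.asarray(dp)[si].reshape(-1)[0])
        if d >= 0:
            dp_val = d
    if ad is not None:
        row = np.asarray(ad)[si].reshape(-1)
        if np.all(row < 0):
            # genotype entirely missing for this sample -> no coverage
            if dp_val is None:
                return 0, 0
            return dp_val, 0
        row = np.clip(row, 0, None)
        alt_count = int(row[ai + 1]) if ai + 1 < row.size else 0
        depth = int(row.sum())
        if dp_val is not None:
            depth = max(depth, dp_val)
        return depth, alt_count
    # AD absent from FORMAT: fall back to DP x AF
    if dp_val is not None and af is not None and ai < len(af):
        alt_count = int(round(dp_val * float(af[ai])))
        return dp_val, min(alt_count, dp_val)
    raise ValueError(
        f"record {site} sample {sample}: no AD field and no DP/AF fallback available"
    )


def write_multisample_vcf(
    variants: Sequence[VariantRecord],
    sample_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write WES observations as a minimal multi-sample VCF (v4.2, GT:AD:DP)."""
    path = Path(path)
    contigs: list[str] = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=residualphylo",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
    )
    for v in sorted(variants, key=lambda r: (contigs.index(r.chrom), r.pos, r.alt)):
        fields = [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".", "PASS", ".", "GT:AD:DP"]
        for s in sample_ids:
            obs = v.observation(s, Assay.WES)
            if obs is None:
                fields.append("./.:.,.:.")
                continue
            gt = "0/1" if obs.alt_count > 0 else "0/0"
            fields.append(f"{gt}:{obs.depth - obs.alt_count},{obs.alt_count}:{obs.depth}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Read-count tables (targeted panels, or any assay)
# ---------------------------------------------------------------------------

def read_readcount_table(
    path: str | Path,
    assay: Assay | None = None,
    into: list[VariantRecord] | None = None,
) -> list[VariantRecord]:
    """Read a TSV read-count table, merging rows by ``variant_id``.

    When ``into`` is given, observations are merged into those records by exact
    ``variant_id`` match (new variant ids create new records); otherwise a
    fresh list is built. ``assay`` overrides the table's ``assay`` column.
    """
    path = Path(path)
    by_id: dict[str, VariantRecord] = {}
    records: list[VariantRecord] = list(into) if into is not None else []
    for rec in records:
        by_id[rec.variant_id] = rec

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("read_readcount_table: %s is empty", path)
            return records
        required = {"variant_id", "sample_id", "depth", "alt_count"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        if assay is None and "assay" not in reader.fieldnames:
            raise ValueError(f"{path}: no assay column and no assay argument")
        n_rows = 0
        for lineno, row in enumerate(reader, start=2):
            n_rows += 1
            try:
                vid = row["variant_id"]
                sample_id = row["sample_id"]
                depth = int(row["depth"])
                alt_count = int(row["alt_count"])
                row_assay = Assay(assay) if assay is not None else Assay(row["assay"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            if alt_count > depth:
                raise ValueError(
                    f"{path}:{lineno}: alt_count {alt_count} > depth {depth}"
                )
            rec = by_id.get(vid)
            if rec is None:
                chrom, pos, ref, alt = parse_variant_id(vid)
                rec = VariantRecord(vid, chrom, pos, ref, alt)
                by_id[vid] = rec
                records.append(rec)
            rec.add_observation(sample_id, row_assay, Observation(depth, alt_count))
    if n_rows == 0:
        logger.warning("read_readcount_table: %s has a header but no rows", path)
    return records


def write_readcount_table(
    variants: Sequence[VariantRecord],
    path: str | Path,
    assays: Iterable[Assay] | None = None,
) -> None:
    """Write observations (optionally restricted to ``assays``) as TSV."""
    wanted = None if assays is None else {Assay(a) for a in assays}
    rows = []
    for v in variants:
        for (sample_id, assay), obs in v.observations.items():
            if wanted is not None and assay not in wanted:
                continue
            rows.append((v.chrom, v.pos, v.alt, v.variant_id, sample_id,
                         assay.value, obs.depth, obs.alt_count))
    rows.sort()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_id", "sample_id", "assay", "depth", "alt_count"])
        for row in rows:
            w.writerow(row[3:])


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> dict[str, SampleMeta]:
    """Read the sample sheet; validates one BLOOD (purity 0) per patient."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "region_class", "timepoint", "purity", "assays"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    metas: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        meta = SampleMeta(
            sample_id=row["sample_id"],
            patient_id=row["patient_id"],
            region_class=RegionClass(row["region_class"]),
            timepoint=Timepoint(row["timepoint"]),
            purity=float(row["purity"]),
            assays=frozenset(Assay(a) for a in row["assays"].split(",") if a),
        )
        if meta.sample_id in metas:
            raise ValueError(f"{path}: duplicate sample_id {meta.sample_id}")
        metas[meta.sample_id] = meta
    for patient in {m.patient_id for m in metas.values()}:
        n_blood = sum(
            1 for m in metas.values()
            if m.patient_id == patient and m.region_class is RegionClass.BLOOD
        )
        if n_blood != 1:
            raise ValueError(
                f"{path}: patient {patient} has {n_blood} BLOOD samples (need exactly 1)"
            )
    return metas


def write_sample_sheet(metas: Mapping[str, SampleMeta] | Sequence[SampleMeta],
                       path: str | Path) -> None:
    items = list(metas.values()) if isinstance(metas, Mapping) else list(metas)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "patient_id", "region_class", "timepoint", "purity", "assays"])
        for m in items:
            w.writerow([
                m.sample_id, m.patient_id, m.region_class.value, m.timepoint.value,
                repr(m.purity), ",".join(sorted(a.value for a in m.assays)),
            ])


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

def read_cn_table(path: str | Path) -> list[CopyNumberSegment]:
    """Read the BED-like (but 1-based closed) copy-number TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "chrom", "start", "end", "total_cn", "major_cn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    segments = [
        CopyNumberSegment(
            sample_id=str(r.sample_id), chrom=str(r.chrom),
            start=int(r.start), end=int(r.end),
            total_cn=int(r.total_cn), major_cn=int(r.major_cn),
        )
        for r in df.itertuples(index=False)
    ]
    _check_non_overlapping(segments)
    return segments


def write_cn_table(segments: Sequence[CopyNumberSegment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "chrom", "start", "end", "total_cn", "major_cn"])
        for s in sorted(segments, key=lambda s: (s.sample_id, s.chrom, s.start)):
            w.writerow([s.sample_id, s.chrom, s.start, s.end, s.total_cn, s.major_cn])


def _check_non_overlapping(segments: Sequence[CopyNumberSegment]) -> None:
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample_id, chrom), segs in by_key.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:  # closed intervals
                raise ValueError(
                    f"overlapping segments for {sample_id} {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def annotate_copy_number(
    variants: Sequence[VariantRecord],
    segments: Sequence[CopyNumberSegment],
    default_state: tuple[int, int] = DEFAULT_CN_STATE,
) -> dict[tuple[str, str], CNAssignment]:
    """Map each (variant_id, sample_id) to its copy-number state.

    Positions outside every segment for a sample fall back to ``default_state``
    with ``is_default=True``; such variants are excluded from beta-binomial
    training downstream but may still be tested.
    """
    index: dict[tuple[str, str], tuple[list[int], list[CopyNumberSegment]]] = {}
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    for key, segs in by_key.items():
        segs.sort(key=lambda s: s.start)
        index[key] = ([s.start for s in segs], segs)

    out: dict[tuple[str, str], CNAssignment] = {}
    for v in variants:
        sample_ids = {s for (s, _a) in v.observations}
        for sample_id in sample_ids:
            starts_segs = index.get((sample_id, v.chrom))
            hit: CopyNumberSegment | None = None
            if starts_segs is not None:
                starts, segs = starts_segs
                i = bisect.bisect_right(starts, v.pos) - 1
                hits = [s for s in segs[max(i, 0): i + 2] if s.contains(v.pos)]
                if len(hits) > 1:
                    raise ValueError(
                        f"overlapping segments at {v.chrom}:{v.pos} for {sample_id}"
                    )
                hit = hits[0] if hits else None
            if hit is None:
                out[(v.variant_id, sample_id)] = CNAssignment(*default_state, True)
            else:
                out[(v.variant_id, sample_id)] = CNAssignment(
                    hit.total_cn, hit.major_cn, False
                )
    return out


# ---------------------------------------------------------------------------
# Results table and Newick
# ---------------------------------------------------------------------------

RESULTS_COLUMNS = [
    "variant_id", "target_sample_id", "assay_used", "depth", "alt_observed",
    "null_vaf", "worst_case_purity", "p_raw", "p_adjusted", "n_tests",
    "testable", "decision", "note",
]


def write_results_table(rows: Sequence[Mapping], path: str | Path,
                        columns: Sequence[str] = RESULTS_COLUMNS) -> None:
    """Write absence-test results (one row per tested SNV per target sample).

    An empty result list produces a header-only TSV.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for row in rows:
            w.writerow([row.get(c, "") for c in columns])


def write_newick(tree, path: str | Path) -> None:
    """Write a rooted tree with branch lengths and integer supports."""
    if not getattr(tree, "rooted", False):
        raise ValueError("write_newick requires a rooted tree")
    Path(path).write_text(tree.to_newick() + "\n")
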