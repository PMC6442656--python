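"""Cancer cell fractions and selection of putative truncal SNVs.

The cancer cell fraction (CCF) of a mutation is the fraction of tumour cells
that carry it. With sample purity ``pi``, tumour total copy number ``CNt`` at
the locus, normal copy number ``CNn`` and mutation multiplicity ``m`` (mutated
copies per tumour cell), the expected variant allele frequency of a clonal
mutation is ``pi*m / (pi*CNt + (1-pi)*CNn)``, so the observed VAF converts to

    ccf = vaf * (pi*CNt + (1-pi)*CNn) / (pi * m).

"Putative truncal" SNVs are those with CCF >= threshold (default 0.8) in every
tumour-mass (T) sample *and* an identical copy-number state across all T
samples; those are the candidates for being present in every cancer cell and
hence for the downstream absence test in low-purity residual-disease samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import (
    Assay,
    CNAssignment,
    RegionClass,
    SampleMeta,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CCFEstimate",
    "TruncalVariant",
    "TruncalSet",
    "compute_ccf",
    "estimate_multiplicity",
    "select_putative_truncal",
]


@dataclass(frozen=True)
class CCFEstimate:
    variant_id: str
    sample_id: str
    vaf: float
    multiplicity: int
    ccf: float
    flagged_supraclonal: bool


def estimate_multiplicity(
    vaf: float, purity: float, total_cn: int, normal_cn: int, major_cn: int
) -> int:
    """Most likely number of mutated copies per tumour cell.

    ``m = clamp(round(vaf*(pi*CNt+(1-pi)*CNn)/pi), 1, major_cn)`` — the value
    that makes the clonal expected VAF closest to the observed VAF, restricted
    to the physically possible range.
    """
    if purity <= 0:
        raise ValueError("estimate_multiplicity requires purity > 0")
    raw = vaf * (purity * total_cn + (1.0 - purity) * normal_cn) / purity
    return int(min(max(round(raw), 1), max(major_cn, 1)))


def compute_ccf(
    alt_count: int,
    depth: int,
    purity: float,
    total_cn: int,
    normal_cn: int = 2,
    multiplicity: int = 1,
    variant_id: str = "",
    sample_id: str = "",
) -> CCFEstimate:
    """Purity/copy-number corrected cancer cell fraction of one observation.

    Raw CCFs above 1 (sampling noise, or model misfit) are capped at 1 and
    flagged ``flagged_supraclonal``.
    """
    if depth <= 0:
        raise ValueError("CCF undefined at zero depth")
    if purity <= 0 or purity > 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if total_cn < 1 or multiplicity < 1:
        raise ValueError("need total_cn >= 1 and multiplicity >= 1")
    vaf = alt_count / depth
    raw = vaf * (purity * total_cn + (1.0 - purity) * normal_cn) / (purity * multiplicity)
    return CCFEstimate(
        variant_id=variant_id,
        sample_id=sample_id,
        vaf=vaf,
        multiplicity=multiplicity,
        ccf=min(raw, 1.0),
        flagged_supraclonal=raw > 1.0,
    )


@dataclass(frozen=True)
class TruncalVariant:
    """One member of the putative truncal set."""

    variant_id: str
    ccf_by_sample: Mapping[str, float]
    cn_state: tuple[int, int]          # (total_cn, major_cn), shared across T samples
    multiplicity: int                  # estimated in the highest-purity T sample
    cn_is_default: bool                # True if any T assignment used the default state


@dataclass
class TruncalSet:
    patient_id: str
    ccf_threshold: float
    tumour_samples: tuple[str, ...]
    variants: dict[str, TruncalVariant] = field(default_factory=dict)

    @property
    def variant_ids(self) -> set[str]:
        return set(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.variants


def select_putative_truncal(
    variants: Sequence[VariantRecord],
    samples: Mapping[str, SampleMeta],
    cn_assignments: Mapping[tuple[str, str], CNAssignment],
    threshold: float = 0.8,
    normal_cn: int = 2,
    assay: Assay = Assay.WES,
    patient_id: str | None = None,
) -> TruncalSet:
    """Select SNVs with CCF >= ``threshold`` in *all* T samples and a shared
    copy-number state across them.

    Selection uses the given ``assay`` (whole-exome by default: truncal
    selection precedes the targeted panels). M/SVZ/BLOOD samples play no role
    here. A variant without coverage in some T sample cannot establish
    truncality and is not selected.
    """
    t_samples = sorted(
        s.sample_id for s in samples.values() if s.region_class is RegionClass.T
    )
    if len(t_samples) < 2:
        raise ValueError(
            f"truncality undefined with {len(t_samples)} tumour-mass sample(s); need >= 2"
        )
    if patient_id is None:
        patient_id = next(iter(samples.values())).patient_id
    # estimate per-variant multiplicity in the highest-purity T sample, where
    # the clonal VAF signal is strongest
    training = max(t_samples, key=lambda s: (samples[s].purity, s))

    out = TruncalSet(patient_id, threshold, tuple(t_samples))
    for v in variants:
        states = []
        ccfs: dict[str, float] = {}
        any_default = False
        keep = True
        multiplicity = 1
        for sid in t_samples:
            obs = v.observation(sid, assay)
            assignment = cn_assignments.get((v.variant_id, sid))
            if obs is None or obs.depth == 0 or assignment is None:
                keep = False
                break
            any_default |= assignment.is_default
            states.append(assignment.state)
            purity = samples[sid].purity
            vaf = obs.alt_count / obs.depth
            m = estimate_multiplicity(
                vaf, purity, assignment.total_cn, normal_cn, assignment.major_cn
            )
            if sid == training:
                multiplicity = m
            est = compute_ccf(
                obs.alt_count, obs.depth, purity, assignment.total_cn,
                normal_cn, m, v.variant_id, sid,
            )
            if est.ccf < threshold:
                keep = False
                break
            ccfs[sid] = est.ccf
        if not keep or len(set(states)) != 1:
            continue
        out.variants[v.variant_id] = TruncalVariant(
            variant_id=v.variant_id,
            ccf_by_sample=ccfs,
            cn_state=states[0],
            multiplicity=multiplicity,
            cn_is_default=any_default,
        )
    logger.info(
        "select_putative_truncal: %d/%d SNVs truncal at CCF >= %.2f over %d T samples",
        len(out), len(variants), threshold, len(t_samples),
    )
    return out
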