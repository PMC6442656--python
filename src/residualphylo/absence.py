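"""Beta-binomial test for true absence of truncal SNVs at low purity.

The statistical core of the pipeline. Putative truncal SNVs define, per
copy-number state, an empirical VAF distribution in a high-purity tumour
sample; a beta-binomial fit (mean ``mu``, overdispersion ``rho``) captures
both binomial read sampling and extra-binomial noise. The mean rescales to an
arbitrary purity through the expected-VAF curve

    f(pi) = pi*m / (pi*CNt + (1-pi)*CNn),

while the concentration ``s = alpha + beta = (1-rho)/rho`` is preserved
(overdispersion is a property of the assay and locus, not of purity). For a
truncal SNV undetected in a margin/SVZ sample at depth ``n`` with ``x`` alt
reads, the one-sided p-value under the null "the mutation is truly truncal,
present at worst-case purity ``pi*``" is ``P(X <= x)`` under the rescaled
beta-binomial; for ``x = 0`` the closed form

    P(X = 0) = B(alpha, beta + n) / B(alpha, beta)

is evaluated in log space. Small p-values (after Bonferroni correction over
the testable candidates of one target sample) are evidence that the mutation
is genuinely absent, i.e. that the margin/SVZ clone diverged before the
mutation arose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import betaln

from .ccf import TruncalSet
from .io_formats import Assay, RegionClass, SampleMeta, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BetaBinomialFit",
    "DetectionRule",
    "MissingCandidate",
    "AbsenceTestResult",
    "FitError",
    "fit_betabinomial_counts",
    "fit_betabinomial",
    "fit_for_state",
    "expected_vaf",
    "rescale_fit",
    "absence_pvalue",
    "identify_missing",
    "run_absence_test",
]

# below this, the model is treated as exactly binomial
_RHO_BINOMIAL_EPS = 1e-12


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class BetaBinomialFit:
    """Beta-binomial VAF model for one copy-number state.

    ``mu`` is the mean VAF, ``rho`` in [0, 1) the overdispersion; ``rho = 0``
    is the binomial limit. ``states_covered`` lists the copy-number states the
    fit stands for (more than one when small groups were pooled).
    """

    cn_state: tuple[int, int]
    sample_id: str
    mu: float
    rho: float
    n_training: int
    pooled: bool = False
    states_covered: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must be in (0, 1), got {self.mu}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")

    @property
    def concentration(self) -> float:
        """alpha + beta; infinite in the binomial limit."""
        if self.rho <= _RHO_BINOMIAL_EPS:
            return math.inf
        return (1.0 - self.rho) / self.rho

    @property
    def alpha(self) -> float:
        return self.mu * self.concentration

    @property
    def beta(self) -> float:
        return (1.0 - self.mu) * self.concentration


def _sigmoid(t: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-t))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _shared_negll(theta: np.ndarray, xs: list[np.ndarray], ns: list[np.ndarray]) -> float:
    """-loglik of per-group means with one shared overdispersion."""
    mus = _sigmoid(theta[:-1])
    rho = max(float(_sigmoid(theta[-1])), 1e-9)
    s = (1.0 - rho) / rho
    total = 0.0
    for mu, x, n in zip(np.atleast_1d(mus), xs, ns):
        total -= float(np.sum(stats.betabinom.logpmf(x, n, mu * s, (1.0 - mu) * s)))
    return total


def _binomial_negll(xs: list[np.ndarray], ns: list[np.ndarray]) -> tuple[list[float], float]:
    """Boundary model rho = 0: per-group binomial MLE and its -loglik."""
    mus, total = [], 0.0
    for x, n in zip(xs, ns):
        mu = float(np.clip(x.sum() / n.sum(), 1e-9, 1 - 1e-9))
        mus.append(mu)
        total -= float(np.sum(stats.binom.logpmf(x, n, mu)))
    return mus, total


def _fit_shared_rho(
    groups: Sequence[tuple[np.ndarray, np.ndarray]]
) -> tuple[list[float], float]:
    """ML fit of per-group mu and a shared rho; rho = 0 when the binomial
    boundary fits at least as well."""
    xs = [g[0] for g in groups]
    ns = [g[1] for g in groups]
    mu0s, ll_binom = _binomial_negll(xs, ns)
    # method-of-moments start for rho from the pooled excess variance
    rho0 = 1e-4
    for mu0, x, n in zip(mu0s, xs, ns):
        if x.size < 2 or not 0 < mu0 < 1:
            continue
        inv_n = float(np.mean(1.0 / n))
        s2 = float(np.var(x / n, ddof=1))
        est = (s2 / (mu0 * (1.0 - mu0)) - inv_n) / max(1.0 - inv_n, 1e-9)
        rho0 = max(rho0, est)
    rho0 = float(np.clip(rho0, 1e-6, 0.5))

    theta0 = np.array([_logit(float(np.clip(m, 1e-6, 1 - 1e-6))) for m in mu0s]
                      + [_logit(rho0)])
    bounds = [(_logit(1e-6), _logit(1 - 1e-6))] * len(mu0s) + [(_logit(1e-8), _logit(0.95))]
    res = optimize.minimize(
        _shared_negll, theta0, args=(xs, ns), method="Nelder-Mead", bounds=bounds,
        options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 5000, "maxfev": 20000},
    )
    if ll_binom <= res.fun + 1e-9:
        # the rho = 0 boundary dominates everything the search found
        return mu0s, 0.0
    if not res.success:
        raise FitError(
            f"beta-binomial fit failed to converge: {res.message} "
            f"(groups={[x.size for x in xs]}, init rho={rho0:.4g})"
        )
    mus = [float(m) for m in np.atleast_1d(_sigmoid(res.x[:-1]))]
    return mus, float(_sigmoid(res.x[-1]))


def fit_betabinomial_counts(
    alt_counts: Sequence[int], depths: Sequence[int]
) -> tuple[float, float]:
    """Maximum-likelihood (mu, rho) for paired (alt, depth) counts.

    Method-of-moments initialisation, then Nelder-Mead on (logit mu,
    logit rho) compared against the binomial boundary rho = 0. Raises
    :class:`FitError` on non-convergence or on all-zero alt counts.
    """
    x = np.asarray(alt_counts, dtype=float)
    n = np.asarray(depths, dtype=float)
    if x.shape != n.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("alt_counts and depths must be equal-length 1-D sequences")
    if np.any(x > n) or np.any(n <= 0):
        raise ValueError("need 0 <= alt <= depth and depth > 0 for every pair")
    if not np.any(x > 0):
        raise FitError("all alt counts are zero; cannot model a truncal VAF")
    mus, rho = _fit_shared_rho([(x, n)])
    return mus[0], rho


def fit_betabinomial(
    observations_by_state: Mapping[tuple[int, int], Sequence[tuple[int, int]]],
    sample_id: str,
    min_training: int = 10,
) -> list[BetaBinomialFit]:
    """Fit one beta-binomial per copy-number state from truncal read counts.

    States with fewer than ``min_training`` SNVs are pooled into the
    nearest-ploidy large group and flagged: the pooled states are fitted
    *jointly* with the host group — one mean per state (their expected VAFs
    differ by construction) but a single shared overdispersion, which is the
    only trained quantity the absence test reuses after purity rescaling.
    If every state is below ``min_training`` all are pooled into one flagged
    joint fit anchored at the most populous state.
    """
    groups = {state: list(obs) for state, obs in observations_by_state.items() if obs}
    if not groups:
        raise ValueError("no training observations")
    large = [s for s in groups if len(groups[s]) >= min_training]
    small = [s for s in groups if len(groups[s]) < min_training]

    hosts = sorted(large) if large else [max(groups, key=lambda s: (len(groups[s]), s))]
    members: dict[tuple[int, int], list[tuple[int, int]]] = {h: [h] for h in hosts}
    for s in sorted(small):
        if s in members:
            continue
        # nearest ploidy: total copy number first, then major
        target = min(members, key=lambda t: (abs(t[0] - s[0]), abs(t[1] - s[1]), t))
        members[target].append(s)

    fits: list[BetaBinomialFit] = []
    for host in sorted(members):
        states = members[host]
        pooled = len(states) > 1 or len(groups[host]) < min_training
        n_total = sum(len(groups[s]) for s in states)
        if n_total < min_training:
            logger.warning(
                "fit_betabinomial: states %s have only %d training SNVs (< %d) "
                "even after pooling; fit flagged", states, n_total, min_training,
            )
        if n_total < 3:
            raise FitError(
                f"states {states}: {n_total} observations are too few to fit (mu, rho)"
            )
        arrays = []
        for s in states:
            alt, depth = zip(*groups[s])
            arrays.append((np.asarray(alt, float), np.asarray(depth, float)))
        if not any(np.any(a[0] > 0) for a in arrays):
            raise FitError(
                f"states {states}: all alt counts are zero; cannot model a truncal VAF"
            )
        mus, rho = _fit_shared_rho(arrays)
        fits.append(BetaBinomialFit(
            cn_state=host,
            sample_id=sample_id,
            mu=mus[0],
            rho=rho,
            n_training=n_total,
            pooled=pooled,
            states_covered=tuple(states),
        ))
    return fits


def fit_for_state(
    fits: Sequence[BetaBinomialFit], state: tuple[int, int]
) -> BetaBinomialFit:
    """Fit responsible for ``state``: exact match, pooled coverage, else nearest ploidy."""
    for f in fits:
        if f.cn_state == state:
            return f
    for f in fits:
        if state in f.states_covered:
            return f
    if not fits:
        raise ValueError("no fits available")
    return min(
        fits,
        key=lambda f: (abs(f.cn_state[0] - state[0]), abs(f.cn_state[1] - state[1]), f.cn_state),
    )


def expected_vaf(
    purity: float, multiplicity: int = 1, total_cn: int = 2, normal_cn: int = 2
) -> float:
    """Expected VAF of a clonal mutation: ``pi*m / (pi*CNt + (1-pi)*CNn)``."""
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    denom = purity * total_cn + (1.0 - purity) * normal_cn
    if denom <= 0:
        raise ValueError(
            "no DNA at locus: purity*total_cn + (1-purity)*normal_cn must be > 0"
        )
    return purity * multiplicity / denom


def rescale_fit(
    fit: BetaBinomialFit,
    target_purity: float,
    multiplicity: int = 1,
    total_cn: int | None = None,
    normal_cn: int = 2,
) -> BetaBinomialFit:
    """Move a trained fit to another purity, preserving the concentration.

    The mean becomes the expected VAF at ``target_purity`` for the locus
    copy-number state; since ``rho = 1/(1 + alpha + beta)`` depends only on the
    concentration, the rescaled overdispersion equals the trained one.
    """
    cnt = fit.cn_state[0] if total_cn is None else total_cn
    mu_new = expected_vaf(target_purity, multiplicity, cnt, normal_cn)
    if mu_new <= 0.0:
        raise ValueError(
            "degenerate rescaled model (expected VAF 0); use target_purity > 0"
        )
    return replace(fit, mu=mu_new)


def absence_pvalue(fit: BetaBinomialFit, depth: int, alt_observed: int) -> float:
    """One-sided lower-tail p-value ``P(X <= x)`` under the (rescaled) fit.

    ``depth = 0`` returns 1: no data cannot reject the null.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return 1.0
    if not 0 <= alt_observed <= depth:
        raise ValueError("need 0 <= alt_observed <= depth")
    if fit.rho <= _RHO_BINOMIAL_EPS:
        return float(stats.binom.cdf(alt_observed, depth, fit.mu))
    a, b = fit.alpha, fit.beta
    if alt_observed == 0:
        return float(math.exp(betaln(a, b + depth) - betaln(a, b)))
    return float(stats.betabinom.cdf(alt_observed, depth, a, b))


@dataclass(frozen=True)
class DetectionRule:
    """A mutation counts as detected when ``alt >= max(min_alt, depth*frac)``."""

    min_alt: int = 2
    frac: float = 5e-4

    def threshold(self, depth: int) -> float:
        return max(float(self.min_alt), depth * self.frac)

    def is_detected(self, alt_count: int, depth: int) -> bool:
        return depth > 0 and alt_count >= self.threshold(depth)

    def max_undetected(self, depth: int) -> int:
        """Largest alt count still classed as not detected."""
        t = self.threshold(depth)
        ceil_t = math.ceil(t)
        return int(ceil_t - 1 if ceil_t == t else math.floor(t))


@dataclass(frozen=True)
class MissingCandidate:
    variant_id: str
    target_sample_id: str
    assay: Assay
    depth: int
    alt_count: int


def identify_missing(
    variants: Sequence[VariantRecord],
    truncal_set: TruncalSet,
    target_sample_id: str,
    detection_rule: DetectionRule = DetectionRule(),
) -> tuple[list[MissingCandidate], list[str], list[str]]:
    """Split the truncal set by status in one margin/SVZ sample.

    Returns ``(candidates, detected_ids, no_coverage_ids)``: candidates are
    truncal SNVs undetected by *every* available assay, each carried forward
    with the deepest assay at the locus; detected ids passed the detection rule
    in at least one assay; no-coverage ids had no observation in any assay.
    """
    candidates: list[MissingCandidate] = []
    detected: list[str] = []
    no_coverage: list[str] = []
    by_id = {v.variant_id: v for v in variants}
    for vid in sorted(truncal_set.variant_ids):
        v = by_id.get(vid)
        obs = (
            []
            if v is None
            else [
                (assay, o)
                for (sid, assay), o in v.observations.items()
                if sid == target_sample_id and o.depth > 0
            ]
        )
        if not obs:
            no_coverage.append(vid)
            continue
        if any(detection_rule.is_detected(o.alt_count, o.depth) for _a, o in obs):
            detected.append(vid)
            continue
        assay, best = max(obs, key=lambda ao: (ao[1].depth, ao[0].value))
        candidates.append(MissingCandidate(vid, target_sample_id, assay, best.depth, best.alt_count))
    return candidates, detected, no_coverage


@dataclass(frozen=True)
class AbsenceTestResult:
    variant_id: str
    target_sample_id: str
    assay_used: Assay | None
    depth: int
    alt_observed: int
    null_vaf: float
    worst_case_purity: float
    p_raw: float
    p_adjusted: float
    n_tests: int
    testable: bool
    decision: str  # ABSENT | UNDETERMINED | DETECTED
    note: str = ""

    def to_row(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "target_sample_id": self.target_sample_id,
            "assay_used": self.assay_used.value if self.assay_used else "",
            "depth": self.depth,
            "alt_observed": self.alt_observed,
            "null_vaf": f"{self.null_vaf:.6g}" if not math.isnan(self.null_vaf) else "",
            "worst_case_purity": self.worst_case_purity,
            "p_raw": f"{self.p_raw:.6g}" if not math.isnan(self.p_raw) else "",
            "p_adjusted": f"{self.p_adjusted:.6g}" if not math.isnan(self.p_adjusted) else "",
            "n_tests": self.n_tests,
            "testable": self.testable,
            "decision": self.decision,
            "note": self.note,
        }


def _testable_count(p_bounds: Sequence[float], alpha: float) -> int:
    """Largest self-consistent number of testable candidates.

    ``k* = max{k : k-th smallest bound < alpha/k}`` — the biggest family such
    that every member could still reach significance after Bonferroni
    correction over that family.
    """
    ordered = sorted(p_bounds)
    k_star = 0
    for k in range(1, len(ordered) + 1):
        if ordered[k - 1] < alpha / k:
            k_star = k
    return k_star


def run_absence_test(
    variants: Sequence[VariantRecord],
    truncal_set: TruncalSet,
    fits: Sequence[BetaBinomialFit],
    target_samples: Sequence[SampleMeta],
    pi_star: float = 0.01,
    alpha: float = 0.05,
    detection_rule: DetectionRule = DetectionRule(),
    normal_cn: int = 2,
) -> list[AbsenceTestResult]:
    """Test every truncal SNV for true absence in each margin/SVZ sample.

    Per target sample: candidates are the truncal SNVs missed by every assay;
    a candidate is *testable* when, at worst-case purity ``pi_star``, even the
    largest undetected alt count would be significant after Bonferroni
    correction over the testable family (self-consistent family size, see
    :func:`_testable_count`). Decisions: ``ABSENT`` when testable and
    ``p_adjusted < alpha``; ``DETECTED`` when the detection rule fires in some
    assay; ``UNDETERMINED`` otherwise (including no-coverage loci).
    """
    if not 0.0 < pi_star <= 1.0:
        raise ValueError(f"pi_star must be in (0, 1], got {pi_star}")
    results: list[AbsenceTestResult] = []
    by_id = {v.variant_id: v for v in variants}
    for target in sorted(target_samples, key=lambda m: m.sample_id):
        if target.region_class not in (RegionClass.M, RegionClass.SVZ):
            raise ValueError(
                f"{target.sample_id}: absence test targets M/SVZ samples, "
                f"got {target.region_class.value}"
            )
        candidates, detected, no_coverage = identify_missing(
            variants, truncal_set, target.sample_id, detection_rule
        )

        prepared = []
        for cand in candidates:
            tv = truncal_set.variants[cand.variant_id]
            fit = fit_for_state(fits, tv.cn_state)
            rescaled = rescale_fit(
                fit, pi_star, tv.multiplicity, tv.cn_state[0], normal_cn
            )
            p_raw = absence_pvalue(rescaled, cand.depth, cand.alt_count)
            x_bound = detection_rule.max_undetected(cand.depth)
            p_bound = absence_pvalue(rescaled, cand.depth, x_bound)
            prepared.append((cand, rescaled.mu, p_raw, p_bound))

        n_tests = _testable_count([p[3] for p in prepared], alpha)
        if prepared and n_tests == 0:
            logger.warning(
                "run_absence_test: no testable candidates in %s "
                "(insufficient depth at pi*=%.3g)", target.sample_id, pi_star,
            )
        # ties on the bound broken by variant id (prepared is id-sorted)
        order = sorted(range(len(prepared)), key=lambda i: (prepared[i][3], i))
        testable_idx = set(order[:n_tests])

        for i, (cand, null_vaf, p_raw, p_bound) in enumerate(prepared):
            testable = i in testable_idx
            p_adj = min(1.0, p_raw * max(n_tests, 1))
            decision = "ABSENT" if testable and p_adj < alpha else "UNDETERMINED"
            results.append(AbsenceTestResult(
                variant_id=cand.variant_id,
                target_sample_id=target.sample_id,
                assay_used=cand.assay,
                depth=cand.depth,
                alt_observed=cand.alt_count,
                null_vaf=null_vaf,
                worst_case_purity=pi_star,
                p_raw=p_raw,
                p_adjusted=p_adj,
                n_tests=n_tests,
                testable=testable,
                decision=decision,
            ))
        for vid in detected:
            v = by_id[vid]
            obs = [
                (assay, o)
                for (sid, assay), o in v.observations.items()
                if sid == target.sample_id and o.depth > 0
            ]
            assay, best = max(obs, key=lambda ao: (ao[1].depth, ao[0].value))
            results.append(AbsenceTestResult(
                variant_id=vid,
                target_sample_id=target.sample_id,
                assay_used=assay,
                depth=best.depth,
                alt_observed=best.alt_count,
                null_vaf=math.nan,
                worst_case_purity=pi_star,
                p_raw=math.nan,
                p_adjusted=math.nan,
                n_tests=n_tests,
                testable=False,
                decision="DETECTED",
            ))
        for vid in no_coverage:
            results.append(AbsenceTestResult(
                variant_id=vid,
                target_sample_id=target.sample_id,
                assay_used=None,
                depth=0,
                alt_observed=0,
                null_vaf=math.nan,
                worst_case_purity=pi_star,
                p_raw=math.nan,
                p_adjusted=math.nan,
                n_tests=n_tests,
                testable=False,
                decision="UNDETERMINED",
                note="NO_COVERAGE",
            ))
    return results
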