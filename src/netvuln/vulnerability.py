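"""Network-vulnerability scoring of microRNAs and the three-step biomarker
filter.

A gene regulated by exactly one microRNA in the condition-specific network is
a single-line regulation: its loss cannot be compensated by a co-regulator,
so such edges are the vulnerable sites of the network. Three per-microRNA
measurements quantify how much vulnerable and functionally important
structure a microRNA controls:

NSR
    number of single-line regulations — how many of the microRNA's targets
    have in-degree exactly 1;
TFP
    transcription-factor gene percentage — the fraction of the microRNA's
    targets that are TF genes;
UTP
    unique-regulated TF gene percentage — the fraction of the microRNA's
    in-degree-1 (unique) targets that are TF genes (0 when NSR = 0).

The filter proceeds in three steps: (1) keep microRNAs whose NSR is
significantly high versus the network-wide NSR population (one-sided
Wilcoxon signed-rank, p < alpha); (2) of those, keep the ones whose TFP is
significantly high versus the network-wide TFP population; (3) keep the ones
with UTP > 0. Survivors of step 3 are the candidate biomarkers.

Two constructions of "significantly high versus the network population" are
provided and selectable everywhere via ``method``:

``"empirical"`` (default)
    the empirical one-sided tail p-value p_i = #{j : score_j >= score_i}/n,
    i.e. the percentile rule — a microRNA is significant when its score sits
    in the upper alpha tail of the network's own score distribution;
``"signed_rank"``
    the differences {score_i - score_j : j != i} (exact zeros removed) enter
    a one-sample Wilcoxon signed-rank test of "median difference > 0". The
    null distribution is enumerated exactly for n <= 25 signs (a tie-aware
    dynamic program equivalent to summing over all 2^n sign vectors) and
    approximated normally with tie and continuity corrections beyond that.
    Beware that in large populations this paired construction rejects for
    any score above the bulk, so it filters far less sharply than the tail
    rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .netbuild import RegulatoryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "VulnerabilityScore",
    "CandidateSet",
    "AllZeroDifferencesError",
    "compute_nsr",
    "compute_tfp",
    "compute_utp",
    "score_network",
    "wilcoxon_signed_rank_one_sided",
    "significant_high",
    "ks_two_sample",
    "utp_filter",
    "microrna_bd_filter",
    "write_scores",
    "read_scores",
    "write_candidates",
    "read_candidates",
]

EXACT_ENUMERATION_MAX_N = 25


class AllZeroDifferencesError(ValueError):
    """All paired differences are exactly zero; the signed-rank p is undefined."""


# ---------------------------------------------------------------------------
# Score containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VulnerabilityScore:
    """Per-microRNA vulnerability measurements and significance calls."""

    mirna: str
    n_targets: int
    nsr: int
    tfp: float
    utp: float
    p_nsr: float | None = None
    p_tfp: float | None = None

    def __post_init__(self) -> None:
        if self.nsr > self.n_targets:
            raise ValueError(f"{self.mirna}: nsr {self.nsr} > n_targets {self.n_targets}")
        if not (0.0 <= self.tfp <= 1.0) or not (0.0 <= self.utp <= 1.0):
            raise ValueError(f"{self.mirna}: tfp/utp outside [0, 1]")
        for frac, count, name in ((self.tfp, self.n_targets, "tfp"),
                                  (self.utp, self.nsr, "utp")):
            prod = frac * count
            if abs(prod - round(prod)) > 1e-9:
                raise ValueError(
                    f"{self.mirna}: {name} * count = {prod} is not an integer"
                )
        if self.nsr == 0 and self.utp != 0.0:
            raise ValueError(f"{self.mirna}: utp must be 0 when nsr is 0")


@dataclass(frozen=True)
class CandidateSet:
    """Trace of the three-step filter."""

    step1: frozenset[str]
    step2: frozenset[str]
    candidates: frozenset[str]
    alpha: float

    def __post_init__(self) -> None:
        if not (self.candidates <= self.step2 <= self.step1):
            raise ValueError("filter trace must be nested: candidates ⊆ step2 ⊆ step1")


# ---------------------------------------------------------------------------
# The three measurements
# ---------------------------------------------------------------------------


def compute_nsr(net: RegulatoryNetwork) -> dict[str, int]:
    """Per-microRNA count of targets with in-degree exactly 1."""
    return {
        m: sum(1 for g in net.targets(m) if net.in_degree(g) == 1)
        for m in net.mirnas
    }


def compute_tfp(net: RegulatoryNetwork, tf_set: set[str]) -> dict[str, float]:
    """Per-microRNA fraction of targets that are TF genes.

    MicroRNAs with zero targets cannot occur in a valid network (node sets
    are edge-derived) and are excluded defensively.
    """
    out: dict[str, float] = {}
    for m in net.mirnas:
        targets = net.targets(m)
        if targets:
            out[m] = len(targets & tf_set) / len(targets)
    return out


def compute_utp(net: RegulatoryNetwork, tf_set: set[str]) -> dict[str, float]:
    """Per-microRNA fraction of unique (in-degree-1) targets that are TFs;
    0 by convention when the microRNA has no unique target."""
    out: dict[str, float] = {}
    for m in net.mirnas:
        unique = {g for g in net.targets(m) if net.in_degree(g) == 1}
        if unique:
            out[m] = len(unique & tf_set) / len(unique)
        else:
            out[m] = 0.0
    return out


def score_network(
    net: RegulatoryNetwork,
    tf_set: set[str],
    alpha: float = 0.05,
    with_significance: bool = True,
    method: str | Callable[[Mapping[str, float]], dict[str, float]] = "empirical",
) -> list[VulnerabilityScore]:
    """All three measurements (plus per-microRNA significance p-values when
    the network has >=3 microRNAs) for every microRNA, sorted by name."""
    nsr = compute_nsr(net)
    tfp = compute_tfp(net, tf_set)
    utp = compute_utp(net, tf_set)
    p_nsr: dict[str, float] = {}
    p_tfp: dict[str, float] = {}
    if with_significance and len(net.mirnas) >= 3:
        p_nsr = population_pvalues({m: float(v) for m, v in nsr.items()}, method)
        p_tfp = population_pvalues(tfp, method)
    return [
        VulnerabilityScore(
            mirna=m,
            n_targets=len(net.targets(m)),
            nsr=nsr[m],
            tfp=tfp[m],
            utp=utp[m],
            p_nsr=p_nsr.get(m),
            p_tfp=p_tfp.get(m),
        )
        for m in sorted(net.mirnas)
    ]


# ---------------------------------------------------------------------------
# One-sided Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank_one_sided(diffs: Sequence[float]) -> float:
    """One-sided signed-rank p-value for H1: median difference > 0.

    Exact zeros are removed before ranking (Wilcoxon's original treatment).
    For n <= 25 remaining differences the p-value is exact: the null
    distribution of the positive rank sum is enumerated over all 2^n equally
    likely sign assignments by dynamic programming on (doubled, so integral)
    average ranks, which handles ties in |diff| exactly. For larger n a
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction is used.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise AllZeroDifferencesError("no differences supplied")
    d = d[d != 0]
    if d.size == 0:
        raise AllZeroDifferencesError("all differences are exactly zero")
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_ENUMERATION_MAX_N:
        return _exact_signed_rank_sf(ranks, w_plus)
    return _approx_signed_rank_sf(ranks, w_plus, n)


def _exact_signed_rank_sf(ranks: np.ndarray, w_plus: float) -> float:
    # doubled average ranks are integers; W+ doubled likewise
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for r in r2:
        shifted = counts[0 : top + 1].copy()
        counts[r : top + r + 1] += shifted
        top += r
    w2 = int(round(2.0 * w_plus))
    return float(counts[w2:].sum() / 2.0 ** len(r2))


def _approx_signed_rank_sf(ranks: np.ndarray, w_plus: float, n: int) -> float:
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return 1.0 if w_plus <= mean else 0.0
    z = (w_plus - mean - 0.5) / math.sqrt(var)
    return float(stats.norm.sf(z))


def signed_rank_population_pvalues(
    scores: Mapping[str, float],
    test: Callable[[Sequence[float]], float] = wilcoxon_signed_rank_one_sided,
) -> dict[str, float]:
    """Signed-rank "significantly high versus the population" p-values.

    For microRNA i the differences {score_i - score_j : j != i, score_j !=
    score_i} are tested for a positive median. A microRNA whose score equals
    every other score gets p = 1 (no evidence of being high). Note that in
    large populations this construction has enormous power: any score above
    the bulk of the population rejects, so it behaves like an
    above-the-median filter rather than a tail filter.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 scores for a population comparison")
    names = list(scores)
    vals = np.array([scores[m] for m in names], dtype=float)
    out: dict[str, float] = {}
    for i, m in enumerate(names):
        diffs = vals[i] - np.delete(vals, i)
        diffs = diffs[diffs != 0]
        if diffs.size == 0:
            out[m] = 1.0
        else:
            out[m] = test(diffs)
    return out


def empirical_tail_pvalues(scores: Mapping[str, float]) -> dict[str, float]:
    """Empirical one-sided tail p-value of each score within the population:
    p_i = #{j : score_j >= score_i} / n (the item itself included, so p is
    never 0 and identical scores share one p). p < alpha selects scores above
    the empirical (1 - alpha) tail — the percentile rule."""
    if len(scores) < 3:
        raise ValueError("need at least 3 scores for a population comparison")
    names = list(scores)
    vals = np.array([scores[m] for m in names], dtype=float)
    n = vals.size
    return {m: float((vals >= vals[i]).sum()) / n for i, m in enumerate(names)}


def population_pvalues(
    scores: Mapping[str, float],
    method: str | Callable[[Mapping[str, float]], dict[str, float]] = "empirical",
) -> dict[str, float]:
    """Per-microRNA p-values for "score is high versus the population".

    ``method`` is ``"empirical"`` (tail/percentile rule, the default),
    ``"signed_rank"`` (one-sided Wilcoxon signed-rank on the paired
    differences against every other microRNA), or a callable mapping the
    whole score dict to a p-value dict.
    """
    if callable(method):
        return method(scores)
    if method == "empirical":
        return empirical_tail_pvalues(scores)
    if method == "signed_rank":
        return signed_rank_population_pvalues(scores)
    raise ValueError(f"unknown method {method!r}")


def significant_high(
    scores: Mapping[str, float],
    alpha: float = 0.05,
    method: str | Callable[[Mapping[str, float]], dict[str, float]] = "empirical",
) -> set[str]:
    """MicroRNAs whose score is significantly high versus the population
    (p < alpha under the chosen construction)."""
    pvals = population_pvalues(scores, method=method)
    return {m for m, p in pvals.items() if p < alpha}


# ---------------------------------------------------------------------------
# Distribution comparison
# ---------------------------------------------------------------------------


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (D, asymptotic p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# The three-step filter
# ---------------------------------------------------------------------------


def utp_filter(step2: set[str], utp: Mapping[str, float]) -> set[str]:
    """Step 3: survivors of step 2 with UTP strictly positive."""
    return {m for m in step2 if utp.get(m, 0.0) > 0.0}


def candidates_from_scores(
    scores: Sequence[VulnerabilityScore], alpha: float = 0.05
) -> CandidateSet:
    """Replay the three-step filter from a pre-computed score table.

    Requires p_nsr and p_tfp to be populated (i.e. the table was produced
    with significance testing on). Produces the same trace as running
    :func:`microrna_bd_filter` on the originating network.
    """
    missing = [s.mirna for s in scores if s.p_nsr is None or s.p_tfp is None]
    if missing:
        raise ValueError(f"scores lack significance p-values: {missing[:5]}")
    step1 = {s.mirna for s in scores if s.p_nsr < alpha}
    step2 = {s.mirna for s in scores if s.p_tfp < alpha} & step1
    cands = utp_filter(step2, {s.mirna: s.utp for s in scores})
    return CandidateSet(
        step1=frozenset(step1),
        step2=frozenset(step2),
        candidates=frozenset(cands),
        alpha=alpha,
    )


def microrna_bd_filter(
    net: RegulatoryNetwork,
    tf_set: set[str],
    alpha: float = 0.05,
    method: str | Callable[[Mapping[str, float]], dict[str, float]] = "empirical",
) -> CandidateSet:
    """Run the full three-step filter on a condition-specific network.

    Step 1 keeps microRNAs with significantly high NSR; step 2 keeps, among
    them, those with significantly high TFP — significance in both steps is
    assessed against the population of ALL network microRNAs, step 1 merely
    restricts which microRNAs may advance; step 3 keeps those with UTP > 0.
    """
    if not net.edges:
        raise ValueError("cannot filter an empty network")
    nsr = {m: float(v) for m, v in compute_nsr(net).items()}
    tfp = compute_tfp(net, tf_set)
    utp = compute_utp(net, tf_set)
    step1 = significant_high(nsr, alpha=alpha, method=method)
    step2 = significant_high(tfp, alpha=alpha, method=method) & step1
    candidates = utp_filter(step2, utp)
    logger.info(
        "filter trace: %d -> step1 %d -> step2 %d -> candidates %d",
        len(net.mirnas), len(step1), len(step2), len(candidates),
    )
    return CandidateSet(
        step1=frozenset(step1),
        step2=frozenset(step2),
        candidates=frozenset(candidates),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Result table IO
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = ["mirna", "n_targets", "nsr", "tfp", "utp", "p_nsr", "p_tfp"]
_CAND_COLUMNS = ["mirna", "passed_step1", "passed_step2", "is_candidate"]


def write_scores(scores: Sequence[VulnerabilityScore], path: str | Path) -> None:
    rows = [
        (s.mirna, s.n_targets, s.nsr, s.tfp, s.utp,
         "" if s.p_nsr is None else s.p_nsr,
         "" if s.p_tfp is None else s.p_tfp)
        for s in scores
    ]
    pd.DataFrame(rows, columns=_SCORE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_scores(path: str | Path) -> list[VulnerabilityScore]:
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str})
    return [
        VulnerabilityScore(
            mirna=r.mirna,
            n_targets=int(r.n_targets),
            nsr=int(r.nsr),
            tfp=float(r.tfp),
            utp=float(r.utp),
            p_nsr=None if pd.isna(r.p_nsr) else float(r.p_nsr),
            p_tfp=None if pd.isna(r.p_tfp) else float(r.p_tfp),
        )
        for r in df.itertuples(index=False)
    ]


def write_candidates(trace: CandidateSet, mirnas: Sequence[str],
                     path: str | Path) -> None:
    """Write the per-microRNA filter trace for all network microRNAs."""
    rows = [
        (m, m in trace.step1, m in trace.step2, m in trace.candidates)
        for m in sorted(mirnas)
    ]
    pd.DataFrame(rows, columns=_CAND_COLUMNS).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path, alpha: float = 0.05) -> CandidateSet:
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str})
    step1 = frozenset(df.loc[df["passed_step1"], "mirna"])
    step2 = frozenset(df.loc[df["passed_step2"], "mirna"])
    cand = frozenset(df.loc[df["is_candidate"], "mirna"])
    return CandidateSet(step1=step1, step2=step2, candidates=cand, alpha=alpha)
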