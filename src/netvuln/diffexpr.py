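"""Two-group differential expression with empirical-Bayes variance shrinkage.

The test statistic is the moderated t: per-feature pooled variances s_g^2 are
shrunk toward a prior s0^2 with weight d0 (the prior degrees of freedom),

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),
    t_g = (mean_B - mean_A) / (s_tilde_g * sqrt(1/n_A + 1/n_B)),

and t_g is referred to a t distribution on d0 + d_g degrees of freedom.
The hyperparameters (d0, s0^2) are either supplied or estimated from the
ensemble of sample variances by the method of moments on log s_g^2, using
digamma/trigamma inversion (the scaled-F hierarchical model: conditional on
sigma_g^2, d_g * s_g^2 / sigma_g^2 ~ chi^2_{d_g}, and 1/sigma_g^2 is drawn
from a scaled chi^2 prior). d0 = 0 recovers the ordinary pooled two-sample
t-test; d0 = +inf pins every posterior variance at s0^2.

Raw p-values are adjusted by Benjamini-Hochberg step-up FDR, probe-level
results are collapsed to genes by keeping each gene's most significant probe,
and a feature is called differentially expressed when adj.p < alpha and
|log2FC| > lfc_cut (strict inequalities).

Expression inputs are assumed to be on log2 scale already; a fold change is a
plain mean difference, B minus A (positive = up in group B).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModeratedTParams",
    "DEResult",
    "log2_fold_change",
    "moderated_t_test",
    "estimate_prior",
    "bh_adjust",
    "adjust_results",
    "collapse_probes",
    "filter_de",
    "run_differential_expression",
    "write_de_table",
    "read_de_table",
]


@dataclass(frozen=True)
class ModeratedTParams:
    """Hyperparameters of the variance prior.

    d0 : prior degrees of freedom (0 = no shrinkage, math.inf = full
         shrinkage to the prior variance).
    s0_sq : prior variance (> 0).
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError(f"d0 must be >= 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


@dataclass(frozen=True)
class DEResult:
    """Per-feature differential-expression outcome."""

    feature_id: str
    log2_fc: float
    t_stat: float
    p_raw: float
    p_adj: float | None = None
    is_de: bool | None = None


def log2_fold_change(mat: ExpressionMatrix, feature: str) -> float:
    """Mean log2 expression difference, group B minus group A."""
    idx = mat.feature_index(feature)
    a = mat.group_columns(mat.group_a_label)
    b = mat.group_columns(mat.group_b_label)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    row = mat.values[idx]
    return float(np.nanmean(row[b]) - np.nanmean(row[a]))


# ---------------------------------------------------------------------------
# Prior estimation (method of moments on log sample variances)
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    trigamma is positive, decreasing and convex on (0, inf), so the iteration
    y <- y + (1 - trigamma(y)*y^2*x') style update converges monotonically
    from the asymptotic start y0 = 0.5 + 1/x.
    """
    if x <= 0:
        return math.inf
    if x > 1e7:  # trigamma(y) ~ 1/y^2 for tiny y
        return 1.0 / math.sqrt(x)
    if x < 1e-6:  # trigamma(y) ~ 1/y for large y
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def estimate_prior(s_sq: np.ndarray, df: np.ndarray) -> ModeratedTParams:
    """Fit (d0, s0_sq) to observed sample variances by moment matching.

    Under the hierarchical model, z_g = log s_g^2 has
    E[z_g] = log s0^2 + digamma(d_g/2) - log(d_g/2) - digamma(d0/2) + log(d0/2)
    and Var[z_g] = trigamma(d_g/2) + trigamma(d0/2); matching the empirical
    mean and variance of z yields the estimates. Excess variance <= 0 gives
    d0 = +inf (all features share one variance).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s_sq > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive variances to estimate the prior")
    s_sq, df = s_sq[ok], df[ok]
    z = np.log(s_sq)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        return ModeratedTParams(d0=math.inf, s0_sq=math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return ModeratedTParams(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# The moderated test
# ---------------------------------------------------------------------------


def moderated_t_test(
    mat: ExpressionMatrix,
    params: ModeratedTParams | Literal["estimate"] = "estimate",
) -> list[DEResult]:
    """Moderated two-sample t-test for every feature; p_adj left unset.

    Missing values (NaN) are allowed; a feature is tested on its non-missing
    samples and excluded (with a log message) when fewer than 2 remain in
    either group. A run where every feature has zero pooled variance is
    degenerate and raises.
    """
    a_cols = mat.group_columns(mat.group_a_label)
    b_cols = mat.group_columns(mat.group_b_label)
    va = mat.values[:, a_cols]
    vb = mat.values[:, b_cols]

    n_a = np.sum(~np.isnan(va), axis=1)
    n_b = np.sum(~np.isnan(vb), axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    if not testable.all():
        skipped = [f for f, t in zip(mat.feature_ids, testable) if not t]
        logger.info("excluding %d feature(s) with <2 samples per group: %s",
                    len(skipped), skipped[:5])
    if not testable.any():
        raise ValueError("no testable features (need >=2 samples per group)")

    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(va, axis=1)
        mean_b = np.nanmean(vb, axis=1)
        var_a = _nanvar_ddof1(va, n_a)
        var_b = _nanvar_ddof1(vb, n_b)

    lfc = mean_b - mean_a
    d_g = n_a + n_b - 2.0
    # pooled variance; groups of size 1 contribute zero sum of squares
    ss = np.where(n_a > 1, (n_a - 1) * var_a, 0.0) + np.where(
        n_b > 1, (n_b - 1) * var_b, 0.0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        s_sq = ss / d_g

    if params == "estimate":
        if np.all(s_sq[testable] == 0):
            raise ValueError("all sample variances are zero; degenerate input")
        params = estimate_prior(s_sq[testable], d_g[testable])
        logger.info("estimated variance prior: d0=%.4g s0_sq=%.4g",
                    params.d0, params.s0_sq)

    d0, s0_sq = params.d0, params.s0_sq
    if math.isinf(d0):
        s_post = np.full_like(s_sq, s0_sq)
        df_total = np.full_like(d_g, np.inf)
    else:
        s_post = (d0 * s0_sq + d_g * s_sq) / (d0 + d_g)
        df_total = d0 + d_g

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s_post * (1.0 / n_a + 1.0 / n_b))
        t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # zero posterior variance: infinite t, p = 0 unless the difference is 0 too
    zero_se = se == 0
    if np.any(zero_se & testable):
        t = np.where(zero_se & (lfc != 0), np.sign(lfc) * np.inf, t)
        t = np.where(zero_se & (lfc == 0), 0.0, t)
        p = np.where(zero_se & (lfc != 0), 0.0, p)
        p = np.where(zero_se & (lfc == 0), 1.0, p)

    out = []
    for i, fid in enumerate(mat.feature_ids):
        if not testable[i]:
            continue
        out.append(
            DEResult(
                feature_id=fid,
                log2_fc=float(lfc[i]),
                t_stat=float(t[i]),
                p_raw=float(p[i]),
            )
        )
    return out


def _nanvar_ddof1(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # slices with n <= 1
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.nanvar(x, axis=1, ddof=1)
    return np.where(n > 1, v, 0.0)


# ---------------------------------------------------------------------------
# Multiple testing, probe collapsing, cut-off filter
# ---------------------------------------------------------------------------


def bh_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_results(results: Sequence[DEResult], alpha: float = 0.05,
                   lfc_cut: float = 1.0) -> list[DEResult]:
    """Fill p_adj (BH) and the DE call for a batch of raw results."""
    p_adj = bh_adjust([r.p_raw for r in results])
    return [
        replace(
            r,
            p_adj=float(q),
            is_de=bool(q < alpha and abs(r.log2_fc) > lfc_cut),
        )
        for r, q in zip(results, p_adj)
    ]


def collapse_probes(
    results: Sequence[DEResult], probe2gene: Mapping[str, str]
) -> list[DEResult]:
    """Collapse probe-level results to one record per gene.

    Each gene keeps the record of its probe with the smallest raw p
    (tie-breaks: largest |t|, then lexicographically smallest probe id);
    the surviving record is re-labelled with the gene symbol. Probes with no
    gene mapping are dropped and logged. Output is ordered by gene symbol.
    """
    best: dict[str, DEResult] = {}
    n_unmapped = 0
    for r in results:
        gene = probe2gene.get(r.feature_id)
        if gene is None:
            n_unmapped += 1
            continue
        cur = best.get(gene)
        if cur is None or _probe_key(r) < _probe_key(cur):
            best[gene] = r
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probe(s)", n_unmapped)
    return [replace(best[g], feature_id=g) for g in sorted(best)]


def _probe_key(r: DEResult) -> tuple[float, float, str]:
    return (r.p_raw, -abs(r.t_stat), r.feature_id)


def filter_de(
    results: Sequence[DEResult], alpha: float = 0.05, lfc_cut: float = 1.0
) -> set[str]:
    """Feature ids passing adj.p < alpha and |log2FC| > lfc_cut (both strict)."""
    missing = [r.feature_id for r in results if r.p_adj is None]
    if missing:
        raise ValueError(f"p_adj not populated for {missing[:5]}")
    return {
        r.feature_id
        for r in results
        if r.p_adj < alpha and abs(r.log2_fc) > lfc_cut
    }


def run_differential_expression(
    mat: ExpressionMatrix,
    alpha: float = 0.05,
    lfc_cut: float = 1.0,
    stat: Literal["moderated", "plain"] = "moderated",
    probe2gene: Mapping[str, str] | None = None,
) -> list[DEResult]:
    """Full DE stage: test, optional probe collapsing, BH adjust, DE call.

    ``stat="plain"`` uses the ordinary pooled t (d0 = 0 with an arbitrary
    prior variance, which the zero weight ignores). Collapsing happens on raw
    p-values, before adjustment, so the gene-level BH is computed on one p per
    gene.
    """
    if stat == "moderated":
        raw = moderated_t_test(mat, "estimate")
    elif stat == "plain":
        raw = moderated_t_test(mat, ModeratedTParams(d0=0.0, s0_sq=1.0))
    else:
        raise ValueError(f"unknown stat {stat!r}")
    if probe2gene is not None:
        raw = collapse_probes(raw, probe2gene)
    return adjust_results(raw, alpha=alpha, lfc_cut=lfc_cut)


# ---------------------------------------------------------------------------
# Result table IO
# ---------------------------------------------------------------------------

_DE_COLUMNS = ["feature_id", "log2_fc", "t_stat", "p_raw", "p_adj", "is_de"]


def write_de_table(results: Sequence[DEResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.feature_id, r.log2_fc, r.t_stat, r.p_raw,
             "" if r.p_adj is None else r.p_adj,
             "" if r.is_de is None else str(r.is_de))
            for r in results
        ],
        columns=_DE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_de_table(path: str | Path) -> list[DEResult]:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    return [
        DEResult(
            feature_id=row.feature_id,
            log2_fc=float(row.log2_fc),
            t_stat=float(row.t_stat),
            p_raw=float(row.p_raw),
            p_adj=None if pd.isna(row.p_adj) else float(row.p_adj),
            is_de=None if pd.isna(row.is_de) else str(row.is_de) == "True",
        )
        for row in df.itertuples(index=False)
    ]
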