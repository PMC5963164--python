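"""Synthetic networks and expression data with planted ground truth.

The network generator emulates the gross topology of curated microRNA-target
corpora: a sparse bipartite graph whose microRNA out-degrees follow a
truncated power law (a few hub microRNAs with hundreds of targets, a long
tail with a handful), a controllable fraction of genes with in-degree
exactly 1 (the single-line regulations the vulnerability analysis keys on),
and a TF label on a random subset of genes. Defaults mirror the scale of a
real reference corpus: mean out-degree ~79 over thousands of genes, about a
quarter of genes single-line, ~10% of genes transcription factors.

"Planted" microRNAs are made vulnerable-and-important on purpose — a block
of their targets is rewired to in-degree 1 and the TF labels around them are
rearranged so they carry a high single-line count, a clearly elevated TF
share among their targets, and at least one TF among their unique targets —
so that the three-step filter has a known answer. Planting rewires existing
edges rather than adding nodes, keeping planted degrees comparable to the
background. Expression simulation draws log2-scale values with additive
group shifts for a chosen set of differential features.

All randomness flows from an explicit integer seed; the same seed reproduces
the same dataset bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from .netbuild import EvidenceSummary, RegulatoryNetwork

logger = logging.getLogger(__name__)

__all__ = ["SyntheticTruth", "simulate_network", "simulate_expression",
           "write_truth", "read_truth"]

# frozen planting profile: scaled to the planted microRNA's out-degree deg —
# min(deg, max(25, deg // 3)) single-line targets, 40% of them TF, and a 35%
# TF share over all targets. These magnitudes echo the score levels at which
# real candidate biomarkers separate from the network background (NSR an
# order of magnitude above the median, TFP three-to-four-fold the background
# TF fraction).
_PLANT_MIN_UNIQUE = 25
_PLANT_UNIQUE_TF_SHARE = 0.4
_PLANT_TFP = 0.35


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    planted_mirnas: frozenset[str]
    tf_fraction: float
    de_features: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def simulate_network(
    n_mirna: int,
    n_gene: int,
    mean_outdegree: float = 79.0,
    singleline_fraction: float = 0.25,
    tf_fraction: float = 0.10,
    n_planted: int = 0,
    seed: int = 0,
    power_exponent: float = 2.0,
) -> tuple[RegulatoryNetwork, set[str], SyntheticTruth]:
    """Simulate a bipartite regulatory network with known vulnerable microRNAs.

    Returns the network, the TF gene set, and the planted truth. MicroRNA
    out-degrees are heavy-tailed (truncated power law with the given
    exponent, rescaled to the requested mean); ``singleline_fraction`` of
    genes receive in-degree exactly 1; the rest receive in-degree >= 2.
    """
    if n_mirna <= 0 or n_gene <= 0:
        raise ValueError("n_mirna and n_gene must be positive")
    for name, frac in (("singleline_fraction", singleline_fraction),
                       ("tf_fraction", tf_fraction)):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if n_planted < 0 or n_planted > n_mirna:
        raise ValueError("n_planted must lie in [0, n_mirna]")
    rng = np.random.default_rng(seed)

    n_single = int(round(singleline_fraction * n_gene))
    n_multi = n_gene - n_single
    n_edges = int(round(mean_outdegree * n_mirna))
    if n_edges < n_single + 2 * n_multi:
        raise ValueError(
            f"infeasible: {n_edges} edges cannot cover {n_single} single-line "
            f"genes plus {n_multi} genes of in-degree >= 2"
        )

    # -- heavy-tailed out-degree propensities ---------------------------
    u = rng.random(n_mirna)
    raw = (1.0 - u) ** (-1.0 / (power_exponent - 1.0))
    k_max = max(10.0, n_gene / 8.0)
    raw = np.minimum(raw, k_max)
    weights = raw / raw.sum()

    mirna_ids = [f"mir-{i:04d}" for i in range(n_mirna)]
    gene_ids = [f"G{j:05d}" for j in range(n_gene)]

    # -- gene in-degree plan --------------------------------------------
    indeg = np.ones(n_gene, dtype=int)
    if n_multi:
        extra = n_edges - n_single - 2 * n_multi
        indeg[n_single:] = 2 + rng.multinomial(extra, np.full(n_multi, 1.0 / n_multi))
        indeg[n_single:] = np.minimum(indeg[n_single:], n_mirna)

    # -- draw distinct regulators per gene ------------------------------
    cumw = np.cumsum(weights)
    cumw[-1] = 1.0
    regulators: list[np.ndarray] = []
    draws = np.searchsorted(cumw, rng.random(int(indeg.sum())), side="right")
    pos = 0
    for j in range(n_gene):
        d = indeg[j]
        regs = np.unique(draws[pos : pos + d])
        pos += d
        while regs.size < min(2, d) or (d >= 2 and regs.size < 2):
            extra_draw = np.searchsorted(cumw, rng.random(d), side="right")
            regs = np.unique(np.concatenate([regs, extra_draw]))[: max(d, 2)]
        regulators.append(regs)

    adj: dict[str, set[str]] = {}  # gene -> regulator mirna set
    for j in range(n_gene):
        adj[gene_ids[j]] = {mirna_ids[i] for i in regulators[j]}

    # -- TF labels -------------------------------------------------------
    n_tf = int(round(tf_fraction * n_gene))
    tf_set: set[str] = (
        {gene_ids[j] for j in rng.choice(n_gene, size=n_tf, replace=False)}
        if n_tf else set()
    )

    # -- plant vulnerable microRNAs -------------------------------------
    targets: dict[str, set[str]] = {}
    for g, regs in adj.items():
        for m in regs:
            targets.setdefault(m, set()).add(g)
    planted = _plant(rng, adj, targets, tf_set, n_planted, gene_ids)

    edges = {
        (m, g): EvidenceSummary(experimental_lt_dbs=frozenset({"synthetic"}))
        for g, regs in adj.items()
        for m in regs
    }
    net = RegulatoryNetwork(edges=edges)
    truth = SyntheticTruth(
        planted_mirnas=frozenset(planted),
        tf_fraction=tf_fraction,
        seed=seed,
    )
    net.log_summary("synthetic network")
    return net, tf_set, truth


def _plant(
    rng: np.random.Generator,
    adj: dict[str, set[str]],
    targets: dict[str, set[str]],
    tf_set: set[str],
    n_planted: int,
    gene_ids: list[str],
) -> set[str]:
    """Rewire the network around ``n_planted`` microRNAs so they carry high
    NSR, high TFP and TF-bearing unique targets. Mutates adj and tf_set."""
    if n_planted == 0:
        return set()
    mirnas = sorted(targets, key=lambda m: len(targets[m]))
    if len(mirnas) < n_planted:
        raise ValueError("fewer realized microRNAs than n_planted")
    # mid-degree band: comparable to the background, big enough to plant into
    lo, hi = int(0.60 * len(mirnas)), int(0.92 * len(mirnas))
    band = mirnas[lo:hi] if hi - lo >= n_planted else mirnas
    planted = {
        str(m) for m in rng.choice(np.array(sorted(band)), size=n_planted,
                                   replace=False)
    }
    planted_target_pool = {g for m in planted for g in targets[m]}
    removable_tfs = sorted(tf_set - planted_target_pool)
    rng.shuffle(removable_tfs)
    protected: set[str] = set()  # unique targets of already-planted microRNAs

    for m in sorted(planted):
        tg = sorted(targets[m] - protected)
        deg = len(targets[m])
        n_uq = min(len(tg), max(2, _PLANT_MIN_UNIQUE, deg // 3))
        n_uq_tf = max(1, int(round(_PLANT_UNIQUE_TF_SHARE * n_uq)))
        # prefer genes that are already single-line to minimize rewiring
        tg.sort(key=lambda g: (len(adj[g]), g))
        unique_block = tg[:n_uq]
        protected.update(unique_block)
        for g in unique_block:
            for other in sorted(adj[g] - {m}):
                adj[g].discard(other)
                targets[other].discard(g)
                _rewire(rng, adj, targets, other, gene_ids, forbidden=protected)
        # TF labels: exactly n_uq_tf TFs inside the unique block ...
        for g in unique_block:
            tf_set.discard(g)
        for j in rng.choice(len(unique_block), size=n_uq_tf, replace=False):
            tf_set.add(unique_block[j])
            if removable_tfs:
                tf_set.discard(removable_tfs.pop())
        # ... and a boosted TF share over all targets
        want_tf = int(round(_PLANT_TFP * deg))
        others = [g for g in tg[n_uq:]]
        cur_tf = n_uq_tf + sum(1 for g in others if g in tf_set)
        candidates_for_tf = [g for g in others if g not in tf_set]
        rng.shuffle(candidates_for_tf)
        while cur_tf < want_tf and candidates_for_tf:
            g = candidates_for_tf.pop()
            tf_set.add(g)
            cur_tf += 1
            if removable_tfs:
                tf_set.discard(removable_tfs.pop())
    return planted


def _rewire(
    rng: np.random.Generator,
    adj: dict[str, set[str]],
    targets: dict[str, set[str]],
    mirna: str,
    gene_ids: list[str],
    forbidden: set[str],
    max_tries: int = 30,
) -> None:
    """Move one edge of ``mirna`` to a gene of in-degree >= 2 (so no new
    single-line regulation appears); give up silently after max_tries."""
    for _ in range(max_tries):
        g = gene_ids[rng.integers(0, len(gene_ids))]
        if g in forbidden or len(adj[g]) < 2 or mirna in adj[g]:
            continue
        adj[g].add(mirna)
        targets.setdefault(mirna, set()).add(g)
        return


def simulate_expression(
    n_features: int,
    n_a: int,
    n_b: int,
    de_features: Mapping[str, float] | None = None,
    sigma: float = 1.0,
    seed: int = 0,
    mu0: float = 8.0,
    feature_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """Simulate a log2-scale two-group expression matrix.

    Group A values are i.i.d. Normal(mu0, sigma^2); group B values are
    shifted by the feature's effect size in log2 units (0 for non-DE
    features). ``de_features`` maps feature ids to effect sizes and must
    reference generated ids (default ids are ``F00000``, ``F00001``, ...).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_features <= 0 or n_a <= 0 or n_b <= 0:
        raise ValueError("counts must be positive")
    if feature_ids is None:
        feature_ids = [f"F{i:05d}" for i in range(n_features)]
    elif len(feature_ids) != n_features:
        raise ValueError("feature_ids length must equal n_features")
    de_features = dict(de_features or {})
    unknown = set(de_features) - set(feature_ids)
    if unknown:
        raise ValueError(f"de_features reference unknown ids: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    values = rng.normal(mu0, sigma, size=(n_features, n_a + n_b))
    effects = np.array([de_features.get(f, 0.0) for f in feature_ids])
    values[:, n_a:] += effects[:, None]
    sample_ids = [f"A{i:03d}" for i in range(n_a)] + [f"B{i:03d}" for i in range(n_b)]
    groups = {s: ("group_A" if s.startswith("A") else "group_B") for s in sample_ids}
    return ExpressionMatrix(
        feature_ids=list(feature_ids),
        sample_ids=sample_ids,
        values=values,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Truth file IO
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    rows = [("planted_mirna", m, "") for m in sorted(truth.planted_mirnas)]
    rows += [("de_feature", f, e) for f, e in sorted(truth.de_features.items())]
    rows += [("tf_fraction", truth.tf_fraction, ""), ("seed", truth.seed, "")]
    pd.DataFrame(rows, columns=["kind", "name", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    planted = frozenset(df.loc[df["kind"] == "planted_mirna", "name"])
    de = {
        r.name: float(r.value)
        for r in df.loc[df["kind"] == "de_feature"].itertuples(index=False)
    }
    tf_frac = float(df.loc[df["kind"] == "tf_fraction", "name"].iloc[0])
    seed = int(df.loc[df["kind"] == "seed", "name"].iloc[0])
    return SyntheticTruth(
        planted_mirnas=planted, tf_fraction=tf_frac, de_features=de, seed=seed
    )
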