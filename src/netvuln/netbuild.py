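"""Assembly of the reference microRNA-mRNA network and its projection onto
differentially expressed feature sets.

The reference network integrates evidence-tagged interaction records from
several source databases under the rule: a (microRNA, gene) pair enters the
network when it is supported by at least one low-throughput experimental
record, or predicted by at least ``min_predicted_support`` distinct
prediction databases. High-throughput experimental records never qualify a
pair on their own (they inflate false positives) and are carried as
annotation only.

Before integration, microRNA names are normalized against a miRBase-style
alias table so that records from databases using different nomenclature
releases collapse onto the same mature name.

The condition-specific network is the induced bipartite subgraph of the
reference on the differentially expressed microRNAs and genes, with nodes
left edgeless removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import AliasTable, EdgeRecord, Evidence, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceSummary",
    "RegulatoryNetwork",
    "normalize_names",
    "integrate_reference",
    "project_condition_network",
    "read_network",
    "write_network",
]


@dataclass(frozen=True)
class EvidenceSummary:
    """Provenance of one integrated (microRNA, gene) pair."""

    experimental_lt_dbs: frozenset[str] = frozenset()
    predicted_dbs: frozenset[str] = frozenset()
    ht_dbs: frozenset[str] = frozenset()

    @property
    def n_experimental_lt(self) -> int:
        return len(self.experimental_lt_dbs)


@dataclass
class RegulatoryNetwork:
    """Bipartite microRNA -> gene regulatory network with evidence provenance.

    Node sets are derived from the edge set, so the no-isolated-node
    invariant holds by construction.
    """

    edges: dict[tuple[str, str], EvidenceSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        self.mirnas: set[str] = {m for m, _ in self.edges}
        self.genes: set[str] = {g for _, g in self.edges}
        self._targets: dict[str, set[str]] = {m: set() for m in self.mirnas}
        self._regulators: dict[str, set[str]] = {g: set() for g in self.genes}
        for m, g in self.edges:
            self._targets[m].add(g)
            self._regulators[g].add(m)

    # -- queries ---------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets(self, mirna: str) -> set[str]:
        return self._targets.get(mirna, set())

    def regulators(self, gene: str) -> set[str]:
        return self._regulators.get(gene, set())

    def in_degree(self, gene: str) -> int:
        return len(self._regulators.get(gene, ()))

    def to_networkx(self) -> nx.DiGraph:
        """Directed bipartite view (edges point microRNA -> gene)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.mirnas, bipartite="mirna")
        g.add_nodes_from(self.genes, bipartite="gene")
        g.add_edges_from(self.edges)
        return g

    def log_summary(self, label: str = "network") -> None:
        logger.info(
            "%s: %d microRNAs, %d genes, %d edges",
            label, len(self.mirnas), len(self.genes), self.n_edges,
        )


# ---------------------------------------------------------------------------
# Nomenclature normalization
# ---------------------------------------------------------------------------


def normalize_names(
    edges: Sequence[EdgeRecord], aliases: AliasTable
) -> list[EdgeRecord]:
    """Replace each record's microRNA name by its canonical mature name.

    Records whose name has no canonical mapping are dropped; the drop count
    and example names are reported through the module logger. Duplicate
    records created by the renaming are retained (integration counts
    evidence over them later).
    """
    out: list[EdgeRecord] = []
    unmapped: list[str] = []
    for rec in edges:
        canon = aliases.canonical(rec.mirna)
        if canon is None:
            unmapped.append(rec.mirna)
            continue
        if canon == rec.mirna:
            out.append(rec)
        else:
            out.append(EdgeRecord(canon, rec.gene, rec.source_db, rec.evidence))
    if unmapped:
        logger.warning(
            "normalize_names: dropped %d record(s) with unmappable microRNA "
            "names (examples: %s)",
            len(unmapped), sorted(set(unmapped))[:5],
        )
    return out


# ---------------------------------------------------------------------------
# Evidence integration
# ---------------------------------------------------------------------------


def integrate_reference(
    edges: Iterable[EdgeRecord], min_predicted_support: int = 2
) -> RegulatoryNetwork:
    """Integrate evidence records into the reference network.

    A pair qualifies with >=1 low-throughput experimental record OR with
    predictions from >= ``min_predicted_support`` distinct source databases.
    Evidence summaries are merged across all records of a pair, qualified or
    not; non-qualifying pairs are discarded.
    """
    if min_predicted_support < 1:
        raise ValueError("min_predicted_support must be >= 1")
    lt: dict[tuple[str, str], set[str]] = {}
    pred: dict[tuple[str, str], set[str]] = {}
    ht: dict[tuple[str, str], set[str]] = {}
    for rec in edges:
        key = (rec.mirna, rec.gene)
        if rec.evidence is Evidence.EXPERIMENTAL_LOW_THROUGHPUT:
            lt.setdefault(key, set()).add(rec.source_db)
        elif rec.evidence is Evidence.PREDICTED:
            pred.setdefault(key, set()).add(rec.source_db)
        else:
            ht.setdefault(key, set()).add(rec.source_db)
    qualified = {k for k in lt} | {
        k for k, dbs in pred.items() if len(dbs) >= min_predicted_support
    }
    net = RegulatoryNetwork(
        edges={
            k: EvidenceSummary(
                experimental_lt_dbs=frozenset(lt.get(k, ())),
                predicted_dbs=frozenset(pred.get(k, ())),
                ht_dbs=frozenset(ht.get(k, ())),
            )
            for k in sorted(qualified)
        }
    )
    net.log_summary("reference network")
    return net


def project_condition_network(
    ref: RegulatoryNetwork, de_mirnas: set[str], de_genes: set[str]
) -> RegulatoryNetwork:
    """Induced bipartite subgraph of ``ref`` on the DE microRNAs x DE genes.

    Nodes that lose all their edges disappear (node sets are edge-derived).
    An empty intersection on either side yields an empty network with a
    warning rather than an error.
    """
    keep_m = de_mirnas & ref.mirnas
    keep_g = de_genes & ref.genes
    if not keep_m or not keep_g:
        logger.warning(
            "projection is empty (%d DE microRNAs and %d DE genes found in "
            "the reference)", len(keep_m), len(keep_g),
        )
        return RegulatoryNetwork(edges={})
    net = RegulatoryNetwork(
        edges={
            (m, g): summary
            for (m, g), summary in ref.edges.items()
            if m in keep_m and g in keep_g
        }
    )
    net.log_summary("condition-specific network")
    return net


# ---------------------------------------------------------------------------
# Network file IO (TSV: mirna, gene, n_experimental_lt, predicted_dbs[, ...])
# ---------------------------------------------------------------------------

_NET_COLUMNS = ["mirna", "gene", "n_experimental_lt", "predicted_dbs",
                "experimental_lt_dbs", "ht_dbs"]


def write_network(net: RegulatoryNetwork, path: str | Path) -> None:
    """Serialize a network to TSV with semicolon-joined db lists."""
    rows = [
        (
            m,
            g,
            s.n_experimental_lt,
            ";".join(sorted(s.predicted_dbs)),
            ";".join(sorted(s.experimental_lt_dbs)),
            ";".join(sorted(s.ht_dbs)),
        )
        for (m, g), s in sorted(net.edges.items())
    ]
    pd.DataFrame(rows, columns=_NET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> RegulatoryNetwork:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("mirna", "gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    edges: dict[tuple[str, str], EvidenceSummary] = {}
    for row in df.itertuples(index=False):
        key = (row.mirna, row.gene)
        if key in edges:
            raise FormatError(f"{path}: duplicate edge {key}")
        lt_dbs = _split(getattr(row, "experimental_lt_dbs", ""))
        n_lt = int(getattr(row, "n_experimental_lt", 0) or 0)
        if not lt_dbs and n_lt:
            # older exports carry only the count; make up stable placeholders
            lt_dbs = frozenset(f"lt_db_{i + 1}" for i in range(n_lt))
        edges[key] = EvidenceSummary(
            experimental_lt_dbs=lt_dbs,
            predicted_dbs=_split(getattr(row, "predicted_dbs", "")),
            ht_dbs=_split(getattr(row, "ht_dbs", "")),
        )
    return RegulatoryNetwork(edges=edges)


def _split(joined: str) -> frozenset[str]:
    joined = (joined or "").strip()
    return frozenset(x for x in joined.split(";") if x)
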