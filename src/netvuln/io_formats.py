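"""Readers and writers for the canonical flat-file formats.

Every external table consumed or produced by the pipeline goes through this
module: microRNA-target edge tables, transcription-factor gene lists, miRNA
alias maps, expression matrices with two-group sample annotations, and the
result tables (differential expression, vulnerability scores, candidate
traces, network exports).

Canonical dialect is TSV with a header line. A column-mapping ``dialect``
parameter lets edge tables exported from different interaction databases be
read without prior reshaping. Gene symbols are upper-cased on ingest; microRNA
names keep their case (miRBase convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Evidence",
    "EdgeRecord",
    "AliasTable",
    "ExpressionMatrix",
    "FormatError",
    "read_edge_table",
    "write_edge_table",
    "read_tf_list",
    "write_tf_list",
    "read_alias_table",
    "read_expression",
    "write_expression",
    "read_name_list",
    "write_name_list",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


class Evidence(str, Enum):
    """Evidence class of a microRNA-target interaction record."""

    EXPERIMENTAL_LOW_THROUGHPUT = "experimental_low_throughput"
    EXPERIMENTAL_HIGH_THROUGHPUT = "experimental_high_throughput"
    PREDICTED = "predicted"


@dataclass(frozen=True)
class EdgeRecord:
    """One microRNA-target interaction claim from a source database.

    Attributes
    ----------
    mirna : str
        MicroRNA name as it appears in the source (possibly an alias that is
        normalized later against a miRBase-style alias table).
    gene : str
        Target gene symbol, upper-cased.
    source_db : str
        Identifier of the originating interaction database.
    evidence : Evidence
        Whether the claim is low-throughput experimental, high-throughput
        experimental, or computationally predicted.
    """

    mirna: str
    gene: str
    source_db: str
    evidence: Evidence

    def __post_init__(self) -> None:
        if not self.mirna:
            raise FormatError("EdgeRecord.mirna must be non-empty")
        if not self.gene:
            raise FormatError("EdgeRecord.gene must be non-empty")
        if not isinstance(self.evidence, Evidence):
            raise FormatError(f"unknown evidence class: {self.evidence!r}")


@dataclass(frozen=True)
class AliasTable:
    """Mapping from microRNA aliases to canonical mature names.

    Canonical names must be fixed points of the mapping (``canonical(c) == c``
    for every canonical ``c`` that appears as a value), and no alias may map
    to two different canonicals.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for alias, canon in self.mapping.items():
            target = self.mapping.get(canon, canon)
            if target != canon:
                raise FormatError(
                    f"canonical name {canon!r} (for alias {alias!r}) is itself "
                    f"remapped to {target!r}; canonicals must be fixed points"
                )

    def canonical(self, name: str) -> str | None:
        """Canonical mature name for ``name``, or None if unmappable.

        A name that is already canonical (a value of the mapping) maps to
        itself even when not listed as its own alias.
        """
        hit = self.mapping.get(name)
        if hit is not None:
            return hit
        if name in self._canonical_set():
            return name
        return None

    def _canonical_set(self) -> set[str]:
        cached = getattr(self, "_canon_cache", None)
        if cached is None:
            cached = set(self.mapping.values())
            object.__setattr__(self, "_canon_cache", cached)
        return cached


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values for features x samples with group labels.

    ``groups`` maps each sample id to one of two condition labels;
    ``group_a_label``/``group_b_label`` fix which label plays the role of the
    reference group (A) and the contrast group (B). Fold changes downstream
    are B minus A.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]
    group_a_label: str = "group_A"
    group_b_label: str = "group_B"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_feat, n_samp = self.values.shape
        if n_feat != len(self.feature_ids) or n_samp != len(self.sample_ids):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise FormatError(f"samples without a group label: {missing[:5]}")
        labels = {self.groups[s] for s in self.sample_ids}
        expected = {self.group_a_label, self.group_b_label}
        if not labels <= expected:
            raise FormatError(f"unexpected group labels {labels - expected}")
        if labels != expected:
            raise FormatError(f"a group has zero samples (present: {labels})")
        # NaN marks a missing measurement and is tolerated; infinities are not
        if np.isinf(self.values).any():
            raise FormatError("expression values must be finite or missing (NaN)")

    # -- convenience accessors -------------------------------------------

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == label]

    def group_columns(self, label: str) -> np.ndarray:
        """Column indices of the samples carrying ``label``."""
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.groups[s] == label],
            dtype=int,
        )

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


# ---------------------------------------------------------------------------
# Edge tables
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("mirna", "gene", "source_db", "evidence")


def read_edge_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[EdgeRecord]:
    """Read an interaction edge table into :class:`EdgeRecord` objects.

    Parameters
    ----------
    path
        TSV file with a header line.
    dialect
        Optional mapping from the canonical column names
        (``mirna, gene, source_db, evidence``) to the column names actually
        used in the file. Unmapped canonical names are looked up verbatim.

    Rows with an empty microRNA or gene field are rejected with a
    row-numbered warning; the remaining rows are returned in file order.
    An evidence label outside the three known classes is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    dialect = dict(dialect or {})
    colmap = {canon: dialect.get(canon, canon) for canon in _EDGE_COLUMNS}
    for canon, actual in colmap.items():
        if actual not in df.columns:
            raise FormatError(
                f"{path}: required column {actual!r} (for {canon!r}) not found; "
                f"available: {list(df.columns)}"
            )
    records: list[EdgeRecord] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        vals = {canon: getattr(row, actual).strip() for canon, actual in colmap.items()}
        if not vals["mirna"] or not vals["gene"]:
            logger.warning("%s: row %d rejected (empty mirna or gene field)", path, i)
            n_rejected += 1
            continue
        try:
            evidence = Evidence(vals["evidence"])
        except ValueError:
            raise FormatError(
                f"{path}: row {i}: unknown evidence label {vals['evidence']!r}"
            ) from None
        records.append(
            EdgeRecord(
                mirna=vals["mirna"],
                gene=vals["gene"].upper(),
                source_db=vals["source_db"],
                evidence=evidence,
            )
        )
    if n_rejected:
        logger.warning("%s: %d malformed rows rejected", path, n_rejected)
    return records


def write_edge_table(records: Iterable[EdgeRecord], path: str | Path) -> None:
    """Write edge records to the canonical TSV layout (columns ``mirna,
    gene, source_db, evidence``)."""
    df = pd.DataFrame(
        [(r.mirna, r.gene, r.source_db, r.evidence.value) for r in records],
        columns=list(_EDGE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene lists / name lists
# ---------------------------------------------------------------------------


def read_tf_list(path: str | Path) -> set[str]:
    """Read a transcription-factor gene list (one symbol per line).

    Symbols are upper-cased and deduplicated; blank lines and ``#`` comments
    are ignored. An empty result is a warning, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    symbols: set[str] = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols.add(line.upper())
    if not symbols:
        logger.warning("%s: TF list is empty", path)
    return symbols


def write_tf_list(symbols: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in sorted(symbols)))


def read_name_list(path: str | Path) -> set[str]:
    """Read a generic name list (one entry per line, ``#`` comments), keeping
    case (used for microRNA name sets such as DE lists or reported
    biomarkers)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    names = {
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.strip().startswith("#")
    }
    return names


def write_name_list(names: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{n}\n" for n in sorted(names)))


# ---------------------------------------------------------------------------
# Alias tables
# ---------------------------------------------------------------------------


def read_alias_table(path: str | Path) -> AliasTable:
    """Read a two-column TSV (``alias``, ``canonical``) into an AliasTable.

    An alias listed with two different canonicals is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("alias", "canonical"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    mapping: dict[str, str] = {}
    for i, (alias, canon) in enumerate(zip(df["alias"], df["canonical"]), start=2):
        alias, canon = alias.strip(), canon.strip()
        if not alias or not canon:
            raise FormatError(f"{path}: row {i}: empty alias or canonical")
        if alias in mapping and mapping[alias] != canon:
            raise FormatError(
                f"{path}: alias {alias!r} maps to both {mapping[alias]!r} and {canon!r}"
            )
        mapping[alias] = canon
    return AliasTable(mapping=mapping)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression(
    matrix_path: str | Path,
    groups_path: str | Path,
    group_a_label: str | None = None,
    group_b_label: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix plus its two-group sample annotation.

    The matrix is TSV: first column feature id, remaining columns samples.
    The group file is TSV with columns ``sample_id, group``. Samples present
    in the matrix but absent from the group file are dropped with a warning.
    When the group labels are not given explicitly they are taken from the
    annotation: the literal labels ``group_A``/``group_B`` if present,
    otherwise the two labels in sorted order (first = A).
    """
    matrix_path, groups_path = Path(matrix_path), Path(groups_path)
    for p in (matrix_path, groups_path):
        if not p.exists():
            raise FileNotFoundError(p)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise FormatError(f"{matrix_path}: non-numeric expression column(s) {bad}")
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "group"):
        if col not in gdf.columns:
            raise FormatError(f"{groups_path}: missing column {col!r}")
    groups = dict(zip(gdf["sample_id"], gdf["group"]))

    labelled = [s for s in df.columns if s in groups]
    dropped = [s for s in df.columns if s not in groups]
    if dropped:
        logger.warning(
            "%s: dropping %d unlabelled sample(s): %s",
            matrix_path,
            len(dropped),
            dropped[:5],
        )
    df = df[labelled]
    present = sorted({groups[s] for s in labelled})
    if group_a_label is None and group_b_label is None:
        if set(present) == {"group_A", "group_B"}:
            group_a_label, group_b_label = "group_A", "group_B"
        elif len(present) == 2:
            group_a_label, group_b_label = present
        else:
            raise FormatError(
                f"{groups_path}: expected exactly 2 group labels, found {present}"
            )
    elif group_a_label is None or group_b_label is None:
        raise ValueError("give both group labels or neither")
    return ExpressionMatrix(
        feature_ids=[str(f) for f in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        groups={s: groups[s] for s in df.columns},
        group_a_label=group_a_label,
        group_b_label=group_b_label,
    )


def write_expression(mat: ExpressionMatrix, matrix_path: str | Path,
                     groups_path: str | Path) -> None:
    """Write matrix + group annotation in the layout ``read_expression``
    consumes. Floats are written with enough digits to round-trip."""
    df = mat.to_frame()
    df.index.name = "feature_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.17g")
    pd.DataFrame(
        {"sample_id": mat.sample_ids, "group": [mat.groups[s] for s in mat.sample_ids]}
    ).to_csv(groups_path, sep="\t", index=False)
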