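"""End-to-end pipeline orchestration.

Runs the full biomarker discovery chain from a flat key=value configuration:
differential expression on the microRNA and mRNA matrices, reference-network
integration, projection onto the DE feature sets, vulnerability scoring, the
three-step filter, and ROC/precision evaluation. Each stage writes its
result table into the output directory and a JSON manifest records the
configuration, input checksums and package version so a run can be audited
and reproduced. With ``resume=True`` a stage whose output file already
exists is read back instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import diffexpr, evaluate, io_formats, netbuild, vulnerability

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "PipelineResult", "load_config", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all paths are input files)."""

    edges: list[str]
    tf: str
    mirna_matrix: str
    mirna_groups: str
    mrna_matrix: str
    mrna_groups: str
    outdir: str
    aliases: str | None = None
    probe2gene: str | None = None
    reported: str | None = None
    alpha: float = 0.05
    lfc_cut: float = 1.0
    min_predicted_support: int = 2
    stat: str = "moderated"
    seed: int | None = None
    group_a_label: str | None = None
    group_b_label: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.lfc_cut < 0:
            raise ValueError("lfc_cut must be >= 0")
        if self.stat not in ("moderated", "plain"):
            raise ValueError("stat must be 'moderated' or 'plain'")

    def input_paths(self) -> dict[str, str]:
        paths: dict[str, str] = {}
        for i, e in enumerate(self.edges):
            paths[f"edges[{i}]"] = e
        for key in ("tf", "mirna_matrix", "mirna_groups", "mrna_matrix",
                    "mrna_groups", "aliases", "probe2gene", "reported"):
            val = getattr(self, key)
            if val is not None:
                paths[key] = val
        return paths

    def validate_paths(self) -> None:
        missing = [f"{k}={v}" for k, v in self.input_paths().items()
                   if not Path(v).exists()]
        if missing:
            raise FileNotFoundError("missing input file(s): " + ", ".join(missing))


_LIST_KEYS = {"edges"}
_FLOAT_KEYS = {"alpha", "lfc_cut"}
_INT_KEYS = {"min_predicted_support", "seed"}


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file (# comments allowed).

    The ``edges`` value may list several files separated by semicolons.
    """
    raw: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _LIST_KEYS:
            raw[key] = [v.strip() for v in value.split(";") if v.strip()]
        elif key in _FLOAT_KEYS:
            raw[key] = float(value)
        elif key in _INT_KEYS:
            raw[key] = int(value)
        else:
            raw[key] = value
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)  # type: ignore[arg-type]


@dataclass
class PipelineResult:
    de_mirnas: set[str]
    de_genes: set[str]
    network: netbuild.RegulatoryNetwork
    scores: list[vulnerability.VulnerabilityScore]
    trace: vulnerability.CandidateSet
    precision: float | None
    outputs: dict[str, Path] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, resume: bool = False) -> PipelineResult:
    """Execute every stage in order; returns the in-memory results and writes
    de_mirna.tsv, de_mrna.tsv, network_ref.tsv, network.tsv, scores.tsv,
    candidates.tsv, eval.tsv and manifest.json under ``config.outdir``."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {
        name: outdir / f"{name}.tsv"
        for name in ("de_mirna", "de_mrna", "network_ref", "network",
                     "scores", "candidates", "eval")
    }

    aliases = (io_formats.read_alias_table(config.aliases)
               if config.aliases else io_formats.AliasTable({}))

    def canon(name: str) -> str:
        return aliases.canonical(name) or name

    # -- stage: differential expression (microRNA) ----------------------
    try:
        mirna_mat = io_formats.read_expression(
            config.mirna_matrix, config.mirna_groups,
            config.group_a_label, config.group_b_label,
        )
        if resume and out["de_mirna"].exists():
            de_mirna = diffexpr.read_de_table(out["de_mirna"])
        else:
            de_mirna = diffexpr.run_differential_expression(
                mirna_mat, alpha=config.alpha, lfc_cut=config.lfc_cut,
                stat=config.stat,  # type: ignore[arg-type]
            )
            diffexpr.write_de_table(de_mirna, out["de_mirna"])
        de_mirnas = {canon(m) for m in diffexpr.filter_de(
            de_mirna, config.alpha, config.lfc_cut)}
    except Exception as exc:  # noqa: BLE001
        raise StageError("diffexpr_mirna", exc) from exc

    # -- stage: differential expression (mRNA) ---------------------------
    try:
        mrna_mat = io_formats.read_expression(
            config.mrna_matrix, config.mrna_groups,
            config.group_a_label, config.group_b_label,
        )
        probe2gene = None
        if config.probe2gene:
            table = io_formats.read_alias_table(config.probe2gene)
            probe2gene = {a: c.upper() for a, c in table.mapping.items()}
        if resume and out["de_mrna"].exists():
            de_mrna = diffexpr.read_de_table(out["de_mrna"])
        else:
            de_mrna = diffexpr.run_differential_expression(
                mrna_mat, alpha=config.alpha, lfc_cut=config.lfc_cut,
                stat=config.stat,  # type: ignore[arg-type]
                probe2gene=probe2gene,
            )
            diffexpr.write_de_table(de_mrna, out["de_mrna"])
        de_genes = diffexpr.filter_de(de_mrna, config.alpha, config.lfc_cut)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("diffexpr_mrna", exc) from exc

    # -- stage: network construction + projection ------------------------
    try:
        if resume and out["network"].exists():
            ref = netbuild.read_network(out["network_ref"])
            net = netbuild.read_network(out["network"])
        else:
            records: list[io_formats.EdgeRecord] = []
            for edge_path in config.edges:
                records.extend(io_formats.read_edge_table(edge_path))
            if config.aliases:
                records = netbuild.normalize_names(records, aliases)
            ref = netbuild.integrate_reference(
                records, min_predicted_support=config.min_predicted_support)
            netbuild.write_network(ref, out["network_ref"])
            net = netbuild.project_condition_network(ref, de_mirnas, de_genes)
            netbuild.write_network(net, out["network"])
    except Exception as exc:  # noqa: BLE001
        raise StageError("netbuild", exc) from exc

    # -- stage: vulnerability scoring + filter ----------------------------
    try:
        tf_set = io_formats.read_tf_list(config.tf)
        scores = vulnerability.score_network(net, tf_set, alpha=config.alpha)
        vulnerability.write_scores(scores, out["scores"])
        trace = vulnerability.microrna_bd_filter(net, tf_set, alpha=config.alpha)
        vulnerability.write_candidates(trace, sorted(net.mirnas), out["candidates"])
    except Exception as exc:  # noqa: BLE001
        raise StageError("score", exc) from exc

    # -- stage: evaluation ------------------------------------------------
    try:
        reported = (io_formats.read_name_list(config.reported)
                    if config.reported else set())
        lfc_by_canon = {canon(r.feature_id): r.log2_fc for r in de_mirna}
        feature_by_canon = {canon(f): f for f in mirna_mat.feature_ids}
        labels = [
            1 if mirna_mat.groups[s] == mirna_mat.group_b_label else 0
            for s in mirna_mat.sample_ids
        ]
        rows = []
        precision = None
        for m in sorted(trace.candidates):
            feat = feature_by_canon.get(m)
            if feat is None:
                logger.warning("candidate %s not found in the microRNA matrix", m)
                continue
            idx = mirna_mat.feature_index(feat)
            res = evaluate.roc_auc(
                mirna_mat.values[idx], labels,
                orient_by=lfc_by_canon.get(m, "none"), mirna=m,
            )
            rows.append((m, res.auc, res.oriented, m in reported))
        if trace.candidates and reported:
            precision = evaluate.prediction_precision(set(trace.candidates), reported)
        with open(out["eval"], "w") as fh:
            fh.write("mirna\tauc_oriented\tflipped\tin_reported\n")
            for m, auc, flipped, in_rep in rows:
                fh.write(f"{m}\t{auc:.6f}\t{flipped}\t{in_rep}\n")
            if precision is not None:
                fh.write(f"# prediction_precision\t{precision:.6f}\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError("evaluate", exc) from exc

    manifest = {
        "package": "netvuln",
        "version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "input_sha256": {k: _sha256(v) for k, v in config.input_paths().items()},
        "n_de_mirnas": len(de_mirnas),
        "n_de_genes": len(de_genes),
        "network": {"mirnas": len(net.mirnas), "genes": len(net.genes),
                    "edges": net.n_edges},
        "candidates": sorted(trace.candidates),
        "precision": precision,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return PipelineResult(
        de_mirnas=de_mirnas,
        de_genes=de_genes,
        network=net,
        scores=scores,
        trace=trace,
        precision=precision,
        outputs={**out, "manifest": outdir / "manifest.json"},
    )
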