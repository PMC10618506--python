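"""The funnel: encode, compare matrices, build trees, validate with metrics.

The staged evaluation works like a funnel. First every configured encoding
turns the input sequences into fixed-length descriptors, a pairwise
Euclidean distance matrix, and a min-max-normalized matrix. Each reference
(an external multiple alignment reduced to a Jukes-Cantor matrix, or a
precomputed matrix) is normalized the same way. Encodings are then ranked
per reference by the Euclidean distance between matrices — smallest
distance means most similar to the reference. Finally NJ trees are built
from every matrix and the nine tree metrics are computed for every
(encoding, reference) pair; an encoding is shortlisted when its tree-metric
values sit below the across-the-board average for a majority of the nine
metrics. With the default seventeen encodings and four references, each
metric's overall average aggregates 17 x 4 = 68 values.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .distances import (
    DistanceMatrix,
    jukes_cantor_matrix,
    matrix_euclidean,
    normalize_minmax,
    pairwise_euclidean,
    read_matrix_csv,
    write_matrix_csv,
)
from .encoders import SCHEMES, EncodingSpec, descriptor_batch
from .njtree import neighbor_joining
from .seqio import SequenceSet, read_fasta, tree_to_newick
from .tree_metrics import METRIC_NAMES, compare_all

logger = logging.getLogger(__name__)


class FunnelError(ValueError):
    pass


@dataclass
class FunnelConfig:
    """What to run: encodings, references, descriptor parameters.

    References may be given as aligned FASTA paths (``ref_alignments``),
    matrix CSV paths (``ref_matrix_paths``), or in-memory objects
    (``ref_alignment_sets`` mapping name -> aligned SequenceSet,
    ``ref_matrices`` mapping name -> DistanceMatrix). At least one
    reference and one encoding are required.
    """

    encodings: list[EncodingSpec] = field(
        default_factory=lambda: [EncodingSpec(s) for s in SCHEMES]
    )
    ref_alignments: list[str] = field(default_factory=list)
    ref_matrix_paths: list[str] = field(default_factory=list)
    ref_alignment_sets: dict[str, SequenceSet] = field(default_factory=dict)
    ref_matrices: dict[str, DistanceMatrix] = field(default_factory=dict)
    moment_order: int = 4
    spectrum_length: int | None = None
    shortlist_majority: int = 5  # of the nine metrics
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.encodings:
            raise FunnelError("at least one encoding required")
        names = [e.name for e in self.encodings]
        if len(set(names)) != len(names):
            raise FunnelError(f"duplicate encodings in config: {names}")
        n_refs = (
            len(self.ref_alignments)
            + len(self.ref_matrix_paths)
            + len(self.ref_alignment_sets)
            + len(self.ref_matrices)
        )
        if n_refs == 0:
            raise FunnelError("at least one reference source required")


@dataclass
class RankingReport:
    """Everything the funnel measures, in long-format tables.

    ``ranking``: one row per (encoding, reference) with the matrix-level
    Euclidean distance and the within-reference rank (1 = most similar).
    ``tree_metrics``: one row per (encoding, reference, metric).
    ``overall_average``: per-metric mean over all (encoding, reference)
    cells. ``shortlist``: encodings below the overall average for at least
    ``shortlist_majority`` of the nine metrics. ``dropped``: encodings that
    failed with the reason.
    """

    ranking: pd.DataFrame
    tree_metrics: pd.DataFrame
    overall_average: pd.Series
    shortlist: list[str]
    dropped: dict[str, str]
    encoding_matrices: dict[str, DistanceMatrix] = field(default_factory=dict)
    reference_matrices: dict[str, DistanceMatrix] = field(default_factory=dict)
    encoding_trees: dict[str, dendropy.Tree] = field(default_factory=dict)
    reference_trees: dict[str, dendropy.Tree] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        """Aggregated (encoding, reference) cells per metric."""
        return len(self.ranking)


def _resolve_references(cfg: FunnelConfig) -> dict[str, DistanceMatrix]:
    refs: dict[str, DistanceMatrix] = {}

    def _add(name: str, matrix: DistanceMatrix) -> None:
        if name in refs:
            raise FunnelError(f"duplicate reference name {name!r}")
        refs[name] = normalize_minmax(matrix)

    for path in cfg.ref_alignments:
        aln = read_fasta(path, aligned=True)
        _add(Path(path).stem, jukes_cantor_matrix(aln))
    for path in cfg.ref_matrix_paths:
        _add(Path(path).stem, read_matrix_csv(path))
    for name, aln in cfg.ref_alignment_sets.items():
        _add(name, jukes_cantor_matrix(aln))
    for name, m in cfg.ref_matrices.items():
        _add(name, m)
    return refs


def run_funnel(seqs: SequenceSet, cfg: FunnelConfig) -> RankingReport:
    """Run the full staged comparison and return a :class:`RankingReport`.

    An encoding that fails (e.g. a sequence below the scheme minimum) is
    dropped from the report with a logged reason rather than aborting the
    sweep.
    """
    t0 = time.perf_counter()
    references = _resolve_references(cfg)
    logger.info("funnel: %d references resolved (%.2fs)", len(references),
                time.perf_counter() - t0)

    enc_matrices: dict[str, DistanceMatrix] = {}
    dropped: dict[str, str] = {}
    for espec in cfg.encodings:
        t1 = time.perf_counter()
        try:
            descs = descriptor_batch(
                espec, seqs, J=cfg.moment_order, m=cfg.spectrum_length
            )
            enc_matrices[espec.name] = normalize_minmax(
                pairwise_euclidean(descs, seqs.ids)
            )
        except Exception as exc:
            logger.warning("funnel: dropping encoding %s: %s", espec.name, exc)
            dropped[espec.name] = str(exc)
            continue
        logger.info("funnel: encoded %s (%.2fs)", espec.name, time.perf_counter() - t1)
    if not enc_matrices:
        raise FunnelError(f"all encodings failed: {dropped}")

    rank_rows = []
    for ref_name, ref_m in references.items():
        dists = {
            name: matrix_euclidean(ref_m, m) for name, m in enc_matrices.items()
        }
        order = sorted(dists, key=lambda k: (dists[k], k))
        for name in enc_matrices:
            rank_rows.append(
                {
                    "encoding": name,
                    "reference": ref_name,
                    "euclidean": dists[name],
                    "rank": order.index(name) + 1,
                }
            )
    ranking = pd.DataFrame(rank_rows)

    t2 = time.perf_counter()
    enc_trees = {name: neighbor_joining(m) for name, m in enc_matrices.items()}
    ref_trees = {name: neighbor_joining(m) for name, m in references.items()}
    logger.info("funnel: %d NJ trees (%.2fs)", len(enc_trees) + len(ref_trees),
                time.perf_counter() - t2)

    t3 = time.perf_counter()
    metric_rows = []
    for ref_name, ref_tree in ref_trees.items():
        for enc_name, enc_tree in enc_trees.items():
            for res in compare_all(enc_tree, ref_tree):
                metric_rows.append(
                    {
                        "encoding": enc_name,
                        "reference": ref_name,
                        "metric": res.metric,
                        "value": res.value,
                        "normalized": res.normalized,
                    }
                )
    tree_metrics = pd.DataFrame(metric_rows)
    logger.info("funnel: tree metrics (%.2fs)", time.perf_counter() - t3)

    overall = tree_metrics.groupby("metric")["value"].mean()
    per_enc = tree_metrics.groupby(["encoding", "metric"])["value"].mean()
    shortlist = []
    for enc in enc_matrices:
        wins = sum(
            1 for metric in METRIC_NAMES if per_enc[(enc, metric)] < overall[metric]
        )
        if wins >= cfg.shortlist_majority:
            shortlist.append(enc)

    report = RankingReport(
        ranking=ranking,
        tree_metrics=tree_metrics,
        overall_average=overall,
        shortlist=sorted(shortlist),
        dropped=dropped,
        encoding_matrices=enc_matrices,
        reference_matrices=references,
        encoding_trees=enc_trees,
        reference_trees=ref_trees,
    )
    if cfg.outdir:
        write_report(report, cfg.outdir)
    return report


def overall_average(report: RankingReport) -> pd.Series:
    """Per-metric arithmetic mean over all (encoding, reference) cells."""
    tm = report.tree_metrics
    encodings = sorted(tm["encoding"].unique())
    refs = sorted(tm["reference"].unique())
    missing = []
    have = set(zip(tm["encoding"], tm["reference"], tm["metric"]))
    for e in encodings:
        for r in refs:
            for mname in METRIC_NAMES:
                if (e, r, mname) not in have:
                    missing.append((e, r, mname))
    if missing:
        raise FunnelError(f"incomplete metric grid; missing cells: {missing[:10]}")
    return tm.groupby("metric")["value"].mean()


def export_radar_table(report: RankingReport) -> pd.DataFrame:
    """Long-format (metric, encoding, value, overall_average) table for
    radar/bar plots; encodings' values are averaged over references."""
    per_enc = (
        report.tree_metrics.groupby(["metric", "encoding"])["value"]
        .mean()
        .reset_index()
    )
    avg = report.overall_average.rename("overall_average").reset_index()
    rows = per_enc.merge(avg, on="metric")
    avg_rows = avg.assign(encoding="__overall__", value=avg["overall_average"])
    return pd.concat([rows, avg_rows[rows.columns]], ignore_index=True)


def write_report(report: RankingReport, outdir: str | Path) -> None:
    """Write matrices (CSV), trees (Newick), ranking/metrics CSVs and a JSON
    summary under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)
    for name, m in report.encoding_matrices.items():
        write_matrix_csv(m, outdir / "matrices" / f"{name}.csv")
    for name, m in report.reference_matrices.items():
        write_matrix_csv(m, outdir / "matrices" / f"ref_{name}.csv")
    for name, t in report.encoding_trees.items():
        (outdir / "trees" / f"{name}.nwk").write_text(tree_to_newick(t))
    for name, t in report.reference_trees.items():
        (outdir / "trees" / f"ref_{name}.nwk").write_text(tree_to_newick(t))
    report.ranking.to_csv(outdir / "ranking.csv", index=False)
    report.tree_metrics.to_csv(outdir / "tree_metrics.csv", index=False)
    export_radar_table(report).to_csv(outdir / "radar_table.csv", index=False)
    summary = {
        "overall_average": {k: float(v) for k, v in report.overall_average.items()},
        "shortlist": report.shortlist,
        "dropped": report.dropped,
        "n_cells_per_metric": report.n_cells,
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2))
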