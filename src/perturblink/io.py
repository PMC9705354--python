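"""Plain-text readers and writers for every on-disk format.

All files are TSV or FASTA; matrices are dense with an id header row and an
id index column, edge lists are two id columns, and the bilayer matrix adds
a single comment line recording its block sizes.  File formats speak ids
only — 0-based indices are an in-memory affair.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .consistency import ConsistencyReport
from .evaluation import EvaluationReport, METRIC_NAMES
from .network import BilayerNetwork, InteractionNetwork
from .similarity import ExpressionProfileTable, SequenceSet, SimilarityMatrix
from .spm import ScoreMatrix


# ---------------------------------------------------------------- edge lists

def read_edge_list(path) -> InteractionNetwork:
    """Read a two-column (lnc_id TAB mi_id) TSV into an interaction network.

    Duplicate pairs collapse to a single link; id registries are built in
    first-appearance order.
    """
    lnc_ids: list[str] = []
    mi_ids: list[str] = []
    pairs: list[tuple[str, str]] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected "
                    f"'lnc_id<TAB>mi_id', got {line!r}"
                )
            lnc, mi = fields[0].strip(), fields[1].strip()
            if lnc not in seen:
                seen.add(lnc)
                lnc_ids.append(lnc)
            if mi not in seen:
                seen.add(mi)
                mi_ids.append(mi)
            pairs.append((lnc, mi))
    if not pairs:
        raise ValueError(f"{path}: empty edge list")
    lnc_index = {x: i for i, x in enumerate(lnc_ids)}
    mi_index = {x: j for j, x in enumerate(mi_ids)}
    lm = np.zeros((len(lnc_ids), len(mi_ids)))
    for lnc, mi in pairs:
        lm[lnc_index[lnc], mi_index[mi]] = 1.0
    return InteractionNetwork(lnc_ids, mi_ids, lm)


def write_edge_list(net: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for i, j in net.interaction_pairs:
            fh.write(f"{net.lnc_ids[i]}\t{net.mi_ids[j]}\n")


# ---------------------------------------------------------- expression / fasta

def read_expression(path, ids: list[str] | None = None) -> ExpressionProfileTable:
    """Read an expression TSV (first column id, rest numeric attributes).

    ``ids`` optionally fixes the id universe (e.g. from a FASTA file);
    profiles present in the file but absent from ``ids`` raise, ids without
    a profile are simply missing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: expression table has no attribute columns")
    profiles = {str(k): df.loc[k].to_numpy(dtype=float) for k in df.index}
    universe = ids if ids is not None else [str(k) for k in df.index]
    return ExpressionProfileTable(ids=universe, profiles=profiles)


def read_fasta(path) -> SequenceSet:
    ids: list[str] = []
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        seqs[record.id] = str(record.seq)
    if not ids:
        raise ValueError(f"{path}: no FASTA records found")
    return SequenceSet(ids=ids, sequences=seqs)


# ------------------------------------------------------------------ matrices

def write_similarity(sim: SimilarityMatrix, path) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(
        path, sep="\t"
    )


def read_similarity(path) -> SimilarityMatrix:
    """Read a dense similarity TSV; validates shape, symmetry and range."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(x) for x in df.index]
    if [str(x) for x in df.columns] != ids:
        raise ValueError(f"{path}: row and column ids differ (not square)")
    return SimilarityMatrix(ids, df.to_numpy(dtype=float))


def write_bilayer(net: BilayerNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#bilayer\tm={net.m}\tn={net.n}\n")
        pd.DataFrame(net.a, index=net.node_ids, columns=net.node_ids).to_csv(
            fh, sep="\t"
        )


def read_bilayer(path) -> BilayerNetwork:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#bilayer"):
            raise ValueError(f"{path}: missing '#bilayer' header line")
        meta = dict(part.split("=") for part in header.split("\t")[1:])
        m, n = int(meta["m"]), int(meta["n"])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    ids = [str(x) for x in df.index]
    if len(ids) != m + n:
        raise ValueError(f"{path}: header says N={m + n}, file has {len(ids)}")
    return BilayerNetwork(ids[:m], ids[m:], df.to_numpy(dtype=float))


# -------------------------------------------------------------------- scores

def write_scores(scores: ScoreMatrix, path) -> None:
    """Write the interaction block as (lnc_id, mi_id, score, known_flag)."""
    block = scores.interaction_scores
    known = scores.known if scores.known is not None else np.zeros(
        block.shape, dtype=bool
    )
    with open(path, "w") as fh:
        fh.write("lnc_id\tmi_id\tscore\tknown\n")
        for i, lnc in enumerate(scores.lnc_ids):
            for j, mi in enumerate(scores.mi_ids):
                fh.write(f"{lnc}\t{mi}\t{block[i, j]:.10g}\t{int(known[i, j])}\n")


def read_scores(path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t")
    lnc_ids = list(dict.fromkeys(df["lnc_id"].astype(str)))
    mi_ids = list(dict.fromkeys(df["mi_id"].astype(str)))
    m, n = len(lnc_ids), len(mi_ids)
    block = np.zeros((m, n))
    known = np.zeros((m, n), dtype=bool)
    li = {x: i for i, x in enumerate(lnc_ids)}
    mj = {x: j for j, x in enumerate(mi_ids)}
    for row in df.itertuples(index=False):
        i, j = li[str(row.lnc_id)], mj[str(row.mi_id)]
        block[i, j] = row.score
        known[i, j] = bool(row.known)
    full = np.zeros((m + n, m + n))
    full[:m, m:] = block
    full[m:, :m] = block.T
    return ScoreMatrix(matrix=full, lnc_ids=lnc_ids, mi_ids=mi_ids,
                       t_used=0, known=known)


# ------------------------------------------------------------------- reports

def write_consistency_report(report: ConsistencyReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("repeat\tdelta\n")
        for r, d in enumerate(report.deltas):
            fh.write(f"{r}\t{d:.6f}\n")
        fh.write(f"mean\t{report.mean:.6f}\n")
        fh.write(f"std\t{report.std:.6f}\n")


def write_evaluation_report(report: EvaluationReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("fold\tauc\t" + "\t".join(METRIC_NAMES) + "\n")
        for f, (a, metrics) in enumerate(
            zip(report.fold_auc, report.fold_metrics)
        ):
            cells = [f"{f}", f"{a:.6f}"]
            cells += [
                "NA" if metrics[name] is None else f"{metrics[name]:.6f}"
                for name in METRIC_NAMES
            ]
            fh.write("\t".join(cells) + "\n")
        fh.write(f"mean\t{report.mean('auc'):.6f}\t" + "\t".join(
            f"{report.mean(name):.6f}" for name in METRIC_NAMES
        ) + "\n")
        fh.write(f"std\t{report.std('auc'):.6f}\t" + "\t".join(
            f"{report.std(name):.6f}" for name in METRIC_NAMES
        ) + "\n")


# -------------------------------------------------------------------- config

@dataclass
class RunConfig:
    """User-facing run parameters with lossless YAML round-trip."""

    t: int = 16
    fraction: float = 0.1
    k: int = 5
    neg_ratio: float = 1.0
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not (0.0 < self.fraction < 1.0):
            raise ValueError("fraction must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.neg_ratio <= 0:
            raise ValueError("neg_ratio must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def write_provenance(out_path, command: str, params: dict) -> Path:
    """Record the effective parameters of a CLI run next to its output."""
    from . import __version__

    log_path = Path(str(out_path) + ".run.json")
    payload = {"command": command, "version": __version__, "params": params}
    log_path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return log_path
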