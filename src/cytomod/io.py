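"""Delimited-text readers/writers shared by all stages, plus run manifests.

File conventions (tab-delimited, genes are always columns):

* expression: header ``sample_id <TAB> gene...``, one row per sample;
* labels: ``sample_id <TAB> label`` with label in {RA, control} or {1, 0};
* gene metadata: ``gene_id <TAB> true_module <TAB> deg_effect``;
* graph edges: ``gene_a <TAB> gene_b <TAB> r <TAB> weight``;
* partition: ``gene_id <TAB> module_index``.

Every CLI invocation writes one JSON manifest recording the command, config
hash, master seed, substream seeds, input/output digests and timestamps, so
any output is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .graph import CoexpressionGraph, ModulePartition
from .simulate import CONTROL, RA, ExpressionCohort

__all__ = [
    "write_expression", "read_expression",
    "write_labels", "read_labels",
    "write_gene_metadata", "read_gene_metadata",
    "write_graph", "read_graph",
    "write_partition", "read_partition",
    "write_manifest", "file_digest",
    "ParseError",
]

_LABEL_TO_INT = {"RA": RA, "control": CONTROL, "1": RA, "0": CONTROL}


class ParseError(ValueError):
    """A delimited file failed validation; the message names the location."""


def write_expression(cohort: ExpressionCohort, path: str) -> None:
    frame = pd.DataFrame(cohort.expression, columns=cohort.gene_ids,
                         index=cohort.sample_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_expression(
    path: str,
    labels_path: Optional[str] = None,
    gene_metadata_path: Optional[str] = None,
) -> ExpressionCohort:
    """Parse an expression matrix; join labels/metadata sidecars when given."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    gene_ids = header[1:]
    dupes = pd.Series(gene_ids)[pd.Series(gene_ids).duplicated()]
    if not dupes.empty:
        raise ParseError(f"duplicate gene id {dupes.iloc[0]!r} in header of {path}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                            float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"ragged or malformed rows in {path}: {exc}") from exc
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ParseError(f"duplicate sample id {dup!r} in {path}")
    body = frame.to_numpy()
    if body.dtype == object or not np.issubdtype(body.dtype, np.number):
        for line_no, (_, row) in enumerate(frame.iterrows(), start=2):
            bad = pd.to_numeric(row, errors="coerce")
            if bad.isna().any():
                col = row.index[bad.isna()][0]
                raise ParseError(
                    f"non-numeric value {row[col]!r} at line {line_no}, column {col!r}"
                )
    if np.isnan(body.astype(np.float64)).any():
        raise ParseError(f"missing values in {path}")

    sample_ids = frame.index.to_numpy(dtype=str)
    n_genes = len(gene_ids)
    labels = np.zeros(len(sample_ids), dtype=np.int64)
    if labels_path is not None:
        label_map = read_labels(labels_path)
        try:
            labels = np.array([label_map[s] for s in sample_ids])
        except KeyError as exc:
            raise ParseError(f"sample {exc.args[0]!r} missing from {labels_path}") from exc
    module_of_gene = np.zeros(n_genes, dtype=np.int64)
    deg_effect = np.zeros(n_genes)
    if gene_metadata_path is not None:
        meta = read_gene_metadata(gene_metadata_path)
        meta = meta.set_index("gene_id").reindex(gene_ids)
        if meta["true_module"].isna().any():
            missing = meta.index[meta["true_module"].isna()][0]
            raise ParseError(f"gene {missing!r} missing from {gene_metadata_path}")
        module_of_gene = meta["true_module"].to_numpy(dtype=np.int64)
        deg_effect = meta["deg_effect"].to_numpy(dtype=np.float64)
    return ExpressionCohort(
        expression=body.astype(np.float64),
        labels=labels,
        gene_ids=np.asarray(gene_ids),
        true_module_of_gene=module_of_gene,
        deg_effect=deg_effect,
        provenance={"cohort_name": Path(path).stem, "sample_ids": sample_ids},
    )


def write_labels(cohort: ExpressionCohort, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in zip(cohort.sample_ids, cohort.labels):
            fh.write(f"{sid}\t{'RA' if lab == RA else 'control'}\n")


def read_labels(path: str) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ParseError(f"{path}: expected 'sample_id\\tlabel' header")
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {line_no} has {len(parts)} fields, expected 2")
            sid, lab = parts
            if lab not in _LABEL_TO_INT:
                raise ParseError(f"{path}: unknown label {lab!r} at line {line_no}")
            if sid in out:
                raise ParseError(f"{path}: duplicate sample id {sid!r} at line {line_no}")
            out[sid] = _LABEL_TO_INT[lab]
    return out


def write_gene_metadata(cohort: ExpressionCohort, path: str) -> None:
    pd.DataFrame({
        "gene_id": cohort.gene_ids,
        "true_module": cohort.true_module_of_gene,
        "deg_effect": cohort.deg_effect,
    }).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_metadata(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    expected = {"gene_id", "true_module", "deg_effect"}
    if not expected.issubset(frame.columns):
        raise ParseError(f"{path}: expected columns {sorted(expected)}")
    return frame


def write_graph(graph: CoexpressionGraph, gene_ids: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={graph.n_nodes}\tgamma={graph.gamma}"
                 f"\tfraction={graph.threshold_fraction}\n")
        fh.write("gene_a\tgene_b\tr\tweight\n")
        for a, b, r, w in zip(graph.edge_a, graph.edge_b, graph.r, graph.weight):
            fh.write(f"{gene_ids[a]}\t{gene_ids[b]}\t{r:.17g}\t{w:.17g}\n")


def read_graph(path: str, gene_ids: np.ndarray) -> CoexpressionGraph:
    index = {g: i for i, g in enumerate(gene_ids)}
    with open(path) as fh:
        meta_line = fh.readline().lstrip("# ").rstrip("\n")
        meta = dict(kv.split("=") for kv in meta_line.split("\t"))
        fh.readline()  # column header
        a, b, r = [], [], []
        for line_no, line in enumerate(fh, start=3):
            ga, gb, rv, _w = line.rstrip("\n").split("\t")
            if ga not in index or gb not in index:
                raise ParseError(f"{path}: unknown gene at line {line_no}")
            a.append(index[ga])
            b.append(index[gb])
            r.append(float(rv))
    r_arr = np.array(r)
    gamma = float(meta["gamma"])
    return CoexpressionGraph(
        n_nodes=int(meta["n_nodes"]),
        edge_a=np.array(a, dtype=np.int64), edge_b=np.array(b, dtype=np.int64),
        r=r_arr, weight=np.abs(r_arr) ** gamma,
        gamma=gamma, threshold_fraction=float(meta["fraction"]),
    )


def write_partition(partition: ModulePartition, gene_ids: np.ndarray, path: str) -> None:
    pd.DataFrame({"gene_id": gene_ids, "module_index": partition.module_of_gene}).to_csv(
        path, sep="\t", index=False)


def read_partition(path: str, gene_ids: np.ndarray) -> ModulePartition:
    frame = pd.read_csv(path, sep="\t").set_index("gene_id").reindex(gene_ids)
    if frame["module_index"].isna().any():
        missing = frame.index[frame["module_index"].isna()][0]
        raise ParseError(f"{path}: gene {missing!r} has no module assignment")
    return ModulePartition(frame["module_index"].to_numpy(dtype=np.int64))


def file_digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(
    out_dir: str,
    command: str,
    config: dict,
    master_seed: int,
    inputs: dict[str, str],
    outputs: dict[str, str],
    substreams: Optional[dict[str, int]] = None,
) -> str:
    from . import __version__

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    manifest = {
        "command": command,
        "config": config,
        "config_hash": config_hash,
        "master_seed": master_seed,
        "substream_seeds": substreams or {},
        "inputs": {k: file_digest(v) for k, v in inputs.items() if Path(v).exists()},
        "outputs": {k: file_digest(v) for k, v in outputs.items() if Path(v).exists()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "package_version": __version__,
    }
    path = Path(out_dir) / f"manifest_{command.replace(' ', '_')}.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return str(path)
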