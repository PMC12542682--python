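"""Readers/writers, rarefaction, relative abundance and seed plumbing.

Formats: tab-separated OTU tables (header row, first column = identifier,
OTUs as rows by default — the common export convention — or samples as
rows via a flag), BIOM 1.0.0 JSON tables, TSV metadata and distance
matrices, and newick trees (scikit-bio ``TreeNode``).
"""

from __future__ import annotations

import datetime
import json
import logging
import zlib

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import OtuTable, SampleMetadata

logger = logging.getLogger("ecospart")

_BIOM_FORMAT = "Biological Observation Matrix 1.0.0"
_BIOM_URL = "http://biom-format.org"


# ---------------------------------------------------------------- seeds

def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a pipeline master seed, deterministically.

    Uses a CRC32 of the stage name folded into a SeedSequence so that
    stages draw independent streams; the result fits in 31 bits.
    """
    tag = zlib.crc32(stage.encode("utf8"))
    ss = np.random.SeedSequence([int(master_seed), tag])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


# ----------------------------------------------------------- OTU tables

def read_otu_table(path, format: str = "tsv", otus_as_rows: bool = True) -> OtuTable:
    """Read an OTU table from ``tsv`` or ``biom`` (JSON) format.

    TSV orientation is declared by ``otus_as_rows`` (default: OTUs are
    rows, samples are columns); the returned table is always samples × OTUs.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if otus_as_rows:
            df = df.T
        return OtuTable(df)
    if format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        return _biom_to_table(doc)
    raise ValueError(f"unknown OTU table format: {format!r}")


def write_otu_table(table: OtuTable, path, format: str = "tsv",
                    otus_as_rows: bool = True) -> None:
    if format == "tsv":
        df = table.to_dataframe()
        if otus_as_rows:
            df = df.T
            df.index.name = "#OTU ID"
        else:
            df.index.name = "#SampleID"
        df.to_csv(path, sep="\t")
        return
    if format == "biom":
        with open(path, "w") as fh:
            json.dump(_table_to_biom(table), fh)
        return
    raise ValueError(f"unknown OTU table format: {format!r}")


def _table_to_biom(table: OtuTable) -> dict:
    # BIOM stores observations (OTUs) as rows, samples as columns.
    counts = table.counts.T
    rows, cols = np.nonzero(counts)
    data = [[int(r), int(c), int(counts[r, c])] for r, c in zip(rows, cols)]
    return {
        "id": None,
        "format": _BIOM_FORMAT,
        "format_url": _BIOM_URL,
        "type": "OTU table",
        "generated_by": "ecospart",
        "date": datetime.datetime.now().isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [counts.shape[0], counts.shape[1]],
        "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }


def _biom_to_table(doc: dict) -> OtuTable:
    n_obs, n_samp = doc["shape"]
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    counts = np.zeros((n_obs, n_samp), dtype=np.int64)
    if doc["matrix_type"] == "sparse":
        for r, c, v in doc["data"]:
            counts[r, c] = v
    elif doc["matrix_type"] == "dense":
        counts[:] = np.asarray(doc["data"], dtype=np.int64)
    else:
        raise ValueError(f"unknown BIOM matrix_type: {doc['matrix_type']!r}")
    return OtuTable(counts.T, sample_ids=sample_ids, otu_ids=otu_ids)


# ------------------------------------------------------------- metadata

def read_metadata(path, dendritic_path=None) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", index_col=0)
    dk = None
    if dendritic_path is not None:
        dk = pd.read_csv(dendritic_path, sep="\t", index_col=0)
    return SampleMetadata(table, dk)


def write_metadata(meta: SampleMetadata, path, dendritic_path=None) -> None:
    df = meta.table.copy()
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")
    if dendritic_path is not None and meta.dendritic_km is not None:
        dk = meta.dendritic_km.copy()
        dk.index.name = "#SampleID"
        dk.to_csv(dendritic_path, sep="\t")


# ---------------------------------------------------------------- trees

def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("tree tip labels are not unique")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if not np.isfinite(node.length) or node.length < 0:
            raise ValueError(f"invalid branch length on node {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def check_tree_covers(tree: TreeNode, otu_ids) -> None:
    """Raise if any OTU used in a phylogenetic operation is not a tip."""
    tips = {t.name for t in tree.tips()}
    missing = [o for o in otu_ids if o not in tips]
    if missing:
        raise ValueError(f"OTU(s) missing from tree: {missing[:10]}")


# ----------------------------------------------------- transformations

def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances; each row sums to one."""
    df = table.to_dataframe().astype(float)
    totals = df.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total count: {zero.index.tolist()}"
        )
    return df.div(totals, axis=0)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total falls below ``depth`` are dropped (and logged),
    matching standard practice; sampling is multivariate hypergeometric
    and bit-reproducible for a fixed seed.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.counts
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    out = np.zeros((int(keep.sum()), table.n_otus), dtype=np.int64)
    r = 0
    for i in range(table.n_samples):
        if not keep[i]:
            continue
        out[r] = rng.multivariate_hypergeometric(counts[i], depth)
        r += 1
    sample_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return OtuTable(out, sample_ids=sample_ids, otu_ids=table.otu_ids)
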