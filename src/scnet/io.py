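"""Readers and writers for cohort tables, networks and scan results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import CorrelationNetwork, RMTScan
from .synthetic import Cohort

_COVARIATES = ("group", "genotype", "age", "gender")


def write_cohort(cohort: Cohort, path) -> None:
    """Tidy CSV: one row per subject, covariate columns then region columns."""
    cohort.table.to_csv(path)


def read_thickness_table(path) -> Cohort:
    """Read a delimited cohort table (comma or tab, sniffed from the header).

    Expects a ``subject_id`` index column, the covariates ``group``,
    ``genotype``, ``age``, ``gender``, and one numeric column per region.
    Errors name the offending subject/region.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    header = text.splitlines()[0]
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    table = pd.read_csv(path, sep=sep, index_col=0, dtype=str)

    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate subject id {dup!r}")
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column {dup!r}")
    missing = [c for c in _COVARIATES if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing covariate column(s) {missing}")

    region_cols = [c for c in table.columns if c not in _COVARIATES]
    if not region_cols:
        raise ValueError(f"{path}: no region columns found")
    thick = pd.DataFrame(index=table.index)
    for col in region_cols:
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            subj = vals.index[vals.isna()][0]
            raise ValueError(
                f"{path}: non-numeric thickness for subject {subj!r}, region {col!r}"
            )
        thick[col] = vals
    age = pd.to_numeric(table["age"], errors="coerce")
    if age.isna().any():
        raise ValueError(f"{path}: non-numeric age for subject {age.index[age.isna()][0]!r}")

    out = table[list(_COVARIATES)].copy()
    out["age"] = age
    out = pd.concat([out, thick], axis=1)
    out.index.name = "subject_id"
    cohort = Cohort(table=out, region_labels=region_cols)
    cohort.validate()
    return cohort


def write_network(net: CorrelationNetwork, matrix_path, edges_path=None) -> None:
    """Full N x N weight-matrix CSV, optionally plus a weighted edge-list TSV."""
    pd.DataFrame(net.weights, index=net.region_labels, columns=net.region_labels).to_csv(
        matrix_path
    )
    if edges_path is not None:
        net.edge_list().to_csv(edges_path, sep="\t", index=False)


def write_rmt_scan(scan: RMTScan, table_path, decision_path=None) -> None:
    scan.table.to_csv(table_path, sep="\t", index=False)
    if decision_path is not None:
        record = {
            "chosen_threshold": scan.chosen_threshold,
            "decision_rule": scan.decision_rule,
            "diagnostic": scan.diagnostic,
        }
        Path(decision_path).write_text(json.dumps(record, indent=2))


def export_heatmap_matrix(net: CorrelationNetwork, path, vmax: float = 1.0) -> None:
    """Render the weight matrix as a heat map (cosmetic convenience)."""
    import warnings

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if net.n_edges == 0:
        warnings.warn("empty-edge network: heat map is uniform", stacklevel=2)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(net.weights, vmin=0.0, vmax=vmax, cmap="RdYlGn_r")
    ax.set_title(f"{net.group or 'network'} (threshold {net.threshold:.2f})")
    fig.colorbar(im, ax=ax, label="|Spearman rho|")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def matrix_fingerprint(arr: np.ndarray) -> str:
    """Shape + checksum fingerprint used in stage-boundary logs."""
    a = np.ascontiguousarray(np.asarray(arr, float))
    import zlib

    return f"{a.shape}:{zlib.crc32(a.tobytes()):08x}"
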