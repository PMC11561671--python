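"""Tab-separated on-disk formats shared by all stages.

Expression matrices are stored genes x samples with the gene identifier
in the first column; sample metadata is one row per sample with the
sample identifier in the first column. Both round-trip through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

SAMPLE_COLUMNS = ["organ", "strain", "sex", "age_months", "replicate"]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression table (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_samples_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata table (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_samples_tsv(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
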