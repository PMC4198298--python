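"""Reading, writing, and gene-level preprocessing of the pipeline's formats.

All tabular formats are plain TSV: expression matrices (first column gene
ids, header row of sample ids), clinical tables (``sample_id``, ``time``,
``event``, then covariates), pairing tables, gene annotations
(gene -> chromosome).  Gene lists are one symbol per line with ``#``
comments; scoring models are JSON documents.

The preprocessing filters mirror standard microarray gene-level hygiene:
collapsing multiple probes to their per-gene average, dropping genes not
"present" in at least a fraction of samples (default two thirds, with a
pluggable presence predicate standing in for platform detection calls), and
removing genes annotated to the sex chromosomes.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .containers import (
    ScoringModel,
    validate_clinical,
    validate_expression,
)
from .errors import ConfigurationError, ParseError

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gene_list",
    "write_gene_list",
    "read_annotation",
    "read_pairing",
    "read_scoring_model",
    "write_scoring_model",
    "collapse_probes",
    "detection_filter",
    "drop_sex_chromosomes",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (log2 values)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ParseError(
                    f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
                ) from None
        raise
    if values.isna().any().any():
        row = values.index[values.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in row {row!r}")
    values.index.name = "gene"
    return validate_expression(values)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    validate_expression(matrix)
    out = matrix.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV (sample_id, time, event, then covariates)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        validate_clinical(df)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df.index.name = "sample_id"
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    validate_clinical(clinical)
    out = clinical.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes: list[str] = []
    seen = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line in seen:
            raise ParseError(f"{path}: duplicate gene {line!r} at line {lineno}")
        seen.add(line)
        genes.append(line)
    return genes


def write_gene_list(genes: list[str], path: str | Path, header: str | None = None) -> None:
    lines = [f"# {header}"] if header else []
    lines.extend(genes)
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path) -> pd.Series:
    """Read a gene -> chromosome TSV (two columns, header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: annotation needs gene and chromosome columns")
    genes, chroms = df.iloc[:, 0], df.iloc[:, 1]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ParseError(f"{path}: gene {dup!r} annotated more than once")
    return pd.Series(chroms.to_numpy(), index=genes.to_numpy(), name="chromosome")


def read_pairing(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"patient_id", "normal_sample_id", "tumor_sample_id"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"{path}: pairing table missing columns {sorted(missing)}")
    return df


def read_scoring_model(path: str | Path) -> ScoringModel:
    return ScoringModel.from_json(Path(path).read_text())


def write_scoring_model(model: ScoringModel, path: str | Path) -> None:
    Path(path).write_text(model.to_json() + "\n")


# ---------------------------------------------------------------------------
# gene-level preprocessing


def collapse_probes(
    matrix: pd.DataFrame, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes by averaging probe rows.

    Probes absent from ``mapping`` are dropped (count logged).  Gene rows are
    the arithmetic mean of their probes' rows.
    """
    if not mapping:
        raise ConfigurationError("probe -> gene mapping is empty")
    genes = pd.Series(
        [mapping.get(p) for p in matrix.index], index=matrix.index, dtype=object
    )
    unmapped = genes.isna()
    if unmapped.any():
        logger.info("collapse_probes: dropping %d unmapped probes", int(unmapped.sum()))
    kept = matrix.loc[~unmapped]
    collapsed = kept.groupby(genes[~unmapped], sort=True).mean()
    collapsed.index.name = "gene"
    return collapsed


def detection_filter(
    matrix: pd.DataFrame,
    min_fraction: float = 2.0 / 3.0,
    *,
    present: Callable[[np.ndarray], np.ndarray] | None = None,
    floor: float | None = None,
) -> pd.DataFrame:
    """Keep genes "present" in at least ``min_fraction`` of samples.

    ``present`` maps the value matrix to a boolean presence matrix.  The
    default predicate is "value strictly greater than ``floor``", with the
    floor defaulting to the cohort-wide 10th percentile — a value-level stand
    in for platform detection calls.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ConfigurationError("min_fraction must be in (0, 1]")
    values = matrix.to_numpy(dtype=float)
    if present is None:
        if floor is None:
            floor = float(np.quantile(values, 0.10)) if values.size else 0.0
        mask = values > floor
    else:
        mask = np.asarray(present(values), dtype=bool)
        if mask.shape != values.shape:
            raise ConfigurationError("presence predicate must preserve shape")
    frac = mask.mean(axis=1) if values.size else np.array([])
    keep = frac >= min_fraction
    out = matrix.loc[keep]
    if len(matrix) and not len(out):
        warnings.warn("detection_filter removed every gene", stacklevel=2)
    return out


def _is_sex_chromosome(label: str) -> bool:
    norm = str(label).strip().lower()
    if norm.startswith("chr"):
        norm = norm[3:]
    return norm in {"x", "y"}


def drop_sex_chromosomes(matrix: pd.DataFrame, annotation: pd.Series) -> pd.DataFrame:
    """Remove genes annotated to chromosome X or Y.

    Labels are normalized case-insensitively with an optional "chr" prefix.
    Genes missing from the annotation are retained with a warning rather
    than silently dropped.
    """
    ann = annotation.reindex(matrix.index)
    unannotated = ann.isna()
    if unannotated.any():
        warnings.warn(
            f"drop_sex_chromosomes: {int(unannotated.sum())} genes lack annotation; retained",
            stacklevel=2,
        )
    sex = ann.fillna("").map(_is_sex_chromosome)
    return matrix.loc[~sex.to_numpy(dtype=bool)]
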