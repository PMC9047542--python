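"""Reading and writing of expression matrices, phenotype tables and signatures.

Expression matrices are plain tab-separated text: first column gene ids,
header row sample ids, numeric body. Phenotype tables are TSV with one row
per sample. Signature files are TSV with ``#``-prefixed header comments
(one of which carries the vote threshold) and one gene pair per line.

All gene identifiers are harmonized on read: surrounding whitespace is
stripped and matching is case-insensitive (ids are upper-cased). Rows that
share a harmonized gene id — multi-probe genes on microarrays — are
collapsed to a single row by per-sample median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("reosig")

#: Columns understood in a phenotype table. Only ``sample_id`` is mandatory.
PHENO_COLUMNS = (
    "sample_id",
    "group",
    "os_months",
    "event",
    "tert_status",
    "idh_status",
    "grade",
    "age",
    "sex",
)


class ParseError(ValueError):
    """Raised when a file cannot be interpreted in the expected dialect."""


def _harmonize_gene_ids(ids: Iterable[str]) -> list[str]:
    return [str(g).strip().upper() for g in ids]


def collapse_duplicate_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a gene id to their per-sample median.

    Idempotent: a matrix with unique gene ids is returned unchanged
    (up to row order, which is preserved by first appearance).
    """
    if matrix.index.is_unique:
        return matrix
    n_dup = matrix.index.duplicated().sum()
    collapsed = matrix.groupby(level=0, sort=False).median()
    logger.info("collapsed %d duplicate gene-id rows by median", n_dup)
    return collapsed


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV.

    Returns a DataFrame indexed by harmonized gene id with sample-id
    columns. Values must be finite and non-negative.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    except Exception as exc:  # malformed beyond cell level
        raise ParseError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")
    df.index = _harmonize_gene_ids(df.index)
    df.columns = [str(c).strip() for c in df.columns]
    if len(set(df.columns)) != len(df.columns):
        raise ParseError(f"{path}: duplicate sample ids in header")
    # locate any non-numeric cell precisely before failing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    na_cells = df.isna()
    problems = bad | na_cells
    if problems.to_numpy().any():
        r, c = np.argwhere(problems.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    df = numeric.astype(float)
    if not np.isfinite(df.to_numpy()).all():
        raise ParseError(f"{path}: non-finite expression value")
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative expression value")
    return collapse_duplicate_genes(df)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_pheno(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table (TSV, one row per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: phenotype table lacks 'sample_id' column")
    df["sample_id"] = df["sample_id"].str.strip()
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids in phenotype table")
    if "os_months" in df.columns and (df["os_months"].dropna() < 0).any():
        raise ParseError(f"{path}: negative survival time")
    if "event" in df.columns:
        ev = df["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ParseError(f"{path}: event indicator must be 0/1")
    return df


def write_pheno(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


@dataclass
class Signature:
    """An ordered list of disjoint gene pairs with a vote threshold.

    Each pair is stored as ``(gene_a, gene_b)`` where ``gene_a > gene_b``
    within a sample is the high-risk (GBM-like) ordering. A sample with
    strictly more than ``threshold`` pairs in the high-risk ordering is
    called high-risk.
    """

    pairs: list[tuple[str, str]]
    threshold: int
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = [g for p in self.pairs for g in p]
        if len(set(genes)) != len(genes):
            seen, dups = set(), set()
            for g in genes:
                (dups if g in seen else seen).add(g)
            raise ValueError(f"signature pairs are not gene-disjoint: {sorted(dups)}")
        if not 0 <= self.threshold <= len(self.pairs):
            raise ValueError(
                f"threshold {self.threshold} outside [0, {len(self.pairs)}]"
            )

    @property
    def genes(self) -> list[str]:
        return [g for p in self.pairs for g in p]

    def __len__(self) -> int:
        return len(self.pairs)


def read_signature(path: str | Path) -> Signature:
    """Read a signature file.

    Format: ``#``-prefixed comment lines, one of which must be
    ``# threshold: <int>``; then one ``gene_a<TAB>gene_b`` pair per line.
    """
    path = Path(path)
    threshold: int | None = None
    metadata: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key, val = key.strip(), val.strip()
                if key == "threshold":
                    threshold = int(val)
                else:
                    metadata[key] = val
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'gene_a<TAB>gene_b'")
        a, b = _harmonize_gene_ids(fields[:2])
        pairs.append((a, b))
    if threshold is None:
        raise ParseError(f"{path}: missing '# threshold: <int>' header")
    return Signature(pairs=pairs, threshold=threshold, metadata=metadata)


def write_signature(signature: Signature, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# threshold: {signature.threshold}"]
    for key, val in signature.metadata.items():
        lines.append(f"# {key}: {val}")
    lines.append("# gene_a\tgene_b\t(gene_a > gene_b is the high-risk ordering)")
    for a, b in signature.pairs:
        lines.append(f"{a}\t{b}")
    path.write_text("\n".join(lines) + "\n")


def intersect_genes(matrices: Sequence[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict every matrix to the shared gene set, in identical order.

    Gene order of the output follows the first matrix.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    shared = set(matrices[0].index)
    for m in matrices[1:]:
        shared &= set(m.index)
    if not shared:
        raise ValueError("gene-id intersection across matrices is empty")
    order = [g for g in matrices[0].index if g in shared]
    return [m.loc[order] for m in matrices]
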