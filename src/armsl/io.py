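"""Matrix and annotation I/O plus the typed containers shared by every stage.

The DepMap/CCLE CSV dialect stores cell lines as rows and genes as columns,
with gene headers formatted ``"SYMBOL (ENTREZ)"``.  Everything in this package
works on matrices oriented genes x cell-lines, so :func:`read_matrix`
normalises orientation at the boundary.  Gene identity joins on the Entrez ID
when present and falls back to the symbol; collisions raise rather than merge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FitnessMatrix",
    "ExpressionMatrix",
    "CopyNumberMatrix",
    "AlignedCohort",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_lineage",
    "write_lineage",
    "align_cohort",
]

_HEADER_RE = re.compile(r"^(?P<symbol>.+?)\s*\((?P<entrez>\d+)\)$")

ANNOTATION_COLUMNS = ["gene_symbol", "entrez_id", "chromosome", "arm", "start_bp", "end_bp"]


class MatrixParseError(ValueError):
    """Raised for malformed matrix files (bad headers, non-numeric cells, duplicates)."""


@dataclass
class GeneMatrix:
    """Base container: a genes x cell-lines numeric matrix.

    ``df`` is indexed by gene symbol with cell-line IDs as columns; ``entrez``
    maps each gene symbol to its Entrez ID (-1 where unknown).  Missing values
    are NaN and are preserved through I/O.
    """

    df: pd.DataFrame
    entrez: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.entrez is None:
            self.entrez = pd.Series(-1, index=self.df.index, dtype=int)
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise MatrixParseError(f"duplicate gene keys: {dups}")
        if self.df.columns.has_duplicates:
            dups = self.df.columns[self.df.columns.duplicated()].unique().tolist()
            raise MatrixParseError(f"duplicate cell-line keys: {dups}")
        self._validate()

    def _validate(self) -> None:  # overridden by subclasses
        pass

    @property
    def genes(self) -> pd.Index:
        return self.df.index

    @property
    def lines(self) -> pd.Index:
        return self.df.columns

    @property
    def n_missing(self) -> int:
        return int(self.df.isna().sum().sum())

    def restrict_lines(self, lines) -> "GeneMatrix":
        return type(self)(self.df.loc[:, list(lines)], self.entrez)


class FitnessMatrix(GeneMatrix):
    """Genes x cell-lines CERES-scale gene-effect scores (negative = fitness defect)."""


class ExpressionMatrix(GeneMatrix):
    """Genes x cell-lines log2(TPM+1) expression; finite and non-negative."""

    def _validate(self) -> None:
        vals = self.df.to_numpy(float)
        obs = vals[~np.isnan(vals)]
        if obs.size and (not np.isfinite(obs).all() or (obs < 0).any()):
            raise ValueError("expression values must be finite and >= 0 (log2(TPM+1) domain)")


class CopyNumberMatrix(GeneMatrix):
    """Genes x cell-lines log2 relative copy number; 0 is copy-neutral."""


@dataclass
class AlignedCohort:
    """The three matrices restricted to one shared, identically ordered line set."""

    fitness: FitnessMatrix
    expression: ExpressionMatrix
    copy_number: CopyNumberMatrix
    lineage: pd.Series  # cell-line -> lineage label (may be empty)
    annotation: pd.DataFrame  # gene_symbol-indexed GeneAnnotation table
    drop_report: dict = field(default_factory=dict)

    @property
    def lines(self) -> pd.Index:
        return self.fitness.lines

    @property
    def n_lines(self) -> int:
        return len(self.lines)


# ---------------------------------------------------------------------------
# matrix I/O


def _parse_gene_headers(tokens) -> tuple[list[str], list[int]]:
    symbols, entrez, bad = [], [], []
    for tok in tokens:
        tok = str(tok).strip()
        m = _HEADER_RE.match(tok)
        if m:
            symbols.append(m.group("symbol"))
            entrez.append(int(m.group("entrez")))
        else:
            bad.append(tok)
    if bad:
        raise MatrixParseError(f"malformed gene headers (expected 'SYMBOL (ENTREZ)'): {bad}")
    return symbols, entrez


def _to_numeric_checked(df: pd.DataFrame) -> pd.DataFrame:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = df.notna() & df.astype(str).ne("") & coerced.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MatrixParseError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    return coerced.astype(float)


def read_matrix(path, dialect: str = "depmap_genes_as_columns", kind: type = GeneMatrix) -> GeneMatrix:
    """Read a genes x cell-lines matrix from CSV.

    Parameters
    ----------
    dialect
        ``"depmap_genes_as_columns"`` — cell lines as rows, gene headers as
        columns (the DepMap portal layout); ``"genes_as_rows"`` — transposed.
    kind
        Container class to construct (FitnessMatrix, ExpressionMatrix, ...).
    """
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=True)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = [str(c).strip() for c in raw.columns]
    if dialect == "depmap_genes_as_columns":
        symbols, entrez = _parse_gene_headers(raw.columns)
        values = _to_numeric_checked(raw).T
        values.index = pd.Index(symbols, name="gene_symbol")
    elif dialect == "genes_as_rows":
        symbols, entrez = _parse_gene_headers(raw.index)
        values = _to_numeric_checked(raw)
        values.index = pd.Index(symbols, name="gene_symbol")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    pairs = pd.DataFrame({"symbol": symbols, "entrez": entrez})
    dup = pairs[pairs.duplicated(keep=False)]
    if len(dup):
        raise MatrixParseError(f"duplicate gene keys: {sorted(set(dup['symbol']))}")
    if pd.Index(symbols).has_duplicates:
        collide = pd.Index(symbols)[pd.Index(symbols).duplicated()].unique().tolist()
        raise MatrixParseError(f"gene symbol collision across distinct Entrez IDs: {collide}")
    ent = pd.Series(entrez, index=values.index, dtype=int)
    values.columns.name = "cell_line"
    return kind(values, ent)


def write_matrix(matrix: GeneMatrix, path, dialect: str = "depmap_genes_as_columns") -> None:
    """Write a matrix in either CSV dialect; inverse of :func:`read_matrix`."""
    headers = [f"{s} ({int(e)})" for s, e in zip(matrix.genes, matrix.entrez)]
    if dialect == "depmap_genes_as_columns":
        out = matrix.df.T.copy()
        out.columns = headers
        out.index.name = "DepMap_ID"
    elif dialect == "genes_as_rows":
        out = matrix.df.copy()
        out.index = pd.Index(headers, name="gene")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    out.to_csv(path)


# ---------------------------------------------------------------------------
# annotation / lineage I/O


def read_annotation(path) -> pd.DataFrame:
    """Read the gene annotation TSV (gene_symbol, entrez_id, chromosome, arm, start_bp, end_bp)."""
    ann = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "arm": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation is missing columns: {missing}")
    if ann.duplicated(["gene_symbol", "entrez_id"]).any():
        dups = ann.loc[ann.duplicated(["gene_symbol", "entrez_id"]), "gene_symbol"].tolist()
        raise ValueError(f"duplicate (gene_symbol, entrez_id) annotation records: {dups}")
    if (ann["start_bp"] > ann["end_bp"]).any():
        bad = ann.loc[ann["start_bp"] > ann["end_bp"], "gene_symbol"].tolist()
        raise ValueError(f"start_bp > end_bp for: {bad}")
    if not ann["arm"].isin(["p", "q"]).all():
        raise ValueError("arm must be 'p' or 'q'")
    return ann.set_index("gene_symbol", drop=False)


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.reset_index(drop=True)[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_lineage(path) -> pd.Series:
    """Read the two-column (line_id, lineage) TSV into a Series."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if tab.shape[1] < 2:
        raise ValueError("lineage table needs two columns: line_id, lineage")
    ser = pd.Series(tab.iloc[:, 1].str.strip().values, index=tab.iloc[:, 0].str.strip())
    ser.index.name, ser.name = "line_id", "lineage"
    return ser


def write_lineage(lineage: pd.Series, path) -> None:
    lineage.rename("lineage").rename_axis("line_id").to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# alignment


def align_cohort(
    fitness: FitnessMatrix,
    expression: ExpressionMatrix,
    copy_number: CopyNumberMatrix,
    annotation: pd.DataFrame,
    lineage: pd.Series | None = None,
) -> AlignedCohort:
    """Restrict all matrices to the shared cell-line set, in one common order.

    The shared order follows the fitness matrix's column order.  The drop
    report makes the intersection explicit: per source, the line IDs that were
    present there but absent from at least one other source.
    """
    sets = {
        "fitness": fitness,
        "expression": expression,
        "copy_number": copy_number,
    }
    shared = None
    for m in sets.values():
        s = set(m.lines)
        shared = s if shared is None else (shared & s)
    if not shared:
        raise ValueError("no cell line is shared by all matrices")
    order = [l for l in fitness.lines if l in shared]
    report = {name: sorted(set(m.lines) - shared) for name, m in sets.items()}
    lin = pd.Series(dtype=object) if lineage is None else lineage.reindex(order)
    return AlignedCohort(
        fitness=fitness.restrict_lines(order),
        expression=expression.restrict_lines(order),
        copy_number=copy_number.restrict_lines(order),
        lineage=lin,
        annotation=annotation,
        drop_report=report,
    )
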