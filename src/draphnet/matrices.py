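"""Core matrix containers, gene-score preprocessing, and delimited-text I/O.

The model consumes three aligned matrices:

* an **endpoint matrix** ``D`` (drugs x assay endpoints) of real-valued
  hit-fraction scores with missing entries, as produced by large in-vitro
  screening programs;
* a **gene-score matrix** ``G`` (genes x phenotypes) of signed z-scores
  summarizing how strongly genetically regulated expression of each gene
  associates with each phenotype;
* a binary **association matrix** ``Y`` (drugs x phenotypes) of recorded
  drug side effects or indications.

This module defines the containers for those matrices, the conversion of
per-gene association p-values plus per-tissue regulation signs into signed
z-scores, the variance filter that keeps the most phenotype-informative
genes, and tab-separated round-trip I/O for all three matrix kinds.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, MatrixParseError

logger = logging.getLogger(__name__)

#: Default floor applied to p-values before the normal quantile map.
PVALUE_FLOOR = 1e-300


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise MatrixParseError(f"duplicated {what} id: {i!r}")
            seen.add(i)
    return ids


@dataclass
class EndpointMatrix:
    """Drugs x endpoints hit-fraction matrix with an observation mask.

    ``values`` holds NaN at unobserved cells; ``mask`` is True where a drug
    was assayed for an endpoint. Every drug must have at least one observed
    endpoint.
    """

    values: np.ndarray
    drug_ids: list[str]
    endpoint_ids: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise InvalidInputError("mask shape must equal values shape")
        if self.values.ndim != 2:
            raise InvalidInputError("values must be 2-dimensional")
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.endpoint_ids = _check_unique(self.endpoint_ids, "endpoint")
        if len(self.drug_ids) != self.values.shape[0]:
            raise InvalidInputError("drug_ids length must match row count")
        if len(self.endpoint_ids) != self.values.shape[1]:
            raise InvalidInputError("endpoint_ids length must match column count")
        empty = ~self.mask.any(axis=1)
        if empty.any():
            bad = self.drug_ids[int(np.flatnonzero(empty)[0])]
            raise InvalidInputError(f"drug {bad!r} has no observed endpoint")
        # canonical form: NaN at unobserved cells
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def filled(self, fill_value: float = 0.0) -> np.ndarray:
        """Dense copy with unobserved entries replaced by ``fill_value``."""
        return np.where(self.mask, self.values, fill_value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids, columns=self.endpoint_ids)


@dataclass
class GeneScoreMatrix:
    """Genes x phenotypes signed z-score matrix; complete and finite."""

    values: np.ndarray
    gene_ids: list[str]
    phenotype_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("values must be 2-dimensional")
        if not np.isfinite(self.values).all():
            raise InvalidInputError("gene score matrix must be finite and complete")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.phenotype_ids = _check_unique(self.phenotype_ids, "phenotype")
        if len(self.gene_ids) != self.values.shape[0]:
            raise InvalidInputError("gene_ids length must match row count")
        if len(self.phenotype_ids) != self.values.shape[1]:
            raise InvalidInputError("phenotype_ids length must match column count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.phenotype_ids)


Polarity = Literal["side_effects", "indications"]


@dataclass
class AssociationMatrix:
    """Drugs x phenotypes binary matrix of recorded associations."""

    values: np.ndarray
    drug_ids: list[str]
    phenotype_ids: list[str]
    polarity: Polarity = "side_effects"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise InvalidInputError("values must be 2-dimensional")
        if not np.isin(values, (0, 1)).all():
            raise InvalidInputError("association matrix entries must be 0 or 1")
        self.values = values.astype(np.int8)
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.phenotype_ids = _check_unique(self.phenotype_ids, "phenotype")
        if len(self.drug_ids) != self.values.shape[0]:
            raise InvalidInputError("drug_ids length must match row count")
        if len(self.phenotype_ids) != self.values.shape[1]:
            raise InvalidInputError("phenotype_ids length must match column count")
        if self.polarity not in ("side_effects", "indications"):
            raise InvalidInputError(f"unknown polarity {self.polarity!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids, columns=self.phenotype_ids)


@dataclass
class TissueSignTable:
    """Long-format per-(gene, phenotype) association p-values and tissue signs.

    ``pvalues`` is a genes x phenotypes frame of combined (cross-tissue)
    association p-values in (0, 1]. ``signs`` is a long frame with columns
    ``gene``, ``phenotype``, ``tissue``, ``sign`` (+1/-1) and optionally
    ``tissue_pvalue``; tissues missing for a gene are simply absent.
    """

    pvalues: pd.DataFrame
    signs: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.pvalues.to_numpy(dtype=float)
        if not ((p > 0) & (p <= 1)).all():
            raise InvalidInputError("combined p-values must lie in (0, 1]")
        required = {"gene", "phenotype", "sign"}
        if not required.issubset(self.signs.columns):
            raise InvalidInputError(f"sign table needs columns {sorted(required)}")
        if not np.isin(self.signs["sign"].to_numpy(), (-1, 1)).all():
            raise InvalidInputError("tissue signs must be -1 or +1")


def compute_gene_zscore(
    p, consensus_sign, *, floor: float = PVALUE_FLOOR
):
    """Signed z-score ``|Phi^-1(p)| * sign`` for a gene-phenotype association.

    ``p`` is a (two-sided, cross-tissue) association p-value; the magnitude
    is the absolute standard-normal quantile, zero at p = 1 (after clipping
    p into ``[floor, 1 - floor]``) growing as p shrinks, and the sign is the
    consensus regulation direction across tissues.

    Accepts scalars or arrays (broadcast together).
    """
    p_arr = np.asarray(p, dtype=float)
    sign_arr = np.asarray(consensus_sign)
    if not np.isin(sign_arr, (-1, 1)).all():
        raise InvalidInputError("consensus_sign must be -1 or +1")
    if (p_arr <= 0).any():
        raise InvalidInputError("p-values must be positive")
    if (p_arr > 1).any():
        raise InvalidInputError("p-values must be <= 1")
    if (p_arr < floor).any():
        logger.warning("p-values below the floor %.3g were clipped", floor)
    clipped = np.clip(p_arr, floor, 1.0 - floor)
    # p numerically 1 (clip is a no-op there in float) carries no signal: z = 0
    z = np.where(clipped >= 1.0, 0.0, np.abs(stats.norm.ppf(clipped))) * sign_arr
    if np.isscalar(p) and np.isscalar(consensus_sign):
        return float(z)
    return z


def consensus_sign(
    tissue_signs: Iterable[int],
    *,
    tie_break: Literal["positive", "most_significant"] = "positive",
    tissue_pvalues: Sequence[float] | None = None,
) -> int:
    """Majority regulation sign across tissues.

    Ties default to +1; with ``tie_break='most_significant'`` the sign of
    the tissue with the smallest p-value wins (requires ``tissue_pvalues``).
    """
    signs = list(tissue_signs)
    if not signs:
        raise InvalidInputError("tissue sign list must be non-empty")
    if not all(s in (-1, 1) for s in signs):
        raise InvalidInputError("tissue signs must be -1 or +1")
    total = sum(signs)
    if total > 0:
        return 1
    if total < 0:
        return -1
    if tie_break == "most_significant":
        if tissue_pvalues is None:
            raise InvalidInputError(
                "tie_break='most_significant' requires tissue_pvalues"
            )
        return int(signs[int(np.argmin(np.asarray(tissue_pvalues)))])
    return 1


def build_gene_score_matrix(
    table: TissueSignTable,
    *,
    tie_break: Literal["positive", "most_significant"] = "positive",
    missing_sign: int = 1,
    floor: float = PVALUE_FLOOR,
) -> GeneScoreMatrix:
    """Assemble the signed z-score matrix from p-values and tissue signs.

    Gene-phenotype pairs with no sign record at all receive ``missing_sign``
    (+1 by default); the magnitude is still the quantile of the combined
    p-value, so such genes are not silently dropped.
    """
    genes = [str(g) for g in table.pvalues.index]
    phenos = [str(c) for c in table.pvalues.columns]
    sign_mat = np.full(table.pvalues.shape, missing_sign, dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    pheno_pos = {c: j for j, c in enumerate(phenos)}
    has_tp = "tissue_pvalue" in table.signs.columns
    grouped = table.signs.groupby(["gene", "phenotype"], sort=False)
    for (gene, pheno), sub in grouped:
        i = gene_pos.get(str(gene))
        j = pheno_pos.get(str(pheno))
        if i is None or j is None:
            continue
        tp = sub["tissue_pvalue"].tolist() if has_tp else None
        sign_mat[i, j] = consensus_sign(
            sub["sign"].tolist(), tie_break=tie_break, tissue_pvalues=tp
        )
    z = compute_gene_zscore(
        table.pvalues.to_numpy(dtype=float), sign_mat, floor=floor
    )
    return GeneScoreMatrix(values=z, gene_ids=genes, phenotype_ids=phenos)


def variance_filter(
    G: GeneScoreMatrix, keep_fraction: float = 0.5
) -> GeneScoreMatrix:
    """Keep the genes whose scores vary most across phenotypes.

    Retains the ``ceil(keep_fraction * n_genes)`` genes with the largest
    across-phenotype standard deviation; survivors keep their input order,
    and ties are broken by input order (stable sort).
    """
    if not (0 < keep_fraction <= 1):
        raise InvalidInputError("keep_fraction must lie in (0, 1]")
    n_genes = G.values.shape[0]
    n_keep = math.ceil(keep_fraction * n_genes)
    sds = G.values.std(axis=1, ddof=0)
    order = np.argsort(-sds, kind="stable")
    keep = np.sort(order[:n_keep])
    return GeneScoreMatrix(
        values=G.values[keep],
        gene_ids=[G.gene_ids[i] for i in keep],
        phenotype_ids=list(G.phenotype_ids),
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

MatrixKind = Literal["endpoint", "gene_score", "association"]

_MISSING_TOKENS = {"", "NA"}


def _read_table(path: str | Path) -> tuple[list[str], list[str], list[list[str]]]:
    """Read a TSV with row ids in column 0 and column ids in row 0."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    col_ids = header[1:]
    n_cols = len(col_ids)
    row_ids: list[str] = []
    cells: list[list[str]] = []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n_cols + 1:
            raise MatrixParseError(
                f"{path}: ragged row {parts[0]!r} (line {ln}): "
                f"expected {n_cols} cells, found {len(parts) - 1}"
            )
        row_ids.append(parts[0])
        cells.append(parts[1:])
    return row_ids, col_ids, cells


def read_matrix(
    path: str | Path, kind: MatrixKind, *, polarity: Polarity | None = None
):
    """Read an :class:`EndpointMatrix`, :class:`GeneScoreMatrix`, or
    :class:`AssociationMatrix` from a tab-separated file.

    Empty cells or ``NA`` denote missing values and are legal only for
    ``kind='endpoint'``. For associations, a ``<path>.json`` sidecar (if
    present) supplies the polarity unless given explicitly.
    """
    path = Path(path)
    row_ids, col_ids, cells = _read_table(path)
    n_rows, n_cols = len(row_ids), len(col_ids)
    values = np.empty((n_rows, n_cols), dtype=float)
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            if cell in _MISSING_TOKENS:
                if kind != "endpoint":
                    raise MatrixParseError(
                        f"{path}: missing cell in row {row_ids[i]!r} "
                        f"(column {col_ids[j]!r}) is not allowed for kind {kind!r}"
                    )
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise MatrixParseError(
                    f"{path}: unparseable cell {cell!r} in row {row_ids[i]!r}"
                ) from exc
    try:
        if kind == "endpoint":
            return EndpointMatrix(values=values, drug_ids=row_ids, endpoint_ids=col_ids)
        if kind == "gene_score":
            return GeneScoreMatrix(values=values, gene_ids=row_ids, phenotype_ids=col_ids)
        if kind == "association":
            if not np.isin(values, (0.0, 1.0)).all():
                bad = row_ids[int(np.flatnonzero(~np.isin(values, (0.0, 1.0)).all(axis=1))[0])]
                raise MatrixParseError(
                    f"{path}: non-binary cell in row {bad!r}"
                )
            if polarity is None:
                sidecar = path.with_suffix(path.suffix + ".json")
                if sidecar.exists():
                    polarity = json.loads(sidecar.read_text()).get(
                        "polarity", "side_effects"
                    )
                else:
                    polarity = "side_effects"
            return AssociationMatrix(
                values=values.astype(np.int8),
                drug_ids=row_ids,
                phenotype_ids=col_ids,
                polarity=polarity,
            )
    except InvalidInputError as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc
    raise InvalidInputError(f"unknown matrix kind {kind!r}")


def _format_cell(x: float) -> str:
    if np.isnan(x):
        return "NA"
    return repr(float(x))


def write_matrix(obj, path: str | Path) -> None:
    """Write a matrix container as TSV; round-trips exactly through
    :func:`read_matrix`. Associations also emit a ``<path>.json`` sidecar
    recording the polarity."""
    path = Path(path)
    if isinstance(obj, EndpointMatrix):
        row_ids, col_ids = obj.drug_ids, obj.endpoint_ids
        rows = [[_format_cell(v) for v in row] for row in obj.values]
    elif isinstance(obj, GeneScoreMatrix):
        row_ids, col_ids = obj.gene_ids, obj.phenotype_ids
        rows = [[repr(float(v)) for v in row] for row in obj.values]
    elif isinstance(obj, AssociationMatrix):
        row_ids, col_ids = obj.drug_ids, obj.phenotype_ids
        rows = [[str(int(v)) for v in row] for row in obj.values]
    else:
        raise InvalidInputError(f"cannot write object of type {type(obj)!r}")
    with path.open("w") as fh:
        fh.write("\t".join(["id", *col_ids]) + "\n")
        for rid, row in zip(row_ids, rows):
            fh.write("\t".join([rid, *row]) + "\n")
    if isinstance(obj, AssociationMatrix):
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"polarity": obj.polarity, "format": "draphnet-association"})
            + "\n"
        )


def align(
    D: EndpointMatrix, G: GeneScoreMatrix, Y: AssociationMatrix
) -> tuple[EndpointMatrix, GeneScoreMatrix, AssociationMatrix]:
    """Align the three inputs on shared drug and phenotype identifiers.

    Drugs are ordered as in ``D`` restricted to drugs present in ``Y``;
    phenotypes as in ``G`` restricted to phenotypes present in ``Y``.
    Raises if the intersections are empty.
    """
    drugs = [d for d in D.drug_ids if d in set(Y.drug_ids)]
    phenos = [p for p in G.phenotype_ids if p in set(Y.phenotype_ids)]
    if not drugs:
        raise InvalidInputError("no shared drugs between D and Y")
    if not phenos:
        raise InvalidInputError("no shared phenotypes between G and Y")
    d_idx = [D.drug_ids.index(d) for d in drugs]
    y_d_idx = [Y.drug_ids.index(d) for d in drugs]
    g_idx = [G.phenotype_ids.index(p) for p in phenos]
    y_p_idx = [Y.phenotype_ids.index(p) for p in phenos]
    D2 = EndpointMatrix(
        values=D.values[d_idx],
        drug_ids=drugs,
        endpoint_ids=list(D.endpoint_ids),
    )
    G2 = GeneScoreMatrix(
        values=G.values[:, g_idx],
        gene_ids=list(G.gene_ids),
        phenotype_ids=phenos,
    )
    Y2 = AssociationMatrix(
        values=Y.values[np.ix_(y_d_idx, y_p_idx)],
        drug_ids=drugs,
        phenotype_ids=phenos,
        polarity=Y.polarity,
    )
    return D2, G2, Y2
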