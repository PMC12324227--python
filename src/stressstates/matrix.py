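"""Count-matrix data model, I/O, QC filtering, normalisation and sampling.

The central container is :class:`CountMatrix`: a sparse cells × genes integer
count matrix with per-cell treatment metadata (chemical label, concentration
in μM) and unique gene identifiers.  Depth normalisation follows the common
counts-per-10k convention (each cell scaled to 10,000 total counts) followed
by ``log2(x + 1)``; provenance flags on :class:`NormMatrix` enforce the
filter → normalise → log order.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

CELL_META_COLUMNS = ("chemical", "conc")


class MatrixError(ValueError):
    """Raised on malformed or inconsistent count-matrix input."""


def _validate_meta(cell_meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_META_COLUMNS if c not in cell_meta.columns]
    if missing:
        raise MatrixError(f"cell_meta missing columns: {missing}")
    if cell_meta.index.duplicated().any():
        dupes = cell_meta.index[cell_meta.index.duplicated()].tolist()[:5]
        raise MatrixError(f"duplicate cell ids: {dupes}")
    return cell_meta


@dataclass
class CountMatrix:
    """Sparse cells × genes non-negative integer counts with annotations.

    Parameters
    ----------
    X : scipy.sparse matrix
        Counts, one row per cell, one column per gene.
    cell_meta : pandas.DataFrame
        Indexed by unique cell id, with at least ``chemical`` (treatment
        label) and ``conc`` (concentration, μM; 0 for vehicle control).
    gene_ids : pandas.Index
        Unique, ordered gene identifiers, one per column.
    """

    X: sp.spmatrix
    cell_meta: pd.DataFrame
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.gene_ids = pd.Index(self.gene_ids)
        if self.gene_ids.duplicated().any():
            dupes = self.gene_ids[self.gene_ids.duplicated()].tolist()[:5]
            raise MatrixError(f"duplicate gene ids: {dupes}")
        _validate_meta(self.cell_meta)
        if self.X.shape != (len(self.cell_meta), len(self.gene_ids)):
            raise MatrixError(
                f"shape {self.X.shape} does not match {len(self.cell_meta)} "
                f"cells × {len(self.gene_ids)} genes"
            )
        if self.X.nnz and self.X.data.min() < 0:
            raise MatrixError("negative counts")
        if self.X.nnz and np.any(self.X.data != np.floor(self.X.data)):
            raise MatrixError("non-integer counts")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    def total_counts(self) -> np.ndarray:
        """Per-cell total counts."""
        return np.asarray(self.X.sum(axis=1)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Per-cell number of genes with count > 0."""
        return np.diff(self.X.indptr)

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        """Return a new matrix restricted to the given cells (order kept)."""
        if isinstance(mask_or_ids, (pd.Index, list)):
            pos = self.cell_meta.index.get_indexer(mask_or_ids)
            if (pos < 0).any():
                raise MatrixError("unknown cell ids in subset")
        else:
            pos = np.flatnonzero(np.asarray(mask_or_ids))
        return CountMatrix(self.X[pos], self.cell_meta.iloc[pos], self.gene_ids)

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        """Group cells by (chemical, conc)."""
        return self.cell_meta.groupby(["chemical", "conc"], sort=True)

    # -- I/O -----------------------------------------------------------

    def write_mtx(self, outdir: str | Path) -> None:
        """Write MatrixMarket triplet plus genes.tsv / cells.tsv companions."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(self.X))
        pd.Series(self.gene_ids).to_csv(
            outdir / "genes.tsv", sep="\t", header=False, index=False
        )
        self.cell_meta.reset_index(names="cell_id").to_csv(
            outdir / "cells.tsv", sep="\t", index=False
        )

    def write_csv(self, path: str | Path) -> None:
        """Write a dense CSV (cells as rows) with chemical/conc columns."""
        df = pd.DataFrame(
            self.X.toarray(), index=self.cell_meta.index, columns=self.gene_ids
        )
        out = pd.concat([self.cell_meta[list(CELL_META_COLUMNS)], df], axis=1)
        out.to_csv(path, index_label="cell_id")


def load_counts(path: str | Path, format: str = "mtx") -> CountMatrix:
    """Load a :class:`CountMatrix` from disk.

    ``format="mtx"`` expects a directory with ``matrix.mtx``, ``genes.tsv``
    (one gene id per line) and ``cells.tsv`` (cell_id, chemical, conc).
    Orientation is resolved by matching the companion table lengths against
    the matrix dimensions.  ``format="csv"`` expects the dense layout written
    by :meth:`CountMatrix.write_csv`.
    """
    path = Path(path)
    if format == "mtx":
        try:
            m = scipy.io.mmread(str(path / "matrix.mtx"))
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise MatrixError(f"cannot parse {path / 'matrix.mtx'}: {exc}") from exc
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
        cells = pd.read_csv(path / "cells.tsv", sep="\t")
        if "cell_id" not in cells.columns:
            raise MatrixError("cells.tsv must have a cell_id column")
        n_c, n_g = len(cells), len(genes)
        if m.shape == (n_c, n_g):
            pass
        elif m.shape == (n_g, n_c):
            m = m.T
        else:
            raise MatrixError(
                f"matrix shape {m.shape} matches neither {n_c} cells × "
                f"{n_g} genes nor its transpose"
            )
        if n_c == n_g and m.shape[0] == m.shape[1]:
            logger.warning("square matrix: assuming cells × genes orientation")
        meta = cells.set_index("cell_id")
        return CountMatrix(sp.csr_matrix(m), meta, pd.Index(genes))
    if format == "csv":
        df = pd.read_csv(path, index_col="cell_id")
        meta = df[list(CELL_META_COLUMNS)]
        values = df.drop(columns=list(CELL_META_COLUMNS))
        return CountMatrix(
            sp.csr_matrix(values.to_numpy()), meta, pd.Index(values.columns)
        )
    raise MatrixError(f"unknown format {format!r}")


@dataclass
class NormMatrix:
    """Real-valued cells × genes matrix with normalisation provenance.

    ``normalized`` means rows were scaled to 10,000 counts per cell;
    ``logged`` means values are ``log2(x + 1)`` of the normalised values.
    """

    values: np.ndarray
    cell_meta: pd.DataFrame
    gene_ids: pd.Index
    normalized: bool = False
    logged: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids)
        _validate_meta(self.cell_meta)
        if self.values.shape != (len(self.cell_meta), len(self.gene_ids)):
            raise MatrixError("values shape does not match annotations")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.cell_meta.index, columns=self.gene_ids
        )

    def save(self, path: str | Path) -> None:
        """Persist as compressed npz with provenance flags."""
        np.savez_compressed(
            path,
            values=self.values,
            cell_meta=self.cell_meta.reset_index(names="cell_id")
            .to_json(orient="records")
            .encode(),
            gene_ids=np.asarray(self.gene_ids, dtype=str),
            flags=np.array([self.normalized, self.logged]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "NormMatrix":
        with np.load(path, allow_pickle=False) as data:
            meta = pd.read_json(
                io.BytesIO(data["cell_meta"].tobytes())
            ).set_index("cell_id")
            meta["conc"] = meta["conc"].astype(float)  # json drops the dtype
            flags = data["flags"]
            return cls(
                data["values"],
                meta,
                pd.Index(data["gene_ids"]),
                normalized=bool(flags[0]),
                logged=bool(flags[1]),
            )


# -- QC and normalisation ---------------------------------------------


def filter_cells(
    cm: CountMatrix, min_counts: int = 10_000, min_genes: int = 1_000
) -> CountMatrix:
    """Drop cells with ≤ ``min_counts`` total counts or ≤ ``min_genes``
    detected genes (strict 'more than' thresholds).

    The gene set is unchanged.  Removal counts per treatment are logged.
    """
    if min_counts < 0 or min_genes < 0:
        raise MatrixError("thresholds must be >= 0")
    totals = cm.total_counts()
    detected = cm.detected_genes()
    keep = (totals > min_counts) & (detected > min_genes)
    if not keep.any():
        raise MatrixError(
            f"QC removed all {cm.n_cells} cells "
            f"(min_counts={min_counts}, min_genes={min_genes})"
        )
    removed = cm.cell_meta.loc[~keep].groupby(["chemical", "conc"]).size()
    for (chem, conc), n in removed.items():
        logger.info("QC removed %d cells from %s @ %g uM", n, chem, conc)
    return cm.subset_cells(keep)


def normalize_cp10k(cm: CountMatrix) -> NormMatrix:
    """Scale each cell to 10,000 total counts (CP10K)."""
    totals = cm.total_counts()
    if np.any(totals == 0):
        raise MatrixError("zero-total cells present; run filter_cells first")
    values = cm.X.multiply(10_000.0 / totals[:, None]).toarray()
    return NormMatrix(values, cm.cell_meta.copy(), cm.gene_ids, normalized=True)


def log2_transform(nm: NormMatrix, force: bool = False) -> NormMatrix:
    """Apply ``log2(x + 1)`` to a normalised matrix.

    Refuses already-logged input, and refuses un-normalised input unless
    ``force=True`` (variance stabilisation assumes depth was removed first).
    """
    if nm.logged:
        raise MatrixError("matrix is already log-transformed")
    if not nm.normalized and not force:
        raise MatrixError("normalise before log-transforming (or pass force=True)")
    return NormMatrix(
        np.log2(nm.values + 1.0),
        nm.cell_meta.copy(),
        nm.gene_ids,
        normalized=nm.normalized,
        logged=True,
    )


def select_hvg(nm: NormMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Rank genes by a binned standardised-variance score and return the top n.

    Per-gene variances of the (log-)normalised values are standardised
    against a mean-expression trend estimated in equal-occupancy bins
    (median/MAD within each bin, robust to the highly variable genes
    themselves), which removes the mean–variance relationship of count
    data.  Ties break by gene id (ascending) for determinism.
    """
    if n > nm.n_genes:
        raise MatrixError(f"requested {n} HVGs but only {nm.n_genes} genes")
    n_bins = max(1, min(n_bins, nm.n_genes // 10 or 1))
    means = nm.values.mean(axis=0)
    variances = nm.values.var(axis=0, ddof=1)
    order = np.argsort(means, kind="stable")
    bins = np.empty(nm.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(nm.n_genes) * n_bins) // nm.n_genes, n_bins - 1
    )
    score = np.empty(nm.n_genes)
    for b in range(n_bins):
        in_bin = bins == b
        if not in_bin.any():
            continue
        v = variances[in_bin]
        med = np.median(v)
        mad = 1.4826 * np.median(np.abs(v - med))
        scale = mad if mad > 0 else (v.std(ddof=0) or 1.0)
        score[in_bin] = (v - med) / scale
    ranking = pd.DataFrame({"score": score, "gene": nm.gene_ids}).sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    )
    return ranking["gene"].head(n).tolist()


def stratified_sample(cm: CountMatrix, per_group: int, seed: int) -> CountMatrix:
    """Sample up to ``per_group`` cells per (chemical, conc) group without
    replacement; deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    keep_pos: list[np.ndarray] = []
    pos_lookup = pd.Series(np.arange(cm.n_cells), index=cm.cell_meta.index)
    for _, grp in cm.groups():
        pos = pos_lookup[grp.index].to_numpy()
        if len(pos) > per_group:
            pos = rng.choice(pos, size=per_group, replace=False)
        keep_pos.append(np.sort(pos))
    pos = np.concatenate(keep_pos)
    return CountMatrix(cm.X[pos], cm.cell_meta.iloc[pos], cm.gene_ids)


def batch_correction_hook(nm: NormMatrix, corrector=None) -> NormMatrix:
    """Optional hook for an external batch-correction algorithm.

    ``corrector`` is a callable mapping a values array to a corrected array
    of the same shape (e.g. a Harmony wrapper); the default is a no-op.
    """
    if corrector is None:
        return nm
    corrected = np.asarray(corrector(nm.values))
    if corrected.shape != nm.values.shape:
        raise MatrixError("batch corrector changed the matrix shape")
    return NormMatrix(
        corrected, nm.cell_meta.copy(), nm.gene_ids, nm.normalized, nm.logged
    )
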