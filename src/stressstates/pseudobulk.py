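"""Pseudo-bulk aggregation and simplified NB Wald differential expression.

Bulk-like replicate profiles are formed per treatment by partitioning its
cells into disjoint random subsets (default: three replicates of one third
of the cells each) and summing raw counts.  Differential expression against
the control then uses a negative-binomial GLM with log link, median-of-ratios
size-factor offsets, and a pooled method-of-moments dispersion — a
deliberately simple stand-in for a full shrinkage-based bulk DE fit.  The
reported effect is bL2FC, the log2 fold-change of the treatment group, with
two-sided Wald p-values and Benjamini–Hochberg q-values.

``export_deseq2`` writes counts + coldata CSVs for users who want to run an
external bulk DE tool on the same pseudo-bulk table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)


class PseudoBulkError(ValueError):
    pass


@dataclass
class PseudoBulkTable:
    """Genes × samples summed counts with replicate provenance.

    ``counts`` is genes × samples; ``sample_meta`` has one row per sample
    with chemical, conc and replicate index; ``members`` records which cell
    ids were summed into each sample.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    members: dict[str, list[str]] = field(default_factory=dict)
    frac: float = 1 / 3
    seed: int | None = None

    def group_columns(self, chemical: str, conc: float | None = None) -> list[str]:
        sel = self.sample_meta["chemical"] == chemical
        if conc is not None:
            sel &= self.sample_meta["conc"] == conc
        return self.sample_meta.index[sel].tolist()


def make_pseudobulk(
    cm: CountMatrix,
    n_reps: int = 3,
    frac: float = 1 / 3,
    seed: int = 0,
    disjoint: bool = True,
) -> PseudoBulkTable:
    """Partition each treatment's cells into replicates and sum raw counts.

    Each (chemical, conc) group is randomly split into ``n_reps`` disjoint
    subsets of ``floor(frac * n)`` cells (remainder cells unassigned); with
    ``disjoint=False`` each replicate is instead an independent
    without-replacement sample of that size, so replicates may overlap.
    """
    if not 0 < frac <= 1:
        raise PseudoBulkError("frac must be in (0, 1]")
    if disjoint and n_reps * frac > 1 + 1e-9:
        raise PseudoBulkError(f"{n_reps} disjoint replicates of {frac:.2%} exceed 100%")
    rng = np.random.default_rng(seed)
    pos_lookup = pd.Series(np.arange(cm.n_cells), index=cm.cell_meta.index)
    cols, metas, members = {}, [], {}
    for (chem, conc), grp in cm.groups():
        n = len(grp)
        size = int(np.floor(frac * n))
        if size < 1 or n < n_reps:
            raise PseudoBulkError(
                f"treatment {chem} @ {conc:g} has {n} cells; cannot form "
                f"{n_reps} replicates of {frac:.2%}"
            )
        perm = rng.permutation(grp.index.to_numpy())
        for rep in range(n_reps):
            if disjoint:
                ids = perm[rep * size : (rep + 1) * size]
            else:
                ids = rng.choice(grp.index.to_numpy(), size=size, replace=False)
            name = f"{chem}_{conc:g}_rep{rep + 1}"
            pos = pos_lookup[ids].to_numpy()
            cols[name] = np.asarray(cm.X[pos].sum(axis=0)).ravel()
            metas.append({"sample": name, "chemical": chem, "conc": conc,
                          "replicate": rep + 1})
            members[name] = list(ids)
    counts = pd.DataFrame(cols, index=cm.gene_ids)
    meta = pd.DataFrame(metas).set_index("sample")
    return PseudoBulkTable(counts, meta, members, frac=frac, seed=seed)


def size_factors(pb: PseudoBulkTable) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples, using only
    genes positive in every sample.
    """
    counts = pb.counts.to_numpy(dtype=float)
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=pb.counts.columns, name="size_factor")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise PseudoBulkError(
            "no gene has positive counts in all samples; filter genes first"
        )
    log_counts = np.log(counts[positive])
    log_ref = log_counts.mean(axis=1, keepdims=True)
    log_sf = np.median(log_counts - log_ref, axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=pb.counts.columns, name="size_factor")


def _pooled_dispersion(y: np.ndarray, sf: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion alpha (Var = mu + alpha mu^2),
    pooled across the two groups on size-factor-normalised counts."""
    est = []
    for g in np.unique(groups):
        z = y[groups == g] / sf[groups == g]
        m = z.mean()
        if m > 0 and z.size >= 2:
            est.append((z.var(ddof=1) - m) / m**2)
    if not est:
        return 1e-8
    return max(float(np.mean(est)), 1e-8)


def _nb_wald_gene(
    y: np.ndarray, sf: np.ndarray, is_treat: np.ndarray, alpha: float
) -> tuple[float, float]:
    """Closed-form NB Wald test for a two-group log-link model with offsets.

    The model is mu_j = sf_j * exp(b0 + b1 * treat_j); with a group-wise
    design the MLE satisfies the per-group score equation
    sum_j (y_j - mu_j) / (1 + alpha * mu_j) = 0, solved by fixed point from
    the moment start sum(y)/sum(sf).  Returns (b1, Wald z variance).
    """
    b = np.empty(2)
    info = np.empty(2)
    for gi, sel in enumerate((~is_treat, is_treat)):
        yy, ss = y[sel], sf[sel]
        m = yy.sum() / ss.sum()  # exact MLE when alpha == 0 or sf constant
        for _ in range(50):
            mu = ss * m
            w = 1.0 / (1.0 + alpha * mu)
            m_new = (yy * w).sum() / (ss * w).sum()
            if abs(m_new - m) <= 1e-12 * max(m, 1.0):
                m = m_new
                break
            m = m_new
        b[gi] = np.log(m) if m > 0 else -np.inf
        mu = ss * m
        info[gi] = (mu / (1.0 + alpha * mu)).sum()  # Fisher info for log-mean
    beta = b[1] - b[0]
    var = 1.0 / info[0] + 1.0 / info[1]
    return beta, var


def nb_wald_de(
    pb: PseudoBulkTable,
    treatment: str,
    conc: float | None = None,
    control: str = "DMSO",
    force_unit_size_factors: bool = False,
) -> pd.DataFrame:
    """Per-gene NB Wald differential expression of one treatment vs control.

    Returns a DataFrame indexed by gene with columns bL2FC (log2
    fold-change), se, p_value and q_value (BH).  Genes with zero counts in
    both groups are reported as all-NaN rows; genes expressed in only one
    group get an infinite bL2FC with a NaN p-value (no finite Wald test).
    """
    t_cols = pb.group_columns(treatment, conc)
    c_cols = pb.group_columns(control)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise PseudoBulkError("need >= 2 replicates per group")
    cols = c_cols + t_cols
    counts = pb.counts[cols].to_numpy(dtype=float)
    if force_unit_size_factors:
        sf = np.ones(len(cols))
    else:
        sf = size_factors(pb)[cols].to_numpy()
    is_treat = np.array([c in t_cols for c in cols])

    n_genes = counts.shape[0]
    bl2fc = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    pvals = np.full(n_genes, np.nan)
    for i in range(n_genes):
        y = counts[i]
        if y.sum() == 0:
            continue
        alpha = _pooled_dispersion(y, sf, is_treat)
        beta, var = _nb_wald_gene(y, sf, is_treat, alpha)
        bl2fc[i] = beta / LN2
        if not np.isfinite(beta):
            continue
        se[i] = np.sqrt(var) / LN2
        z = beta / np.sqrt(var)
        pvals[i] = 2.0 * stats.norm.sf(abs(z))
    out = pd.DataFrame(
        {"bL2FC": bl2fc, "se": se, "p_value": pvals}, index=pb.counts.index
    )
    out["q_value"] = np.nan
    ok = out["p_value"].notna().to_numpy()
    if ok.any():
        out.loc[ok, "q_value"] = bh_adjust(out.loc[ok, "p_value"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise PseudoBulkError("p-values outside [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def export_deseq2(pb: PseudoBulkTable, outdir: str | Path) -> None:
    """Write counts.csv (genes × samples) and coldata.csv for external bulk
    DE tools."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pb.counts.to_csv(outdir / "counts.csv", index_label="gene")
    pb.sample_meta.to_csv(outdir / "coldata.csv", index_label="sample")
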