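"""Per-cell connectivity scoring of stress-pathway signatures.

Each cell's (log-normalised) expression is standardised gene-wise against
the vehicle-control population (z = (x - mu_DMSO) / sd_DMSO), its 200 most
up- and 200 most down-regulated genes are selected (the Z200 set), and the
signed overlap with each pathway signature is scored with a generalized
Jaccard (gj) similarity.  For up-set U, down-set D and signature genes with
positive / negative sign S+ / S-::

    gj = (|U ∩ S+| + |D ∩ S-| - |U ∩ S-| - |D ∩ S+|) / |U ∪ D ∪ S|

which lies in [-1, 1]: +1 when the cell's extreme genes exactly match the
signature in the concordant direction, negative when they oppose it.  A
weighted variant (min/max of clipped |z| magnitudes) is available.  Raw gj
scores are finally standardised per (pathway, signature size) against the
control cells' scores, so a score of z_gj = 1 reads "one control-SD above
the control mean".

Effect sizes of concentration and signature length on the scores are
quantified per (chemical, pathway) with a two-way ANOVA (sequential sums of
squares) reporting eta-squared and slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .matrix import NormMatrix
from .signatures import SignatureLibrary

logger = logging.getLogger(__name__)

#: Cohen-style eta-squared interpretation bands.
ETA_SQUARED_BANDS = ((0.14, "large"), (0.06, "medium"), (0.01, "small"))

DEFAULT_N_EXTREME = 200


class ConnectivityError(ValueError):
    pass


@dataclass
class ZMatrix:
    """Cells × genes z-scores relative to the control population.

    Genes constant in the control (sd = 0) are excluded and listed in
    ``excluded_genes``.
    """

    z: np.ndarray
    cell_meta: pd.DataFrame
    gene_ids: pd.Index
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.z.shape[0]


def standardize_to_control(nm: NormMatrix, control_label: str = "DMSO") -> ZMatrix:
    """Per-gene z-scores against the mean/SD (ddof=1) of control cells."""
    is_control = (nm.cell_meta["chemical"] == control_label).to_numpy()
    if is_control.sum() < 2:
        raise ConnectivityError("need >= 2 control cells to standardise")
    ctrl = nm.values[is_control]
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ConnectivityError("every gene is constant in the control")
    excluded = nm.gene_ids[~keep].tolist()
    if excluded:
        logger.info("excluding %d genes constant in control", len(excluded))
    z = (nm.values[:, keep] - mu[keep]) / sd[keep]
    return ZMatrix(z, nm.cell_meta.copy(), nm.gene_ids[keep], excluded)


@dataclass
class Z200:
    """A cell's signed extreme-gene set: top up- and down-regulated genes."""

    up: dict[str, float]    # gene -> z > 0
    down: dict[str, float]  # gene -> z < 0

    @property
    def genes(self) -> set[str]:
        return set(self.up) | set(self.down)


def select_z200(z_row, gene_ids, n: int = DEFAULT_N_EXTREME) -> Z200:
    """Select the n largest strictly-positive and n smallest strictly-negative
    z genes; ties break by gene id for determinism."""
    s = pd.Series(np.asarray(z_row, dtype=float), index=pd.Index(gene_ids))
    s = s[np.isfinite(s.values)]
    pos = s[s > 0].sort_values(ascending=False, kind="stable")
    neg = s[s < 0].sort_values(ascending=True, kind="stable")
    # stable sort on values then ids: re-sort equal values by gene id
    pos = pos.iloc[np.lexsort((pos.index, -pos.values))].head(n)
    neg = neg.iloc[np.lexsort((neg.index, neg.values))].head(n)
    return Z200(pos.to_dict(), neg.to_dict())


def gj_score(
    z200: Z200,
    signature: list[str],
    signs: dict[str, float] | None = None,
    weighted: bool = False,
) -> float:
    """Generalized Jaccard similarity between a Z200 set and a signature.

    ``signs`` gives each signature gene a direction (+1 up-regulated in the
    pathway, -1 down; default +1 for all).  In the weighted variant the
    numerator is the sum of sign-agreement * min(|a|, |b|) and the
    denominator the sum of max(|a|, |b|) over the union, with Z200 weights
    clipped to [-1, 1].
    """
    if not signature:
        raise ConnectivityError("empty signature")
    sig_sign = {g: (signs or {}).get(g, 1.0) for g in signature}
    if not weighted:
        s_pos = {g for g, w in sig_sign.items() if w >= 0}
        s_neg = {g for g, w in sig_sign.items() if w < 0}
        u, d = set(z200.up), set(z200.down)
        num = (
            len(u & s_pos) + len(d & s_neg) - len(u & s_neg) - len(d & s_pos)
        )
        denom = len(u | d | s_pos | s_neg)
        return num / denom if denom else 0.0
    cell_w = {g: min(max(w, -1.0), 1.0) for g, w in z200.up.items()}
    cell_w.update({g: min(max(w, -1.0), 1.0) for g, w in z200.down.items()})
    num = 0.0
    denom = 0.0
    for g in set(cell_w) | set(sig_sign):
        a = cell_w.get(g, 0.0)
        b = sig_sign.get(g, 0.0)
        denom += max(abs(a), abs(b))
        if a and b:
            num += (1.0 if a * b > 0 else -1.0) * min(abs(a), abs(b))
    return num / denom if denom else 0.0


@dataclass
class ScoreTensor:
    """Raw and control-standardised gj scores per (cell, pathway, size).

    ``raw`` and ``z`` are arrays of shape (n_cells, n_srps, n_sizes); the
    standardised ``z`` is (raw - mean) / sd of the control cells' raw scores
    per (pathway, size) slice.
    """

    raw: np.ndarray
    z: np.ndarray
    cell_meta: pd.DataFrame
    srps: tuple[str, ...]
    sizes: tuple[int, ...]

    def frame(self, with_meta: bool = False) -> pd.DataFrame:
        """Long-form (cell, srp, size, raw, z) table, optionally with the
        per-cell chemical/conc columns attached."""
        idx = pd.MultiIndex.from_product(
            [self.cell_meta.index, self.srps, self.sizes],
            names=["cell_id", "srp", "size"],
        )
        out = pd.DataFrame(
            {"raw": self.raw.ravel(), "z": self.z.ravel()}, index=idx
        ).reset_index()
        if with_meta:
            out = out.merge(
                self.cell_meta[["chemical", "conc"]].reset_index(names="cell_id"),
                on="cell_id",
            )
        return out

    def z_frame(self, size: int) -> pd.DataFrame:
        """Cells × pathways standardised scores at one signature size."""
        k = self.sizes.index(size)
        return pd.DataFrame(
            self.z[:, :, k], index=self.cell_meta.index, columns=list(self.srps)
        )


def score_cells(
    zm: ZMatrix,
    lib: SignatureLibrary,
    sizes: tuple[int, ...] | None = None,
    n_extreme: int = DEFAULT_N_EXTREME,
    control_label: str = "DMSO",
    weighted: bool = False,
) -> ScoreTensor:
    """gj scores of every cell against every signature at every size,
    standardised against the control cells."""
    sizes = tuple(sizes or lib.sizes)
    srps = tuple(lib.names)
    matrix_genes = set(zm.gene_ids)
    usable: list[str] = []
    for name in srps:
        if matrix_genes & set(lib.genes[name]):
            usable.append(name)
        else:
            logger.warning("signature %s shares no genes with the matrix", name)
    raw = np.full((zm.n_cells, len(srps), len(sizes)), np.nan)
    sig_cache = {
        (name, size): [g for g in lib.at_size(name, size)]
        for name in usable
        for size in sizes
    }
    for ci in range(zm.n_cells):
        z200 = select_z200(zm.z[ci], zm.gene_ids, n=n_extreme)
        for si, name in enumerate(srps):
            if name not in usable:
                continue
            signs = lib.weights.get(name)
            for ki, size in enumerate(sizes):
                raw[ci, si, ki] = gj_score(
                    z200, sig_cache[(name, size)], signs, weighted=weighted
                )
    is_control = (zm.cell_meta["chemical"] == control_label).to_numpy()
    if is_control.sum() < 2:
        raise ConnectivityError("need >= 2 control cells to standardise scores")
    mu = raw[is_control].mean(axis=0)
    sd = raw[is_control].std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (raw - mu) / sd
    return ScoreTensor(raw, z, zm.cell_meta.copy(), srps, sizes)


def effect_band(eta_sq: float) -> str:
    for cut, label in ETA_SQUARED_BANDS:
        if eta_sq >= cut:
            return label
    return "negligible"


def anova_effects(
    scores: ScoreTensor,
    log_conc: bool = False,
    pseudocount: float = 1e-4,
) -> pd.DataFrame:
    """Two-way ANOVA of standardised scores on concentration and signature
    length, per (chemical, pathway).

    Both factors enter as numeric covariates in an additive linear model
    ``z ~ conc + length`` with sequential (type-I) sums of squares in that
    order.  Eta-squared is SS_factor / SS_total; slopes are the fitted
    coefficients.  Concentration is raw μM (control = 0) unless
    ``log_conc`` requests log10(conc + pseudocount).
    """
    long = scores.frame().merge(
        scores.cell_meta[["chemical", "conc"]].reset_index(names="cell_id"),
        on="cell_id",
    )
    # the control population enters every chemical's model at conc = 0
    is_ctrl = long["conc"] == 0
    ctrl_block = long[is_ctrl]
    rows = []
    for (chem, srp), sub in long[~is_ctrl].groupby(["chemical", "srp"], sort=True):
        sub = pd.concat([sub, ctrl_block[ctrl_block["srp"] == srp]])
        sub = sub.dropna(subset=["z"])
        conc = sub["conc"].to_numpy(dtype=float)
        if log_conc:
            conc = np.log10(conc + pseudocount)
        df = pd.DataFrame(
            {"z": sub["z"].to_numpy(), "conc": conc,
             "length": sub["size"].to_numpy(dtype=float)}
        )
        if df["conc"].nunique() < 2 or df["length"].nunique() < 2:
            continue
        model = smf.ols("z ~ conc + length", data=df).fit()
        ss_total = ((df["z"] - df["z"].mean()) ** 2).sum()
        if ss_total == 0:
            for factor in ("conc", "length"):
                rows.append(
                    {"chemical": chem, "srp": srp, "factor": factor,
                     "eta_squared": 0.0, "slope": 0.0, "p_value": np.nan,
                     "band": "negligible"}
                )
            continue
        tab = anova_lm(model, typ=1)
        for factor in ("conc", "length"):
            eta = float(tab.loc[factor, "sum_sq"] / ss_total)
            rows.append(
                {
                    "chemical": chem,
                    "srp": srp,
                    "factor": factor,
                    "eta_squared": eta,
                    "slope": float(model.params[factor]),
                    "p_value": float(tab.loc[factor, "PR(>F)"]),
                    "band": effect_band(eta),
                }
            )
    return pd.DataFrame(rows)
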