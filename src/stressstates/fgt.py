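"""FGT1+: the per-gene fraction of responsive treated cells.

For a gene with control mean ``mu_ctrl``, the statistic counts the fraction
f0 of treated cells whose expression strictly exceeds the threshold
``T = mu_ctrl * 2**L2FC0`` (default L2FC0 = 1, a two-fold increase).  The
null model is a negative binomial fitted to the control cells by the method
of moments::

    m = mean(control),  v = var(control, ddof=1)
    r = m^2 / (v - m),  p = m / v          (requires v > m)

with Poisson and degenerate fallbacks when the control is under-dispersed
(v <= m) or constant.  The null exceedance probability is the survival
function pi = P(X > floor(T)); the p-value is the binomial upper tail
P(Binom(n1, pi) >= k) — the probability of observing at least as many
exceeding cells by chance among the n1 treated cells.

The statistic operates on RAW counts by default.  Under the null the
treated and control cells share the same depth distribution, so depth
variation enters both the exceedance counts and the fitted null
symmetrically and is absorbed into the method-of-moments overdispersion;
rescaling counts per cell (counts-per-10k or similar) breaks the integer
lattice the NB tail is evaluated on and turns the data into a mixture of
differently-scaled NBs whose tail the moment-matched NB underestimates —
measurably worse p-value calibration.  A ``target_depth`` option is
provided for depth-imbalanced designs; the moment fit itself does not
require integer values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.05, 0.1, 0.2)


class FgtError(ValueError):
    pass


@dataclass
class NBControlModel:
    """Method-of-moments null model of control expression for one gene.

    ``family`` is 'NB' when over-dispersed (v > m), 'Poisson' when
    0 < v <= m, and 'degenerate' for a constant control vector.
    """

    m: float
    v: float
    family: str
    r: float = float("nan")
    p: float = float("nan")

    def survival(self, threshold: float) -> float:
        """P(X > floor(threshold)) under the fitted family."""
        t = np.floor(threshold)
        if self.family == "NB":
            return float(stats.nbinom.sf(t, self.r, self.p))
        if self.family == "Poisson":
            return float(stats.poisson.sf(t, self.m))
        return float(self.m > threshold)


def fit_nb_mom(control_values) -> NBControlModel:
    """Fit the control null model by the method of moments."""
    x = np.asarray(control_values, dtype=float)
    if x.size < 2:
        raise FgtError("need at least 2 control values")
    if np.any(x < 0):
        raise FgtError("negative control values")
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if v == 0.0:
        return NBControlModel(m, v, "degenerate")
    if v <= m:
        return NBControlModel(m, v, "Poisson")
    r = m * m / (v - m)
    return NBControlModel(m, v, "NB", r=r, p=m / v)


def exceedance_prob(model: NBControlModel, threshold: float) -> float:
    """Null probability that a single cell's expression exceeds ``threshold``."""
    if threshold < 0:
        raise FgtError("threshold must be >= 0")
    return model.survival(threshold)


@dataclass
class FgtResult:
    """FGT result for one gene under one treatment condition."""

    gene: str
    chemical: str
    conc: float
    l2fc0: float
    threshold: float
    n_treated: int
    n_control: int
    k_exceed: int
    f0: float
    pi0: float
    p_value: float


def fgt_test(
    treated,
    control,
    l2fc0: float = 1.0,
    gene: str = "",
    chemical: str = "",
    conc: float = float("nan"),
    downregulation: bool = False,
) -> FgtResult:
    """FGT test for one gene.

    With ``downregulation=True`` the mirrored FGT1- variant is computed:
    threshold ``T' = mu_ctrl * 2**(-l2fc0)``, counting treated cells
    strictly below T' against the lower-tail null probability.  This mirror
    is an extension beyond the upregulation statistic.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0:
        raise FgtError("empty treated vector")
    model = fit_nb_mom(control)
    n1 = int(treated.size)
    if downregulation:
        threshold = model.m * 2.0 ** (-l2fc0)
        k = int((treated < threshold).sum())
        t = np.floor(threshold)
        if model.family == "NB":
            pi = float(stats.nbinom.cdf(t - 1, model.r, model.p))
        elif model.family == "Poisson":
            pi = float(stats.poisson.cdf(t - 1, model.m))
        else:
            pi = float(model.m < threshold)
    else:
        threshold = model.m * 2.0**l2fc0
        k = int((treated > threshold).sum())
        pi = model.survival(threshold)
    f0 = k / n1
    if model.family == "degenerate" and model.m == 0.0 and l2fc0 != 0.0:
        # all-zero control: the threshold is 0 and no fold-change is defined
        return FgtResult(
            gene, chemical, conc, l2fc0, 0.0, n1, control.size, k, f0,
            float("nan"), float("nan"),
        )
    p = 1.0 if k == 0 else float(stats.binom.sf(k - 1, n1, pi))
    return FgtResult(
        gene, chemical, conc, l2fc0, float(threshold), n1, int(control.size),
        k, f0, pi, p,
    )


def _vectorized_fgt(
    treated: np.ndarray, control: np.ndarray, l2fc0: float
) -> pd.DataFrame:
    """FGT over all genes at once for one treatment block.

    ``treated`` and ``control`` are cells × genes arrays on the normalised
    scale.  Returns one row per gene.
    """
    n1, n_genes = treated.shape
    n2 = control.shape[0]
    m = control.mean(axis=0)
    v = control.var(axis=0, ddof=1)
    threshold = m * 2.0**l2fc0
    k = (treated > threshold[None, :]).sum(axis=0)
    f0 = k / n1

    pi = np.full(n_genes, np.nan)
    t = np.floor(threshold)
    nb = v > m
    if nb.any():
        r = m[nb] ** 2 / (v[nb] - m[nb])
        pi[nb] = stats.nbinom.sf(t[nb], r, m[nb] / v[nb])
    pois = (v <= m) & (v > 0)
    if pois.any():
        pi[pois] = stats.poisson.sf(t[pois], m[pois])
    degen = v == 0
    if degen.any():
        pi[degen] = (m[degen] > threshold[degen]).astype(float)
    unscorable = degen & (m == 0) & (l2fc0 != 0)

    p = np.where(k == 0, 1.0, stats.binom.sf(k - 1, n1, pi))
    p = np.where(unscorable, np.nan, p)
    pi = np.where(unscorable, np.nan, pi)
    return pd.DataFrame(
        {
            "threshold": np.where(unscorable, 0.0, threshold),
            "n1": n1,
            "n2": n2,
            "k_exceed": k,
            "f0": f0,
            "pi0": pi,
            "p": p,
        }
    )


def fgt_screen(
    cm: CountMatrix,
    control_label: str = "DMSO",
    l2fc0: float = 1.0,
    alpha: float = 0.1,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    target_depth: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FGT for every gene × (chemical, conc) condition.

    Operates on raw counts unless ``target_depth`` is given, in which case
    each cell is rescaled to that total count (see the module docstring for
    why raw counts are the default).  Returns ``(results, summary)``: a
    tidy per-gene table with BH q-values computed within each (chemical,
    conc) stratum, and a per-condition summary counting genes with
    ``p < alpha`` whose f0 exceeds each of the reporting thresholds
    (default 0.05 / 0.1 / 0.2).
    """
    if target_depth is not None:
        totals = cm.total_counts()
        if np.any(totals == 0):
            raise FgtError("zero-total cells present; run filter_cells first")
        values = cm.X.multiply(target_depth / totals[:, None]).toarray()
    else:
        values = cm.X.toarray().astype(float)

    is_control = cm.cell_meta["chemical"] == control_label
    if not is_control.any():
        raise FgtError(f"no control cells labelled {control_label!r}")
    control = values[is_control.to_numpy()]

    results = []
    conditions = (
        cm.cell_meta.loc[~is_control, ["chemical", "conc"]]
        .drop_duplicates()
        .sort_values(["chemical", "conc"])
    )
    for chem, conc in conditions.itertuples(index=False):
        sel = (
            (cm.cell_meta["chemical"] == chem) & (cm.cell_meta["conc"] == conc)
        ).to_numpy()
        block = _vectorized_fgt(values[sel], control, l2fc0)
        block.insert(0, "gene", cm.gene_ids)
        block.insert(1, "chemical", chem)
        block.insert(2, "conc", conc)
        ok = block["p"].notna()
        q = np.full(len(block), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(block.loc[ok, "p"], method="fdr_bh")[1]
        block["q"] = q
        results.append(block)
    table = pd.concat(results, ignore_index=True)
    return table, summarize_thresholds(table, alpha, thresholds)


def summarize_thresholds(
    table: pd.DataFrame,
    alpha: float = 0.1,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Count genes per condition with p < alpha and f0 above each threshold."""
    rows = []
    for (chem, conc), sub in table.groupby(["chemical", "conc"], sort=True):
        sig = sub[sub["p"] < alpha]
        row = {"chemical": chem, "conc": conc, "n_significant": len(sig)}
        for thr in thresholds:
            row[f"fgt_gt_{thr:g}"] = int((sig["f0"] > thr).sum())
        rows.append(row)
    return pd.DataFrame(rows)
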