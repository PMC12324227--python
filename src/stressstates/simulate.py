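"""Synthetic single-cell count data with known stress-response structure.

The generator realises the count model the downstream statistics assume:
per-gene baseline means drawn log-normally, per-cell depth (size) factors
drawn log-normally, and counts drawn negative-binomially with shared size
parameter r, i.e. for gene g in cell c::

    X_cg ~ NB(mean = mu_g * s_c, size = r),   Var = m + m^2 / r

Chemical treatments are emulated as responsive subpopulations: within each
treatment a Bernoulli(responsive_fraction) subset of cells carries a
multiplicative ``2**l2fc`` shift on the mean of every gene in the targeted
stress-pathway signatures, applied to the NB mean so the counts stay NB.
Responder status is drawn once per cell (the targeted programme switches on
coherently), with a per-gene-independent mode behind a flag.  Ground truth
(per-cell responder flags and state labels, per-gene applied effects) is
recorded for parameter-recovery tests.

Default scale is a desk-scale stand-in for a ~22.5k-gene, ~34k-cell
experiment: 2,000 genes and 500 cells per condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import CountMatrix
from .signatures import SignatureLibrary, CooccurrenceTable, DEFAULT_SIZES

#: Fixed stress-response pathway order used throughout (alphabetical).
SRP_LABELS = ("APO", "AUT", "DDR", "HPX", "HSR", "OSR", "SEN", "UPR")

#: Five phenotype archetypes in SRP score space: basal, then increasingly
#: perturbed combinations of adaptive and terminal programmes.
PHENOTYPE_ARCHETYPES: dict[str, tuple[str, ...]] = {
    "I": (),
    "II": ("APO", "DDR"),
    "III": ("HSR", "OSR", "UPR"),
    "IV": ("HPX", "SEN", "DDR"),
    "V": ("AUT", "APO"),
}

CONTROL_CHEMICAL = "DMSO"


class SimulationError(ValueError):
    pass


@dataclass
class TreatmentSpec:
    """One chemical × concentration condition.

    ``l2fc`` is the log2 multiplicative effect applied to the NB mean of
    every gene in the targeted signatures; ``responsive_fraction`` is the
    probability that a cell mounts the response at all.
    """

    chemical: str
    conc: float
    target_srps: tuple[str, ...]
    l2fc: float = 2.0
    responsive_fraction: float = 0.5
    n_cells: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise SimulationError("responsive_fraction must be in [0, 1]")
        if self.conc < 0:
            raise SimulationError("conc must be >= 0")
        if self.conc == 0 and self.chemical != CONTROL_CHEMICAL:
            raise SimulationError("conc = 0 is reserved for the control")
        if self.n_cells < 1:
            raise SimulationError("n_cells must be positive")


@dataclass
class SimConfig:
    """Generator parameters.

    Baseline per-gene means are LogNormal(baseline_log_mean_mu,
    baseline_log_mean_sigma) in counts/cell; with the defaults the mean
    total is ~13k counts per cell over 2,000 genes, comfortably above the
    10k QC threshold and comparable to the per-cell depth of droplet-free
    single-cell chemistry.  ``dispersion`` is the shared NB size r;
    ``depth_log_sigma`` the log-SD of per-cell size factors.
    """

    n_genes: int = 2000
    n_control_cells: int = 500
    baseline_log_mean_mu: float = float(np.log(4.0))
    baseline_log_mean_sigma: float = 1.0
    dispersion: float = 5.0
    depth_log_sigma: float = 0.3
    treatments: list[TreatmentSpec] = field(default_factory=list)
    signatures: SignatureLibrary | None = None
    per_gene_independent: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_control_cells < 1:
            raise SimulationError("n_genes and n_control_cells must be positive")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be > 0")
        if self.depth_log_sigma < 0:
            raise SimulationError("depth_log_sigma must be >= 0")
        labels = [(t.chemical, t.conc) for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise SimulationError("duplicate (chemical, conc) treatment labels")
        if self.treatments:
            if self.signatures is None:
                raise SimulationError("treatments reference signatures but none given")
            known = set(self.signatures.genes)
            for t in self.treatments:
                unknown = set(t.target_srps) - known
                if unknown:
                    raise SimulationError(
                        f"{t.chemical} targets unknown signatures {sorted(unknown)}"
                    )
            if self.n_genes < len(self.signatures.all_genes()):
                raise SimulationError("n_genes smaller than the signature universe")


@dataclass
class GroundTruth:
    """What the generator actually did.

    ``effects``: per (chemical, conc, gene) the applied l2fc and the
    treatment's responsive fraction.  ``cells``: per cell the responder
    flag and true state label (control and non-responders are 'basal';
    responders are labelled by their targeted SRPs).
    """

    effects: pd.DataFrame
    cells: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effects": self.effects.to_dict(orient="list"),
            "cells": self.cells.reset_index(names="cell_id").to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        cells = pd.DataFrame(payload["cells"]).set_index("cell_id")
        return cls(pd.DataFrame(payload["effects"]), cells)


def _gene_ids(n: int) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(n)])


def make_signature_library(
    n_srps: int,
    genes_per_srp: int,
    overlap_fraction: float,
    universe_size: int,
    seed: int,
    names: tuple[str, ...] | None = None,
    sizes: tuple[int, ...] | None = None,
) -> SignatureLibrary:
    """Generate named gene sets over a synthetic gene universe.

    Each signature holds ``genes_per_srp`` genes; an
    ``overlap_fraction * genes_per_srp``-gene core is shared by all
    signatures, the remainder is private, so every pairwise overlap equals
    the requested fraction.  Deterministic under ``seed``.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise SimulationError("overlap_fraction must be in [0, 1)")
    n_core = round(overlap_fraction * genes_per_srp)
    n_private = genes_per_srp - n_core
    needed = n_core + n_srps * n_private
    if needed > universe_size:
        raise SimulationError(
            f"universe of {universe_size} genes too small: need {needed} "
            f"({n_srps} signatures x {n_private} private + {n_core} shared)"
        )
    rng = np.random.default_rng(seed)
    universe = _gene_ids(universe_size)
    picked = rng.choice(universe_size, size=needed, replace=False)
    core = [universe[i] for i in picked[:n_core]]
    if names is None:
        names = tuple(SRP_LABELS[i] if i < len(SRP_LABELS) else f"SRP{i}"
                      for i in range(n_srps))
    genes: dict[str, list[str]] = {}
    for j, name in enumerate(names[:n_srps]):
        start = n_core + j * n_private
        private = [universe[i] for i in picked[start : start + n_private]]
        # core first so the shared genes survive truncation to smaller sizes
        genes[name] = core + private
    if sizes is None:
        sizes = tuple(s for s in DEFAULT_SIZES if s <= genes_per_srp) or (
            genes_per_srp,
        )
    return SignatureLibrary(genes, sizes)


def _draw_counts(rng, mean: np.ndarray, r: float) -> np.ndarray:
    """NB(mean, size r) draws; numpy's (n, p) with p = r/(r+mean)."""
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.int64)


def simulate_control(config: SimConfig) -> CountMatrix:
    """Control (vehicle) population under the baseline NB model."""
    rng = np.random.default_rng(config.seed)
    mu = rng.lognormal(
        config.baseline_log_mean_mu, config.baseline_log_mean_sigma, config.n_genes
    )
    s = rng.lognormal(0.0, config.depth_log_sigma, config.n_control_cells)
    counts = _draw_counts(rng, np.outer(s, mu), config.dispersion)
    meta = pd.DataFrame(
        {"chemical": CONTROL_CHEMICAL, "conc": 0.0},
        index=pd.Index(
            [f"{CONTROL_CHEMICAL}_0_c{i:05d}" for i in range(config.n_control_cells)],
            name="cell_id",
        ),
    )
    return CountMatrix(sp.csr_matrix(counts), meta, _gene_ids(config.n_genes))


def simulate_experiment(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Control plus all treatments, with ground truth.

    Within each treatment a Bernoulli(responsive_fraction) subset of cells
    has the means of its target-signature genes multiplied by ``2**l2fc``;
    all other genes are identical in law to the control.
    """
    rng = np.random.default_rng(config.seed)
    mu = rng.lognormal(
        config.baseline_log_mean_mu, config.baseline_log_mean_sigma, config.n_genes
    )
    gene_ids = _gene_ids(config.n_genes)
    gene_pos = pd.Series(np.arange(config.n_genes), index=gene_ids)

    blocks: list[np.ndarray] = []
    meta_rows: list[pd.DataFrame] = []
    cell_records: list[pd.DataFrame] = []
    effect_records: list[dict] = []

    # control block
    s = rng.lognormal(0.0, config.depth_log_sigma, config.n_control_cells)
    blocks.append(_draw_counts(rng, np.outer(s, mu), config.dispersion))
    ctrl_ids = pd.Index(
        [f"{CONTROL_CHEMICAL}_0_c{i:05d}" for i in range(config.n_control_cells)],
        name="cell_id",
    )
    meta_rows.append(
        pd.DataFrame({"chemical": CONTROL_CHEMICAL, "conc": 0.0}, index=ctrl_ids)
    )
    cell_records.append(
        pd.DataFrame({"responder": False, "state": "basal"}, index=ctrl_ids)
    )

    for t in config.treatments:
        target_genes = sorted(
            set().union(*(config.signatures.genes[srp] for srp in t.target_srps))
        ) if t.target_srps else []
        tpos = gene_pos[target_genes].to_numpy() if target_genes else np.array([], int)
        fold = 2.0**t.l2fc
        s = rng.lognormal(0.0, config.depth_log_sigma, t.n_cells)
        mean = np.outer(s, mu)
        if config.per_gene_independent:
            responders = np.zeros(t.n_cells, dtype=bool)  # no coherent flag
            if t.l2fc != 0 and len(tpos):
                hit = rng.random((t.n_cells, len(tpos))) < t.responsive_fraction
                mean[:, tpos] = np.where(hit, mean[:, tpos] * fold, mean[:, tpos])
        else:
            responders = rng.random(t.n_cells) < t.responsive_fraction
            if t.l2fc != 0 and len(tpos):
                mean[np.ix_(responders, tpos)] *= fold
        blocks.append(_draw_counts(rng, mean, config.dispersion))
        ids = pd.Index(
            [f"{t.chemical}_{t.conc:g}_c{i:05d}" for i in range(t.n_cells)],
            name="cell_id",
        )
        meta_rows.append(
            pd.DataFrame({"chemical": t.chemical, "conc": t.conc}, index=ids)
        )
        state = "+".join(sorted(t.target_srps)) if t.target_srps else "basal"
        flagged = responders if t.l2fc != 0 else np.zeros(t.n_cells, dtype=bool)
        cell_records.append(
            pd.DataFrame(
                {
                    "responder": flagged,
                    "state": np.where(flagged, state, "basal"),
                },
                index=ids,
            )
        )
        for g in target_genes:
            effect_records.append(
                {
                    "chemical": t.chemical,
                    "conc": t.conc,
                    "gene": g,
                    "l2fc": t.l2fc,
                    "responsive_fraction": t.responsive_fraction,
                }
            )

    counts = sp.csr_matrix(np.vstack(blocks))
    cm = CountMatrix(counts, pd.concat(meta_rows), gene_ids)
    truth = GroundTruth(
        pd.DataFrame(
            effect_records,
            columns=["chemical", "conc", "gene", "l2fc", "responsive_fraction"],
        ),
        pd.concat(cell_records),
    )
    return cm, truth


def default_experiment(
    seed: int = 0,
    n_genes: int = 2000,
    cells_per_condition: int = 500,
    genes_per_srp: int = 200,
    control_pool_factor: int = 4,
) -> SimConfig:
    """Desk-scale hepatotoxicant screen: 7 chemicals x 3 rising
    concentrations, each targeting its known stress pathways, with
    dose-dependent responsive fractions.

    The vehicle pool is ``control_pool_factor`` times a treatment group, as
    in screens that share one large DMSO population across all treatments —
    the responsive-fraction p-values need well-estimated control moments.
    """
    lib = make_signature_library(
        n_srps=8,
        genes_per_srp=genes_per_srp,
        overlap_fraction=0.0,
        universe_size=n_genes,
        seed=seed,
    )
    design: list[tuple[str, tuple[str, ...], tuple[float, ...]]] = [
        ("BrefeldinA", ("UPR", "APO"), (0.001, 0.01, 0.1)),
        ("Tunicamycin", ("UPR",), (0.001, 0.01, 0.1)),
        ("Etoposide", ("DDR", "APO"), (0.25, 2.5, 25.0)),
        ("Rotenone", ("OSR", "HPX"), (0.2, 0.4, 0.8)),
        ("tBHQ", ("OSR",), (3.0, 30.0, 300.0)),
        ("Cycloheximide", ("HSR", "UPR"), (0.2, 2.0, 20.0)),
        ("Troglitazone", ("HSR", "UPR"), (0.001, 0.01, 0.1)),
    ]
    fractions = (0.05, 0.2, 0.5)  # responsive fraction rises with dose
    treatments = [
        TreatmentSpec(
            chemical=chem,
            conc=conc,
            target_srps=srps,
            l2fc=2.0,
            responsive_fraction=f,
            n_cells=cells_per_condition,
        )
        for chem, srps, concs in design
        for conc, f in zip(concs, fractions)
    ]
    return SimConfig(
        n_genes=n_genes,
        n_control_cells=control_pool_factor * cells_per_condition,
        treatments=treatments,
        signatures=lib,
        seed=seed,
    )


def simulate_archetype_scores(
    n_cells: int = 5000,
    seed: int = 0,
    active_level: float = 3.0,
    noise_sd: float = 1.0,
    archetypes: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cells drawn from phenotype archetypes directly in 8-D SRP score space.

    Each cell picks an archetype uniformly; its targeted SRPs sit at
    ``active_level`` (in standardized-score units) and the rest at 0, plus
    isotropic Gaussian noise.  Returns (scores, true archetype labels).
    """
    if archetypes is None:
        archetypes = PHENOTYPE_ARCHETYPES
    rng = np.random.default_rng(seed)
    names = sorted(archetypes)
    labels = rng.choice(len(names), size=n_cells)
    centers = np.zeros((len(names), len(SRP_LABELS)))
    for i, name in enumerate(names):
        for srp in archetypes[name]:
            centers[i, SRP_LABELS.index(srp)] = active_level
    scores = centers[labels] + rng.normal(0.0, noise_sd, (n_cells, len(SRP_LABELS)))
    idx = pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell_id")
    return (
        pd.DataFrame(scores, index=idx, columns=list(SRP_LABELS)),
        pd.Series([names[l] for l in labels], index=idx, name="archetype"),
    )


def make_cooccurrence_table(
    n_terms: int = 3,
    planted_per_term: int = 10,
    n_background_genes: int = 50,
    N: int = 100_000,
    seed: int = 0,
) -> tuple[CooccurrenceTable, dict[str, list[str]]]:
    """Fabricate a gene-term co-occurrence table with planted associations.

    Planted genes co-occur with their term far above independence (high
    nPMI); background genes co-occur at the independence rate (nPMI ~ 0).
    Returns the table and the planted gene lists per term.
    """
    rng = np.random.default_rng(seed)
    rows = []
    planted: dict[str, list[str]] = {}
    gene_counter = 0
    for ti in range(n_terms):
        term = f"TERM{ti}"
        n_t = int(rng.integers(2000, 5000))
        planted[term] = []
        for _ in range(planted_per_term):
            g = f"PG{gene_counter:04d}"
            gene_counter += 1
            n_g = int(rng.integers(500, 2000))
            # strong association: half the gene's mentions co-occur with term
            n_gt = max(1, n_g // 2)
            rows.append((g, term, n_g, n_t, min(n_gt, n_t)))
            planted[term].append(g)
        for bi in range(n_background_genes):
            g = f"BG{bi:04d}"
            n_g = int(rng.integers(500, 2000))
            n_gt = max(0, round(n_g * n_t / N))  # independence rate
            rows.append((g, term, n_g, n_t, n_gt))
    table = pd.DataFrame(
        rows, columns=["gene", "term", "n_gene", "n_term", "n_pair"]
    )
    return CooccurrenceTable(N, table), planted


def write_simulation(
    outdir: str | Path, cm: CountMatrix, truth: GroundTruth, config: SimConfig
) -> None:
    """Persist a simulated experiment: MTX + companions, ground truth JSON,
    signatures GMT, and the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm.write_mtx(outdir)
    truth.to_json(outdir / "ground_truth.json")
    if config.signatures is not None:
        config.signatures.write_gmt(outdir / "signatures.gmt")
    cfg = asdict(config)
    cfg.pop("signatures")
    Path(outdir / "sim_config.json").write_text(json.dumps(cfg, indent=2))
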