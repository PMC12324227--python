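"""Stress-pathway gene signatures mined from literature co-occurrence.

Gene–pathway associations are quantified with normalised pointwise mutual
information (nPMI) computed from a gene × term document co-occurrence table
(abstract counts).  With ``p_gt = n_gt/N``, ``p_g = n_g/N``, ``p_t = n_t/N``::

    nPMI = ln(p_gt / (p_g * p_t)) / (-ln p_gt)

nPMI lies in [-1, 1]: 1 for perfect co-occurrence (the gene and term only
ever appear together), 0 for independence, and -1 as the never-co-occur
limit.  Signatures keep genes with nPMI above a threshold (default 0.2),
ranked by co-occurrence count then nPMI, truncated to a ladder of sizes
(default 50/100/150/200) in which each smaller signature is a prefix of the
next larger one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SIZES = (50, 100, 150, 200)


class SignatureError(ValueError):
    pass


def npmi(n_gt: int, n_g: int, n_t: int, N: int) -> float:
    """Normalised pointwise mutual information of one gene–term pair.

    Parameters are document counts: ``n_gt`` abstracts mentioning both,
    ``n_g`` / ``n_t`` mentioning the gene / term, ``N`` total.  Returns -1
    when the pair never co-occurs and NaN (undefined) when the pair occurs
    in every document.
    """
    if not (0 <= n_gt <= min(n_g, n_t) <= N) or N <= 0:
        raise SignatureError(
            f"invalid counts n_gt={n_gt}, n_g={n_g}, n_t={n_t}, N={N}"
        )
    if n_gt == 0:
        return -1.0
    if n_gt == N:
        return float("nan")
    p_gt = n_gt / N
    p_g = n_g / N
    p_t = n_t / N
    return math.log(p_gt / (p_g * p_t)) / (-math.log(p_gt))


@dataclass
class CooccurrenceTable:
    """Gene × term document co-occurrence counts.

    ``table`` has columns gene, term, n_gene, n_term, n_pair; ``N`` is the
    total document count shared by all rows.
    """

    N: int
    table: pd.DataFrame

    REQUIRED = ("gene", "term", "n_gene", "n_term", "n_pair")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SignatureError(f"co-occurrence table missing columns {missing}")
        t = self.table
        bad = (
            (t.n_pair < 0)
            | (t.n_pair > t.n_gene)
            | (t.n_pair > t.n_term)
            | (t.n_gene > self.N)
            | (t.n_term > self.N)
        )
        if bad.any():
            raise SignatureError(
                f"{int(bad.sum())} rows violate 0 <= n_pair <= min(n_gene, "
                f"n_term) <= N"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CooccurrenceTable":
        df = pd.read_csv(path)
        if "N" not in df.columns:
            raise SignatureError("CSV must carry an N column (total documents)")
        n_values = df["N"].unique()
        if len(n_values) != 1:
            raise SignatureError("N must be constant across rows")
        return cls(int(n_values[0]), df.drop(columns="N"))

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["N"] = self.N
        out.to_csv(path, index=False)

    def scored(self) -> pd.DataFrame:
        """Table with an npmi column appended."""
        out = self.table.copy()
        out["npmi"] = [
            npmi(r.n_pair, r.n_gene, r.n_term, self.N)
            for r in out.itertuples(index=False)
        ]
        return out


@dataclass
class SignatureLibrary:
    """Named gene sets at a ladder of sizes, with optional weights.

    ``genes`` maps a signature name to its full ranked gene list (the
    largest size); ``sizes`` is the ladder, each size a prefix of the list.
    ``weights`` holds per-gene signs/weights (default +1, i.e. unsigned
    upregulation signatures); ``provenance`` optionally carries the nPMI
    score and co-occurrence count each retained gene was ranked by.
    """

    genes: dict[str, list[str]]
    sizes: tuple[int, ...] = DEFAULT_SIZES
    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    provenance: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sizes = tuple(sorted(self.sizes))
        for name, gs in self.genes.items():
            if len(set(gs)) != len(gs):
                raise SignatureError(f"duplicate genes in signature {name}")

    @property
    def names(self) -> list[str]:
        return sorted(self.genes)

    def at_size(self, name: str, size: int) -> list[str]:
        """The signature truncated to ``size`` genes (prefix of the ranking)."""
        return self.genes[name][:size]

    def weight(self, name: str, gene: str) -> float:
        return self.weights.get(name, {}).get(gene, 1.0)

    def all_genes(self) -> set[str]:
        return set().union(*self.genes.values()) if self.genes else set()

    # -- GMT I/O -------------------------------------------------------

    def write_gmt(self, path: str | Path) -> None:
        """Write standard GMT; weighted genes encoded as ``gene|weight``."""
        with open(path, "w") as fh:
            for name in self.names:
                fields = [name, f"sizes={','.join(map(str, self.sizes))}"]
                w = self.weights.get(name, {})
                for g in self.genes[name]:
                    fields.append(f"{g}|{w[g]:g}" if g in w else g)
                fh.write("\t".join(fields) + "\n")

    @classmethod
    def read_gmt(
        cls, path: str | Path, sizes: tuple[int, ...] = DEFAULT_SIZES
    ) -> "SignatureLibrary":
        genes: dict[str, list[str]] = {}
        weights: dict[str, dict[str, float]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise SignatureError(
                        f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                        f"fields, got {len(parts)}"
                    )
                name, desc, members = parts[0], parts[1], parts[2:]
                if desc.startswith("sizes="):
                    sizes = tuple(int(s) for s in desc[6:].split(","))
                glist, w = [], {}
                for m in members:
                    if "|" in m:
                        g, wt = m.split("|", 1)
                        try:
                            w[g] = float(wt)
                        except ValueError as exc:
                            raise SignatureError(
                                f"{path}:{lineno}: bad weight {wt!r}"
                            ) from exc
                        glist.append(g)
                    else:
                        glist.append(m)
                genes[name] = glist
                if w:
                    weights[name] = w
        lib = cls(genes, sizes)
        lib.weights = weights
        return lib


def build_signatures(
    table: CooccurrenceTable,
    threshold: float = 0.2,
    sizes: tuple[int, ...] = DEFAULT_SIZES,
    rank_by_npmi_first: bool = False,
) -> SignatureLibrary:
    """Build a signature library from a co-occurrence table.

    Per term, genes with nPMI > ``threshold`` are ranked by co-occurrence
    count then nPMI (both descending; swap the order with
    ``rank_by_npmi_first``), ties broken by gene id ascending, and truncated
    to the largest requested size.  A term with fewer eligible genes than
    the smallest size is kept at its available length with a warning.
    """
    sizes = tuple(sorted(sizes))
    scored = table.scored()
    keys = (
        ["npmi", "n_pair", "gene"] if rank_by_npmi_first else ["n_pair", "npmi", "gene"]
    )
    genes: dict[str, list[str]] = {}
    provenance: dict[str, pd.DataFrame] = {}
    for term, sub in scored.groupby("term", sort=True):
        eligible = sub[sub.npmi > threshold].sort_values(
            keys, ascending=[False, False, True], kind="stable"
        )
        ranked = eligible.head(max(sizes))
        if len(ranked) < min(sizes):
            logger.warning(
                "term %s has only %d genes above nPMI %g (smallest signature "
                "size is %d)",
                term,
                len(ranked),
                threshold,
                min(sizes),
            )
        genes[term] = ranked.gene.tolist()
        provenance[term] = ranked[["gene", "n_pair", "npmi"]].reset_index(drop=True)
    lib = SignatureLibrary(genes, sizes)
    lib.provenance = provenance
    return lib
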