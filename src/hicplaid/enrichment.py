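"""Over-representation of switched-compartment genes in pathway gene sets.

For each pathway the upper-tail hypergeometric probability of observing at
least the seen overlap between the gene list and the pathway, given the
background universe, is computed (the one-sided Fisher exact test).  Raw
p-values with a 0.05 significance rule are reported by default;
Benjamini-Hochberg correction is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["PathwayCollection", "load_gmt", "write_gmt", "hypergeom_enrich"]


@dataclass
class PathwayCollection:
    """Named gene sets (GMT semantics): pathway -> member gene ids."""

    pathways: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)


def load_gmt(path) -> PathwayCollection:
    """Parse a GMT file (name <tab> description <tab> members...).

    Duplicate members within a line are deduplicated; a line with fewer than
    three fields is a parse error reported with its line number.
    """
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            name, desc, *members = fields
            pathways[name] = {m for m in members if m}
            descriptions[name] = desc
    return PathwayCollection(pathways, descriptions)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.pathways.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def hypergeom_enrich(
    scgs: set[str],
    pathways: PathwayCollection,
    universe: set[str],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation test per pathway.

    With N = |universe|, K = |pathway ∩ universe|, n = |gene list ∩ universe|
    and k their overlap, the p-value is P(X >= k) for X hypergeometric
    (N, K, n).  Pathways empty after intersection with the universe are
    dropped with a warning; list genes outside the universe are dropped with
    a warning.  Rows sorted ascending by p; the significance flag applies
    ``alpha`` to the raw p (or to the BH-adjusted p when ``bh_correct``).
    """
    if not universe:
        raise ValueError("empty background universe")
    extra = scgs - universe
    if extra:
        warnings.warn(f"{len(extra)} query gene(s) outside the universe dropped")
    query = scgs & universe
    if not query:
        raise ValueError("empty gene list after intersection with universe")

    n_univ = len(universe)
    n_query = len(query)
    rows = []
    for name, members in pathways.pathways.items():
        in_univ = members & universe
        if not in_univ:
            warnings.warn(f"pathway {name!r} empty after universe intersection; dropped")
            continue
        k = len(query & in_univ)
        p = float(hypergeom.sf(k - 1, n_univ, len(in_univ), n_query))
        rows.append(
            {
                "term": name,
                "count": k,
                "pathway_size": len(in_univ),
                "universe_size": n_univ,
                "list_size": n_query,
                "enriched_genes": ",".join(sorted(query & in_univ)),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if bh_correct:
        _, adj, _, _ = multipletests(out["p_value"], method="fdr_bh")
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
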