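"""Taxon-taxon co-occurrence network and strong-node (hub) detection.

Edges connect genus pairs whose abundance profiles correlate with
|rho| >= rho_min at BH q < alpha (one correction family over all taxon
pairs, bacteria and fungi together).  "Strong nodal" taxa — the
Co-occurring group — are those in the upper quantile of weighted degree
(strength = sum of |rho| over incident edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import AbundanceTable, DataValidationError


@dataclass
class CooccurrenceNetwork:
    """Undirected signed correlation network over taxa."""

    graph: nx.Graph  # nodes carry kingdom; edges carry rho, q, sign

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            (a, b, d["rho"], d["q"], d["sign"]) for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "q", "sign"])

    @property
    def strengths(self) -> pd.Series:
        s = {t: 0.0 for t in self.graph.nodes}
        for a, b, d in self.graph.edges(data=True):
            s[a] += abs(d["rho"])
            s[b] += abs(d["rho"])
        return pd.Series(s, name="strength")

    def write_edges(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    abund: AbundanceTable,
    method: str = "spearman",
    rho_min: float = 0.6,
    alpha: float = 0.05,
    taxa: list[str] | set[str] | None = None,
) -> CooccurrenceNetwork:
    """All-pairs taxon correlation network with BH-controlled edges.

    ``taxa`` optionally restricts the network (typically to the Major
    group).  Degenerate (constant) taxa never gain edges.
    """
    if method not in ("spearman", "pearson"):
        raise DataValidationError(f"unknown correlation method {method!r}")
    table = abund if taxa is None else _subset(abund, taxa)
    names = table.taxa
    if len(names) < 2:
        raise DataValidationError("need >= 2 taxa to build a co-occurrence network")
    if len(table.samples) < 4:
        raise DataValidationError("need >= 4 samples to build a co-occurrence network")
    x = table.data.to_numpy()

    pairs, rhos, ps = [], [], []
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.ptp(x[i]) == 0 or np.ptp(x[j]) == 0:
                continue
            res = corr(x[i], x[j])
            rho, p = float(res.statistic), float(res.pvalue)
            if not np.isfinite(rho):
                continue
            pairs.append((names[i], names[j]))
            rhos.append(rho)
            ps.append(p)

    g = nx.Graph()
    for t in names:
        g.add_node(t, kingdom=str(table.kingdom[t]))
    if pairs:
        q = multipletests(ps, method="fdr_bh")[1]
        for (a, b), rho, qv in zip(pairs, rhos, q):
            if abs(rho) >= rho_min and qv < alpha:
                g.add_edge(a, b, rho=rho, q=float(qv), sign=1 if rho > 0 else -1)
    return CooccurrenceNetwork(g)


def _subset(abund: AbundanceTable, taxa) -> AbundanceTable:
    keep = [t for t in abund.taxa if t in set(taxa)]
    return AbundanceTable(abund.data.loc[keep].copy(), abund.kingdom.loc[keep].copy())


def hub_taxa(net: CooccurrenceNetwork, quantile: float = 0.8) -> set[str]:
    """Strong-node taxa: strength at or above the given quantile of the
    positive-strength distribution.  Isolated nodes never qualify; ties at
    the cutoff are all included."""
    if not (0.0 <= quantile <= 1.0):
        raise DataValidationError("quantile must be in [0, 1]")
    s = net.strengths
    if len(s) == 0:
        raise DataValidationError("empty network")
    positive = s[s > 0]
    if positive.empty:
        warnings.warn("all nodes isolated; hub set is empty", stacklevel=2)
        return set()
    # quantile over the distinct strength values: a star center (one high
    # value against many tied leaves) must qualify alone at quantile 0.8
    cutoff = float(np.quantile(np.unique(positive.to_numpy()), quantile))
    return set(positive[positive >= cutoff].index)
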