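"""High-stringency co-expression network over the 30-sample design.

Nodes are DE transcripts of any biotype; an undirected edge joins two
transcripts whose pairwise Pearson correlation across samples is strictly
above the threshold in magnitude (default |R| > 0.97; R = 0.97 exactly is
no edge).  Connected components of this graph are the candidate coordinated
programs — the largest upregulated one is the muscle 'degradome' — and hubs
are ranked by degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ValidationError

R_NETWORK = 0.97


def edge_passes(r: float, r_threshold: float = R_NETWORK) -> bool:
    """Strict threshold on the correlation magnitude: |R| must exceed it."""
    return r > r_threshold or r < -r_threshold


def scale_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Equalize column totals to the mean library (per-sample scaling).

    Each column is multiplied by one constant, so within-column structure —
    and hence Pearson correlations between rows after this step — reflects
    depth-corrected expression.
    """
    totals = matrix.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = [matrix.columns[i] for i in np.flatnonzero(totals == 0)]
        raise ValidationError(f"all-zero sample column(s): {bad}")
    return matrix * (totals.mean() / totals)


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    r_threshold: float
    biotypes: Mapping[str, str] = field(default_factory=dict)
    directions: Mapping[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["r"]) for u, v, d in self.graph.edges(data=True)]


def build_network(
    matrix: pd.DataFrame,
    r_threshold: float = R_NETWORK,
    biotypes: Mapping[str, str] | None = None,
    directions: Mapping[str, str] | None = None,
    log2: bool = False,
) -> CorrelationNetwork:
    """Correlation network over the rows of a normalized expression matrix.

    Pairwise Pearson R over samples; an edge is added iff R > threshold or
    R < -threshold.  Constant rows have no defined correlation and are
    excluded with a warning.  ``log2`` applies log2(x+1) first (off by
    default; plain scaled values otherwise).
    """
    if matrix.shape[1] < 3:
        raise ValidationError("need at least 3 samples for correlations")
    if not 0 < r_threshold < 1:
        raise ValidationError("r_threshold must be in (0, 1)")
    x = matrix.to_numpy(dtype=float)
    if log2:
        x = np.log2(x + 1.0)
    sds = x.std(axis=1)
    keep = sds > 0
    if (~keep).any():
        warnings.warn(f"excluding {int((~keep).sum())} constant row(s) from the network")
    ids = matrix.index[keep].to_list()
    corr = np.atleast_2d(np.corrcoef(x[keep]))
    g = nx.Graph()
    g.add_nodes_from(ids)
    iu, ju = np.triu_indices(len(ids), k=1)
    hit = np.flatnonzero((corr[iu, ju] > r_threshold) | (corr[iu, ju] < -r_threshold))
    for k in hit:
        r = float(corr[iu[k], ju[k]])
        g.add_edge(ids[iu[k]], ids[ju[k]], r=r, sign="+" if r > 0 else "-")
    return CorrelationNetwork(g, r_threshold, dict(biotypes or {}), dict(directions or {}))


def connected_components(network: CorrelationNetwork) -> list[dict]:
    """Size-ordered components of the non-isolated nodes, with biotype tallies.

    Isolated nodes are not components: an edgeless graph has zero
    components, matching the convention that only connected transcripts are
    displayed.
    """
    comps = []
    for nodes in nx.connected_components(network.graph):
        if len(nodes) < 2:
            continue
        tally: dict[str, int] = {}
        for n in nodes:
            bt = network.biotypes.get(n, "unknown")
            tally[bt] = tally.get(bt, 0) + 1
        comps.append(dict(size=len(nodes), members=sorted(nodes), biotype_counts=tally))
    comps.sort(key=lambda c: (-c["size"], c["members"]))
    return comps


def hub_scores(network: CorrelationNetwork) -> list[tuple[str, int]]:
    """Nodes ranked by degree, descending; ties broken by id (stable)."""
    deg = dict(network.graph.degree())
    return sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))


def betweenness_hubs(network: CorrelationNetwork) -> list[tuple[str, float]]:
    """Alternative hub ranking by betweenness centrality."""
    bc = nx.betweenness_centrality(network.graph)
    return sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# Export


def export_graph(network: CorrelationNetwork, path: str | Path, fmt: str = "sif") -> None:
    """Write the network as SIF ('coexp' interaction lines) or GraphML."""
    path = Path(path)
    if fmt == "sif":
        lines = [f"{u}\tcoexp\t{v}" for u, v, _ in sorted(network.edges)]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        g = network.graph.copy()
        for n in g.nodes:
            g.nodes[n]["biotype"] = network.biotypes.get(n, "unknown")
            g.nodes[n]["direction"] = network.directions.get(n, "unknown")
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown export format {fmt!r}")


def read_sif(path: str | Path) -> set[tuple[str, str]]:
    """Edge set from a SIF file (unordered pairs)."""
    edges = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        u, _rel, v = line.split("\t")
        edges.add(tuple(sorted((u, v))))
    return edges


def analytic_null_edge_probability(n_samples: int, r_threshold: float = R_NETWORK) -> float:
    """P(|R| > threshold) for the Pearson R of two independent normal rows.

    Uses the exact t-transform of the null correlation with n-2 degrees of
    freedom: R = t / sqrt(t^2 + n - 2).
    """
    from scipy import stats

    df = n_samples - 2
    t = r_threshold * np.sqrt(df / (1.0 - r_threshold**2))
    return float(2.0 * stats.t.sf(t, df))


__all__ = [
    "CorrelationNetwork",
    "R_NETWORK",
    "analytic_null_edge_probability",
    "betweenness_hubs",
    "build_network",
    "connected_components",
    "edge_passes",
    "export_graph",
    "hub_scores",
    "read_sif",
    "scale_normalize",
]
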