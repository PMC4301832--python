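"""Disease network from selected triads and its centrality measures.

Every selected triad contributes its three disease pairs to an undirected
simple graph (pairs deduplicated across triads, each edge remembering its
supporting triads). Two degree-centrality conventions are reported:

* ``degree_centrality_pct`` — node degree divided by the network's degree sum
  (2×|edges|), as a percentage; these shares sum to 100 across nodes. This is
  the convention of the published centrality table.
* ``degree_centrality_classic`` — degree/(n−1), the textbook normalization.

Betweenness likewise comes in two conventions: ``betweenness_norm_pct`` is
shortest-path betweenness normalized by (n−1)(n−2)/2 (×100), and
``betweenness_pct`` is the node's share of the summed raw betweenness (×100),
which is the convention the published table and its "average node
betweenness" (= 100/n) follow.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def extract_edgelist(
    triples,
    prevalence: pd.Series | None = None,
) -> nx.Graph:
    """Build the disease network from an iterable of 3-tuples of group ids."""
    triples = [tuple(sorted(t)) for t in triples]
    if not triples:
        raise ValueError("no selected triads — cannot build a network")
    G = nx.Graph()
    for t in triples:
        a, b, c = t
        if len({a, b, c}) != 3:
            raise ValueError(f"triad {t} has repeated members")
        for u, v in ((a, b), (a, c), (b, c)):
            if G.has_edge(u, v):
                G[u][v]["triads"].append(t)
            else:
                G.add_edge(u, v, triads=[t])
    if prevalence is not None:
        for node in G.nodes:
            if node in prevalence.index:
                G.nodes[node]["prevalence"] = float(prevalence[node])
    return G


def degree_metrics(G: nx.Graph) -> pd.DataFrame:
    """Per-node edge counts and both degree-centrality conventions."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    degsum = 2 * G.number_of_edges()
    n = G.number_of_nodes()
    rows = {
        node: {
            "degree": d,
            "degree_centrality_pct": 100.0 * d / degsum,
            "degree_centrality_classic": d / (n - 1) if n > 1 else 0.0,
        }
        for node, d in G.degree()
    }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def betweenness_metrics(G: nx.Graph) -> pd.DataFrame:
    """Shortest-path betweenness per node, in both conventions.

    ``betweenness_norm_pct``: raw betweenness / ((n−1)(n−2)/2) × 100 (pairs in
    different components contribute 0). ``betweenness_pct``: share of the
    summed raw betweenness × 100. Network-level means of both columns are in
    ``.attrs`` (the share-convention mean is identically 100/n).
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    raw = nx.betweenness_centrality(G, normalized=False)
    n = G.number_of_nodes()
    denom = (n - 1) * (n - 2) / 2
    total = sum(raw.values())
    df = pd.DataFrame.from_dict(
        {
            node: {
                "betweenness_raw": v,
                "betweenness_norm_pct": 100.0 * v / denom if denom else 0.0,
                "betweenness_pct": 100.0 * v / total if total else 0.0,
            }
            for node, v in raw.items()
        },
        orient="index",
    ).sort_index()
    df.attrs["average_betweenness_norm_pct"] = float(df["betweenness_norm_pct"].mean())
    df.attrs["average_betweenness_pct"] = float(df["betweenness_pct"].mean())
    return df


def network_metrics(G: nx.Graph) -> pd.DataFrame:
    """Combined per-node metric table (degree + betweenness + annotations)."""
    df = degree_metrics(G).join(betweenness_metrics(G))
    for attr in ("prevalence", "cluster"):
        vals = nx.get_node_attributes(G, attr)
        if vals:
            df[attr] = pd.Series(vals)
    df.attrs["n_nodes"] = G.number_of_nodes()
    df.attrs["n_edges"] = G.number_of_edges()
    df.attrs["degree_sum"] = 2 * G.number_of_edges()
    df.attrs["average_betweenness_pct"] = float(df["betweenness_pct"].mean())
    df.attrs["average_betweenness_norm_pct"] = float(df["betweenness_norm_pct"].mean())
    return df


def _classical_mds(D: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Torgerson double-centering MDS of a distance matrix into 2D."""
    n = D.shape[0]
    if n == 1:
        return np.zeros((1, 2))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = B + rng.normal(scale=1e-9, size=B.shape)  # break exact eigenvalue ties
    B = (B + B.T) / 2
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:2]
    coords = v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
    if coords.shape[1] < 2:
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    return coords


def layout_mds(G: nx.Graph, seed: int = 0) -> dict:
    """Classical MDS on all-pairs shortest-path distances; components laid out
    separately and offset horizontally."""
    rng = np.random.default_rng(seed)
    pos: dict = {}
    x_offset = 0.0
    for comp in sorted(nx.connected_components(G), key=len, reverse=True):
        nodes = sorted(comp)
        sub = G.subgraph(nodes)
        D = np.zeros((len(nodes), len(nodes)))
        sp = dict(nx.all_pairs_shortest_path_length(sub))
        for i, u in enumerate(nodes):
            for j, v in enumerate(nodes):
                D[i, j] = sp[u][v]
        coords = _classical_mds(D, rng)
        coords[:, 0] += x_offset - coords[:, 0].min()
        x_offset = coords[:, 0].max() + 2.0
        pos.update({node: tuple(coords[i]) for i, node in enumerate(nodes)})
    return pos


def annotate_clusters(G: nx.Graph, assignments: dict[str, frozenset[str]]) -> nx.Graph:
    """Label each node with its cluster set ('none' if unassigned, 'both' if two)."""
    for node in G.nodes:
        clusters = assignments.get(node)
        if clusters is None:
            logger.warning("node %s missing from cluster assignments; labelled 'none'", node)
            G.nodes[node]["cluster"] = "none"
        elif not clusters:
            G.nodes[node]["cluster"] = "none"
        elif len(clusters) == 1:
            G.nodes[node]["cluster"] = next(iter(clusters))
        else:
            G.nodes[node]["cluster"] = "both"
    return G


def plot_network(G: nx.Graph, pos: dict | None = None, path=None, seed: int = 0):
    """Cluster-coloured network plot; node area scales with prevalence."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = pos or layout_mds(G, seed=seed)
    clusters = [G.nodes[n].get("cluster", "none") for n in G.nodes]
    palette = {}
    colors = []
    cycle = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for c in clusters:
        palette.setdefault(c, cycle[len(palette) % len(cycle)])
        colors.append(palette[c])
    prev = np.array([G.nodes[n].get("prevalence", 0.1) for n in G.nodes])
    sizes = 3000 * prev / max(prev.max(), 1e-9)
    fig, ax = plt.subplots(figsize=(9, 7))
    nx.draw_networkx_edges(G, pos, ax=ax, alpha=0.4)
    nx.draw_networkx_nodes(G, pos, ax=ax, node_color=colors, node_size=sizes, alpha=0.85)
    nx.draw_networkx_labels(G, pos, ax=ax, font_size=6)
    handles = [plt.Line2D([], [], marker="o", ls="", color=col, label=lab)
               for lab, col in palette.items()]
    ax.legend(handles=handles, loc="best", fontsize=8)
    ax.set_axis_off()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
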