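"""Spatial neighbor graphs and permutation-based interaction scoring.

Per ROI, a neighbor graph is built on cell centroids either by **expansion**
(undirected edge iff Euclidean distance strictly below a radius, default
20 um) or **k-nearest neighbors** (directed out-edges to the k = 10 nearest
cells; distance ties broken by lower cell id).  The "classic" interaction
statistic for an ordered pair (from, to) is the mean number of to-type
neighbors per from-type cell.

Significance is assessed by permuting all cell labels within the ROI with
the graph fixed (n = 1000 by default).  With the plus-one convention,
p_enrich = (1 + #{perm >= obs}) / (n_perm + 1) and symmetrically for
p_avoid; a pair scores sigval +1 when p_enrich < alpha (default 0.01),
-1 when p_avoid < alpha, 0 otherwise.  Scores are averaged in two stages —
ROIs to sample, samples to group — with missing entries excluded at both
stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

@dataclass
class NeighborGraph:
    """Edge list over cells of one ROI.

    ``edges`` holds row positions into the originating cell table slice.
    Expansion graphs store each unordered pair once and are interpreted
    symmetrically; knn graphs are directed (out-edges).
    """

    roi_id: str
    method: str                      # "expansion" | "knn"
    parameter: float                 # radius (um) or k
    n_cells: int
    edges: np.ndarray                # (E, 2) int
    directed: bool
    cell_ids: np.ndarray = field(default_factory=lambda: np.empty(0, object))

    def out_neighbor_pairs(self) -> np.ndarray:
        """(source, target) pairs with symmetric duplication for
        undirected graphs; shape (E', 2)."""
        if len(self.edges) == 0:
            return np.empty((0, 2), dtype=int)
        if self.directed:
            return self.edges
        return np.concatenate([self.edges, self.edges[:, ::-1]])


def build_graph(cells: pd.DataFrame, method: str = "expansion",
                radius_um: float = 20.0, k: int = 10) -> NeighborGraph:
    """Build the neighbor graph for the cells of one ROI."""
    n = len(cells)
    if n < 2:
        raise DataError("graph building needs >= 2 cells")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    ids = cells["cell_id"].to_numpy() if "cell_id" in cells.columns \
        else np.arange(n)
    roi_id = str(cells["roi_id"].iloc[0]) if "roi_id" in cells.columns else ""
    if method == "expansion":
        if radius_um <= 0:
            raise ConfigurationError("expansion radius must be > 0")
        tree = cKDTree(xy)
        pairs = tree.query_pairs(r=radius_um, output_type="ndarray")
        if len(pairs):
            d = np.sqrt(((xy[pairs[:, 0]] - xy[pairs[:, 1]]) ** 2).sum(axis=1))
            pairs = pairs[d < radius_um]          # strict inequality
        return NeighborGraph(roi_id=roi_id, method="expansion",
                             parameter=float(radius_um), n_cells=n,
                             edges=np.asarray(pairs, dtype=int).reshape(-1, 2),
                             directed=False, cell_ids=ids)
    if method == "knn":
        if k <= 0:
            raise ConfigurationError("k must be > 0")
        if k >= n:
            log.warning("knn: k=%d >= n=%d cells; truncating to %d", k, n, n - 1)
            k = n - 1
        # ties broken by lower cell id: order candidates by (distance, id)
        id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
        if n <= 4096:
            d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
            np.fill_diagonal(d, np.inf)
            order = np.lexsort((id_rank[None, :].repeat(n, axis=0), d), axis=1)
            nbrs = order[:, :k]
        else:
            tree = cKDTree(xy)
            dist, idx = tree.query(xy, k=k + 1)
            nbrs = np.empty((n, k), dtype=int)
            for i in range(n):
                cand = [(dist[i, j], id_rank[idx[i, j]], idx[i, j])
                        for j in range(k + 1) if idx[i, j] != i]
                cand.sort()
                nbrs[i] = [c[2] for c in cand[:k]]
        src = np.repeat(np.arange(n), k)
        edges = np.stack([src, nbrs.ravel()], axis=1)
        return NeighborGraph(roi_id=roi_id, method="knn", parameter=float(k),
                             n_cells=n, edges=edges, directed=True,
                             cell_ids=ids)
    raise ConfigurationError(f"unknown graph method {method!r}")


# ---------------------------------------------------------------------------
# interaction statistic
# ---------------------------------------------------------------------------

def _count_matrix(pairs: np.ndarray, codes: np.ndarray, n_types: int) -> np.ndarray:
    """C[a, b] = number of (source label a, target label b) neighbor pairs."""
    if len(pairs) == 0:
        return np.zeros((n_types, n_types), dtype=np.int64)
    flat = codes[pairs[:, 0]] * n_types + codes[pairs[:, 1]]
    return np.bincount(flat, minlength=n_types * n_types).reshape(n_types,
                                                                  n_types)


def interaction_statistic(graph: NeighborGraph, labels: Sequence,
                          from_type, to_type) -> float:
    """Mean number of to-type neighbors per from-type cell.

    Returns NaN (missing) when the ROI has no from-type cells; 0.0 when it
    has from-type cells but no qualifying neighbors.
    """
    labels = np.asarray(labels)
    if len(labels) != graph.n_cells:
        raise DataError("labels must cover all graph nodes")
    n_from = int((labels == from_type).sum())
    if n_from == 0:
        return float("nan")
    pairs = graph.out_neighbor_pairs()
    if len(pairs) == 0:
        return 0.0
    hits = (labels[pairs[:, 0]] == from_type) & (labels[pairs[:, 1]] == to_type)
    return float(hits.sum() / n_from)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_test(graph: NeighborGraph, labels: Sequence,
                     n_perm: int = 1000, alpha: float = 0.01, seed: int = 0,
                     types: Sequence | None = None,
                     chunk: int = 250) -> pd.DataFrame:
    """Label-permutation interaction test for all ordered type pairs.

    Returns one row per ordered (from, to) pair with the observed
    statistic, p_enrich, p_avoid, sigval in {+1, 0, -1} and a ``missing``
    flag for pairs whose from- or to-type is absent from the ROI.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must be in (0, 1)")
    labels = np.asarray(labels)
    if len(labels) != graph.n_cells:
        raise DataError("labels must cover all graph nodes")
    vocab = list(types) if types is not None else sorted(pd.unique(labels))
    t_index = {t: i for i, t in enumerate(vocab)}
    unknown = set(labels) - set(vocab)
    if unknown:
        raise DataError(f"labels outside the type vocabulary: {sorted(unknown)}")
    T = len(vocab)
    codes = np.fromiter((t_index[l] for l in labels), dtype=np.int64,
                        count=len(labels))
    n_by_type = np.bincount(codes, minlength=T)
    pairs = graph.out_neighbor_pairs()
    obs_counts = _count_matrix(pairs, codes, T)

    rng = np.random.default_rng(seed)
    ge = np.zeros((T, T), dtype=np.int64)   # perm count >= observed
    le = np.zeros((T, T), dtype=np.int64)
    src, dst = pairs[:, 0], pairs[:, 1]
    done = 0
    while done < n_perm:
        p = min(chunk, n_perm - done)
        perm = np.tile(codes, (p, 1))
        perm = rng.permuted(perm, axis=1)
        if len(pairs):
            flat = (perm[:, src] * T + perm[:, dst]
                    + (np.arange(p) * T * T)[:, None])
            counts = np.bincount(flat.ravel(), minlength=p * T * T)
            counts = counts.reshape(p, T, T)
        else:
            counts = np.zeros((p, T, T), dtype=np.int64)
        ge += (counts >= obs_counts[None]).sum(axis=0)
        le += (counts <= obs_counts[None]).sum(axis=0)
        done += p

    p_enrich = (1.0 + ge) / (n_perm + 1.0)
    p_avoid = (1.0 + le) / (n_perm + 1.0)
    rows = []
    for a, ta in enumerate(vocab):
        for b, tb in enumerate(vocab):
            missing = n_by_type[a] == 0 or n_by_type[b] == 0
            if missing:
                rows.append({"roi_id": graph.roi_id, "from_type": ta,
                             "to_type": tb, "observed": np.nan,
                             "p_enrich": np.nan, "p_avoid": np.nan,
                             "sigval": np.nan, "n_perm": n_perm,
                             "missing": True})
                continue
            pe, pa = p_enrich[a, b], p_avoid[a, b]
            if pe < alpha and pa < alpha:
                if pe == pa:
                    log.warning("pair (%s, %s): enrichment and avoidance "
                                "p tied below alpha; sigval 0", ta, tb)
                    sig = 0
                else:
                    sig = 1 if pe < pa else -1
            elif pe < alpha:
                sig = 1
            elif pa < alpha:
                sig = -1
            else:
                sig = 0
            rows.append({"roi_id": graph.roi_id, "from_type": ta,
                         "to_type": tb,
                         "observed": obs_counts[a, b] / n_by_type[a],
                         "p_enrich": pe, "p_avoid": pa, "sigval": float(sig),
                         "n_perm": n_perm, "missing": False})
    return pd.DataFrame(rows)


def score_rois(cells: pd.DataFrame, label_col: str = "phenotype",
              method: str = "expansion", radius_um: float = 20.0, k: int = 10,
              n_perm: int = 1000, alpha: float = 0.01, seed: int = 0,
              types: Sequence | None = None) -> pd.DataFrame:
    """Run the permutation test on every ROI of a cell table."""
    if types is None:
        types = sorted(pd.unique(cells[label_col]))
    results = []
    for i, (roi_id, sub) in enumerate(cells.groupby("roi_id", sort=True)):
        graph = build_graph(sub, method=method, radius_um=radius_um, k=k)
        results.append(permutation_test(
            graph, sub[label_col].to_numpy(), n_perm=n_perm, alpha=alpha,
            seed=np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31),
            types=types))
    return pd.concat(results, ignore_index=True)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class InteractionScoreMatrix:
    """Group-level mean-sigval matrix over ordered (from, to) type pairs."""

    group: str
    scores: pd.DataFrame             # from_type x to_type, values in [-1, 1]
    n_samples: pd.DataFrame          # contributing samples per pair


def aggregate_scores(results: pd.DataFrame,
                     roi_to_sample: Mapping[str, str],
                     sample_to_group: Mapping[str, str]
                     ) -> dict[str, InteractionScoreMatrix]:
    """Two-stage mean of sigvals: ROIs -> sample, samples -> group.

    Missing entries (NaN sigval) are excluded at both stages; a sample with
    all entries missing for a pair does not contribute to that pair.
    """
    df = results.copy()
    unmapped = set(df["roi_id"]) - set(roi_to_sample)
    if unmapped:
        raise DataError(f"ROI(s) not mapped to a sample: {sorted(unmapped)}")
    df["sample_id"] = df["roi_id"].map(roi_to_sample)
    unmapped = set(df["sample_id"]) - set(sample_to_group)
    if unmapped:
        raise DataError(f"sample(s) not mapped to a group: {sorted(unmapped)}")
    df["group"] = df["sample_id"].map(sample_to_group)
    sample_means = (df.groupby(["group", "sample_id", "from_type", "to_type"],
                               observed=True)["sigval"]
                    .mean()                      # NaNs excluded per pandas
                    .reset_index())
    out: dict[str, InteractionScoreMatrix] = {}
    for group, sub in sample_means.groupby("group", observed=True):
        mat = sub.pivot_table(index="from_type", columns="to_type",
                              values="sigval", aggfunc="mean")
        counts = sub.dropna(subset=["sigval"]).pivot_table(
            index="from_type", columns="to_type", values="sample_id",
            aggfunc="nunique").reindex_like(mat).fillna(0).astype(int)
        out[str(group)] = InteractionScoreMatrix(group=str(group), scores=mat,
                                                 n_samples=counts)
    return out


def plot_score_heatmap(matrix: InteractionScoreMatrix, path) -> None:
    """Export a diverging heatmap (-1..+1) of a group score matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    data = matrix.scores.to_numpy(dtype=float)
    im = ax.imshow(data, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(matrix.scores.columns)),
                  matrix.scores.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.scores.index)), matrix.scores.index,
                  fontsize=7)
    ax.set_xlabel("to type")
    ax.set_ylabel("from type")
    ax.set_title(f"mean interaction score — {matrix.group}")
    fig.colorbar(im, ax=ax, label="mean sigval")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
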