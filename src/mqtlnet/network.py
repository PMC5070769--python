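"""Condition-specific metabolite-transcript correlation networks.

Metabolites with a significant time effect (one-way ANOVA,
Benjamini-Hochberg FDR within condition) are correlated against the full
transcript universe over the time axis; an undirected bipartite network
links every pair whose |PCC| reaches a permutation-calibrated threshold
controlling the edge FDR.  Conserved edges and merged networks summarize
agreement across environmental conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import TimecourseDataset

__all__ = [
    "ConditionNetwork",
    "anova_select_metabolites",
    "correlate",
    "permutation_pcc_threshold",
    "build_condition_network",
    "conserved_edges",
    "merge_networks",
    "network_edge_table",
]


@dataclass
class ConditionNetwork:
    """Bipartite metabolite-transcript network for one condition."""

    condition: str
    threshold: float | None
    edges: dict  # (metabolite, transcript) -> signed PCC

    def __post_init__(self) -> None:
        if self.threshold is not None:
            bad = [k for k, v in self.edges.items() if abs(v) < self.threshold]
            if bad:
                raise ValueError(f"edges below threshold: {bad[:3]}")

    def neighbors(self, metabolite: str) -> set:
        return {t for (m, t) in self.edges if m == metabolite}

    def metabolites(self) -> set:
        return {m for m, _ in self.edges}

    def transcripts(self) -> set:
        return {t for _, t in self.edges}


def anova_select_metabolites(
    data: TimecourseDataset, condition: str, fdr: float = 0.05
):
    """Metabolites whose profile changes over time in one condition.

    One-way ANOVA with time point as factor over replicate values, then
    Benjamini-Hochberg correction across metabolites within the
    condition; metabolites with q < ``fdr`` are returned.  Constant
    (zero-variance) metabolites are flagged degenerate and excluded.

    Returns ``(selected ids, per-metabolite table)``.
    """
    sub = data.data[(data.data["condition"] == condition)
                    & (data.data["kind"] == "metabolite")]
    if sub.empty:
        raise KeyError(f"no metabolite data for condition {condition!r}")
    rep_counts = sub.groupby(["feature", "time"])["value"].size()
    if rep_counts.nunique() > 1:
        bad = rep_counts[rep_counts != rep_counts.iloc[0]].index[0][0]
        raise ValueError(f"unbalanced replicates for feature {bad!r}")

    rows = []
    for feature, grp in sub.groupby("feature"):
        groups = [g["value"].to_numpy() for _, g in grp.groupby("time")]
        if len(groups) < 2 or len(groups[0]) < 2:
            raise ValueError("need >= 2 time points and >= 2 replicates")
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            rows.append({"metabolite": feature, "p": np.nan, "degenerate": True})
            continue
        p = float(stats.f_oneway(*groups).pvalue)
        rows.append({"metabolite": feature, "p": p, "degenerate": False})
    table = pd.DataFrame(rows)
    valid = table[~table["degenerate"]].copy()
    if valid.empty:
        table["q"] = np.nan
        return [], table
    valid["q"] = multipletests(valid["p"].to_numpy(), method="fdr_bh")[1]
    table = table.merge(valid[["metabolite", "q"]], on="metabolite", how="left")
    selected = sorted(valid.loc[valid["q"] < fdr, "metabolite"])
    return selected, table


def _pcc_matrix(M: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between two feature x time matrices."""
    def zscore(A):
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (A - mu) / sd
        Z[~np.isfinite(Z)] = np.nan
        return Z

    Zm, Zt = zscore(M), zscore(T)
    n = M.shape[1]
    return (Zm @ Zt.T) / n


def correlate(
    data: TimecourseDataset,
    condition: str,
    metabolites: list,
    mode: str = "replicate_means",
) -> pd.DataFrame:
    """PCC matrix (selected metabolites x all transcripts) for a condition.

    ``mode='replicate_means'`` averages replicates per time point and
    correlates over the time-point axis (n = 23 on the default grid);
    ``mode='all_samples'`` correlates over every (time, replicate) sample.
    Zero-variance features yield missing correlations.
    """
    if not metabolites:
        raise ValueError("selected metabolite list is empty")
    collapse = mode == "replicate_means"
    if mode not in ("replicate_means", "all_samples"):
        raise ValueError(f"unknown mode {mode!r}")
    M = data.feature_matrix(condition, "metabolite", collapse_replicates=collapse)
    T = data.feature_matrix(condition, "transcript", collapse_replicates=collapse)
    M = M.loc[metabolites]
    pcc = _pcc_matrix(M.to_numpy(float), T.to_numpy(float))
    return pd.DataFrame(pcc, index=M.index, columns=T.index)


def permutation_pcc_threshold(
    data: TimecourseDataset,
    condition: str,
    metabolites: list,
    n_perm: int = 300,
    fdr: float = 0.05,
    seed: int = 0,
    mode: str = "replicate_means",
    grid_step: float = 0.01,
):
    """Permutation-calibrated |PCC| cutoff controlling the edge FDR.

    For each permutation the time order of every metabolite profile is
    shuffled independently (transcripts fixed) and all |PCC| values are
    recomputed.  For each candidate threshold t on a ``grid_step`` grid,
    FDR(t) = mean permuted exceedance count / observed exceedance count;
    the smallest t with FDR(t) < ``fdr`` is returned together with the
    null-count table.  Returns ``(threshold or None, table)``; None means
    no threshold achieves the target FDR (no network is built).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    collapse = mode == "replicate_means"
    M = data.feature_matrix(condition, "metabolite",
                            collapse_replicates=collapse).loc[metabolites]
    T = data.feature_matrix(condition, "transcript",
                            collapse_replicates=collapse)
    Mv = M.to_numpy(float)
    Tv = T.to_numpy(float)
    obs = np.abs(_pcc_matrix(Mv, Tv)).ravel()
    obs = obs[np.isfinite(obs)]

    grid = np.round(np.arange(grid_step, 1.0 + grid_step / 2, grid_step), 10)
    observed_counts = np.array([(obs >= t).sum() for t in grid])
    if observed_counts.max() == 0:
        raise ValueError("no observed |PCC| above the smallest threshold")

    null_counts = np.zeros(len(grid))
    n_cols = Mv.shape[1]
    for _ in range(n_perm):
        perm = np.empty_like(Mv)
        for i in range(Mv.shape[0]):
            perm[i] = Mv[i, rng.permutation(n_cols)]
        null = np.abs(_pcc_matrix(perm, Tv)).ravel()
        null = null[np.isfinite(null)]
        null_counts += np.array([(null >= t).sum() for t in grid])
    null_counts /= n_perm

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_t = np.where(observed_counts > 0, null_counts / observed_counts, np.inf)
    table = pd.DataFrame({
        "threshold": grid,
        "observed": observed_counts,
        "null_mean": null_counts,
        "fdr": fdr_t,
    })
    qualifying = np.flatnonzero((fdr_t < fdr) & (observed_counts > 0))
    if qualifying.size == 0:
        return None, table
    return float(grid[qualifying[0]]), table


def build_condition_network(
    pcc: pd.DataFrame, threshold: float | None, condition: str = ""
) -> ConditionNetwork:
    """Edges for every metabolite-transcript pair with |PCC| >= threshold."""
    if threshold is None:
        return ConditionNetwork(condition=condition, threshold=None, edges={})
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    vals = pcc.to_numpy(float)
    hit = np.abs(vals) >= threshold
    hit &= np.isfinite(vals)
    edges = {
        (pcc.index[i], pcc.columns[j]): float(vals[i, j])
        for i, j in zip(*np.nonzero(hit))
    }
    return ConditionNetwork(condition=condition, threshold=threshold, edges=edges)


def conserved_edges(networks: list, min_conditions: int) -> pd.DataFrame:
    """Edges shared by at least ``min_conditions`` condition networks.

    Returns a DataFrame (metabolite, transcript, support, plus one signed
    PCC column per condition, NaN where the edge is absent).
    """
    if not networks:
        raise ValueError("need at least one network")
    conds = [n.condition for n in networks]
    keys = sorted({k for n in networks for k in n.edges})
    rows = []
    for m, t in keys:
        pccs = {n.condition: n.edges.get((m, t), np.nan) for n in networks}
        support = int(sum(np.isfinite(v) for v in pccs.values()))
        if support >= min_conditions:
            rows.append({"metabolite": m, "transcript": t,
                         "support": support, **pccs})
    return pd.DataFrame(rows, columns=["metabolite", "transcript", "support",
                                       *conds])


def merge_networks(
    networks: list,
    focus: str | None = None,
    require_all_conditions: bool = False,
    min_support: int = 1,
) -> pd.DataFrame:
    """Union network with edge weight = supporting-condition count.

    With ``focus`` set to a metabolite, only transcripts connected to it
    are kept; ``require_all_conditions`` keeps only partners connected to
    the focus in every merged condition.  ``min_support`` filters the
    remaining edges by weight.
    """
    if not networks:
        raise ValueError("need at least one network")
    merged = conserved_edges(networks, min_conditions=1)
    if focus is not None:
        present = set(merged["metabolite"]) | set(merged["transcript"])
        if focus not in present:
            raise KeyError(f"focus feature {focus!r} not present in merged network")
        on_focus = merged[(merged["metabolite"] == focus)
                          | (merged["transcript"] == focus)]
        if require_all_conditions:
            on_focus = on_focus[on_focus["support"] == len(networks)]
        merged = on_focus
    merged = merged[merged["support"] >= min_support].reset_index(drop=True)
    merged = merged.rename(columns={"support": "weight"})
    return merged


def write_graphml(networks: list, path) -> None:
    """Export the union of condition networks as GraphML.

    Edges carry per-condition PCC attributes and a support count; nodes
    carry their kind (metabolite or transcript).
    """
    import networkx as nx

    g = nx.Graph()
    for n in networks:
        for (m, t), v in n.edges.items():
            if not g.has_node(m):
                g.add_node(m, kind="metabolite")
            if not g.has_node(t):
                g.add_node(t, kind="transcript")
            if g.has_edge(m, t):
                g[m][t]["support"] += 1
            else:
                g.add_edge(m, t, support=1)
            g[m][t][f"pcc_{n.condition}"] = float(v)
    nx.write_graphml(g, str(path))


def edge_table_to_networks(table: pd.DataFrame) -> list:
    """Rebuild ConditionNetwork objects from a long edge list."""
    nets = []
    for cond, grp in table.groupby("condition", sort=True):
        edges = {(r.metabolite, r.transcript): float(r.pcc)
                 for r in grp.itertuples(index=False)}
        nets.append(ConditionNetwork(condition=str(cond), threshold=None,
                                     edges=edges))
    return nets


def network_edge_table(networks: list) -> pd.DataFrame:
    """Long edge list (condition, metabolite, transcript, pcc)."""
    rows = []
    for n in networks:
        for (m, t), v in sorted(n.edges.items()):
            rows.append({"condition": n.condition, "metabolite": m,
                         "transcript": t, "pcc": v})
    return pd.DataFrame(rows, columns=["condition", "metabolite",
                                       "transcript", "pcc"])
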