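"""Relating instrument settings to quality indicators.

Three complementary views:

* per-setting Pearson correlation with one indicator (Bonferroni-adjusted
  over the number of settings tested);
* two-group distribution tests: runs are split at an indicator percentile
  (top 20% vs the rest) and each setting is compared across groups with
  Kolmogorov-Smirnov, Mann-Whitney U and Kruskal-Wallis tests, each family
  Benjamini-Hochberg adjusted across settings — a setting is called
  significant only when all three adjusted p-values pass, and the largest
  of the three is reported (the most conservative consistent value);
* constraint-based causal structure learning with the PC algorithm:
  PC-stable skeleton search using Fisher-z partial-correlation conditional
  independence tests, v-structure orientation and Meek propagation,
  yielding a CPDAG over tunable settings and indicators.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError

__all__ = [
    "correlate_settings",
    "compare_groups",
    "pc_causal_graph",
    "CausalGraph",
]


def correlate_settings(
    settings: pd.DataFrame,
    indicator_values: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of every setting with one indicator series.

    Rows align on the shared index; constant settings are excluded (their
    correlation is undefined) and listed via the ``excluded`` attribute of
    the returned frame. p-values are Bonferroni-adjusted by the number of
    settings tested.
    """
    common = settings.index.intersection(indicator_values.index)
    if len(common) < 5:
        raise InsufficientDataError(
            f"need >= 5 runs with settings and indicator values, have {len(common)}"
        )
    s = settings.loc[common]
    y = indicator_values.loc[common].to_numpy(dtype=float)
    sds = s.std(axis=0, ddof=1)
    excluded = [str(c) for c in sds.index[~(sds > 0)]]
    tested = [c for c in s.columns if c not in excluded]
    rows = []
    m = len(tested)
    for name in tested:
        r, p = stats.pearsonr(s[name].to_numpy(dtype=float), y)
        rows.append(
            {
                "setting": name,
                "pearson_r": float(r),
                "p_raw": float(p),
                "p_bonferroni": float(min(p * m, 1.0)),
                "significant": bool(min(p * m, 1.0) < alpha),
            }
        )
    out = pd.DataFrame(rows).sort_values("p_bonferroni", ignore_index=True)
    out.attrs["excluded"] = excluded
    return out


def compare_groups(
    settings: pd.DataFrame,
    indicator_values: pd.Series,
    split_percentile: float = 80.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare each setting between high- and low-indicator run groups.

    The high group is the top (100 - split_percentile)% of runs by the
    indicator. Returns one row per setting with the three adjusted
    p-values, the significance call, the reported p (max of the three when
    significant) and the sign of the median difference (blank when the
    medians are equal).
    """
    common = settings.index.intersection(indicator_values.index)
    y = indicator_values.loc[common].to_numpy(dtype=float)
    cut = np.percentile(y, split_percentile)
    high = y >= cut
    if high.sum() < 5 or (~high).sum() < 5:
        raise InsufficientDataError(
            f"groups of {int(high.sum())}/{int((~high).sum())} runs are too small"
        )
    s = settings.loc[common]
    sds = s.std(axis=0, ddof=1)
    tested = [c for c in s.columns if sds[c] > 0]
    raw = {"ks": [], "mwu": [], "kw": []}
    medians = []
    for name in tested:
        x = s[name].to_numpy(dtype=float)
        a, b = x[high], x[~high]
        raw["ks"].append(stats.ks_2samp(a, b).pvalue)
        raw["mwu"].append(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        raw["kw"].append(stats.kruskal(a, b).pvalue)
        medians.append((float(np.median(a)), float(np.median(b))))
    adj = {
        k: multipletests(v, method="fdr_bh")[1] if v else np.array([])
        for k, v in raw.items()
    }
    rows = []
    for i, name in enumerate(tested):
        p_ks, p_mwu, p_kw = adj["ks"][i], adj["mwu"][i], adj["kw"][i]
        significant = bool(max(p_ks, p_mwu, p_kw) < alpha)
        med_hi, med_lo = medians[i]
        if med_hi > med_lo:
            sign = "+"
        elif med_hi < med_lo:
            sign = "-"
        else:
            sign = ""
        rows.append(
            {
                "setting": name,
                "p_ks": float(p_ks), "p_mwu": float(p_mwu), "p_kw": float(p_kw),
                "significant": significant,
                "reported_p": float(max(p_ks, p_mwu, p_kw)) if significant else np.nan,
                "sign": sign,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PC algorithm
# ---------------------------------------------------------------------------


@dataclass
class CausalGraph:
    """CPDAG output of the PC algorithm.

    ``skeleton`` holds every adjacency as a frozenset pair; ``directed``
    the oriented edges (tail, head); ``undirected`` the adjacencies left
    unoriented. The directed portion is acyclic by construction.
    """

    nodes: list[str]
    skeleton: set[frozenset]
    directed: set[tuple[str, str]]
    undirected: set[frozenset]
    alpha: float
    sepsets: dict[frozenset, tuple[str, ...]] = field(default_factory=dict)

    def reduced(self, keep_nodes: set[str]) -> "CausalGraph":
        """Retain only edges incident to at least one of ``keep_nodes``."""
        directed = {
            (a, b) for a, b in self.directed if a in keep_nodes or b in keep_nodes
        }
        undirected = {e for e in self.undirected if e & keep_nodes}
        skeleton = {e for e in self.skeleton if e & keep_nodes}
        return CausalGraph(
            nodes=self.nodes, skeleton=skeleton, directed=directed,
            undirected=undirected, alpha=self.alpha,
        )

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            {"source": a, "target": b, "oriented": True} for a, b in sorted(self.directed)
        ]
        rows += [
            {"source": a, "target": b, "oriented": False}
            for a, b in sorted(tuple(sorted(e)) for e in self.undirected)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "oriented"])

    def to_dot(self, indicator_nodes: set[str] | None = None) -> str:
        ind = indicator_nodes or set()
        lines = ["digraph causal {"]
        for n in self.nodes:
            if frozenset_touches(self.skeleton, n):
                color = "red" if n in ind else "blue"
                lines.append(f'  "{n}" [color={color}];')
        for a, b in sorted(self.directed):
            lines.append(f'  "{a}" -> "{b}";')
        for e in sorted(tuple(sorted(e)) for e in self.undirected):
            lines.append(f'  "{e[0]}" -> "{e[1]}" [dir=none];')
        lines.append("}")
        return "\n".join(lines)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        for a, b in (tuple(sorted(e)) for e in self.undirected):
            g.add_edge(a, b, undirected=True)
            g.add_edge(b, a, undirected=True)
        return g


def frozenset_touches(edges: set[frozenset], node: str) -> bool:
    return any(node in e for e in edges)


def _fisher_z_pvalue(
    corr: np.ndarray, n: int, i: int, j: int, cond: tuple[int, ...]
) -> float:
    """p-value of the partial correlation of i,j given cond (Fisher z)."""
    if not cond:
        r = corr[i, j]
    else:
        idx = [i, j, *cond]
        sub = corr[np.ix_(idx, idx)]
        try:
            prec = np.linalg.pinv(sub)
        except np.linalg.LinAlgError:
            return 1.0
        denom = np.sqrt(prec[0, 0] * prec[1, 1])
        r = -prec[0, 1] / denom if denom > 0 else 0.0
    r = float(np.clip(r, -0.999999, 0.999999))
    dof = n - len(cond) - 3
    if dof <= 0:
        return 1.0
    z = 0.5 * np.log((1 + r) / (1 - r))
    statistic = np.sqrt(dof) * abs(z)
    return float(2.0 * stats.norm.sf(statistic))


def pc_causal_graph(
    data: pd.DataFrame,
    alpha: float = 0.15,
    max_cond: int = 3,
    min_rows: int = 30,
) -> CausalGraph:
    """Learn a CPDAG over the data columns with the PC algorithm.

    PC-stable skeleton search with Fisher-z conditional-independence tests
    (conditioning sets up to ``max_cond`` variables), v-structure
    orientation, then Meek rules. Zero-variance columns are dropped;
    non-finite values are rejected.
    """
    if len(data) < min_rows:
        raise InsufficientDataError(
            f"PC needs >= {min_rows} complete rows, have {len(data)}"
        )
    arr = data.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("data contains non-finite values")
    sds = arr.std(axis=0, ddof=1)
    keep = sds > 0
    cols = [c for c, k in zip(data.columns, keep) if k]
    arr = arr[:, keep]
    n, p = arr.shape
    corr = np.corrcoef(arr, rowvar=False)

    adj: dict[int, set[int]] = {i: set(range(p)) - {i} for i in range(p)}
    sepsets: dict[frozenset, tuple[int, ...]] = {}
    level = 0
    while level <= max_cond:
        any_tested = False
        frozen_adj = {i: set(neigh) for i, neigh in adj.items()}  # PC-stable
        for i in range(p):
            for j in sorted(frozen_adj[i]):
                if j not in adj[i]:
                    continue
                candidates = sorted(frozen_adj[i] - {j})
                if len(candidates) < level:
                    continue
                for cond in itertools.combinations(candidates, level):
                    any_tested = True
                    if _fisher_z_pvalue(corr, n, i, j, cond) > alpha:
                        adj[i].discard(j)
                        adj[j].discard(i)
                        sepsets[frozenset((i, j))] = cond
                        break
        if not any_tested and level > 0:
            break
        level += 1

    skeleton = {
        frozenset((cols[i], cols[j]))
        for i in range(p) for j in adj[i] if i < j
    }

    # orientation: v-structures i -> k <- j when k not in sepset(i, j)
    directed: set[tuple[int, int]] = set()
    for k in range(p):
        for i, j in itertools.combinations(sorted(adj[k]), 2):
            if j in adj[i]:
                continue
            sep = sepsets.get(frozenset((i, j)), ())
            if k not in sep:
                directed.add((i, k))
                directed.add((j, k))

    def creates_cycle(edges: set[tuple[int, int]], a: int, b: int) -> bool:
        # would a -> b close a directed cycle?
        stack, seen = [b], set()
        while stack:
            u = stack.pop()
            if u == a:
                return True
            if u in seen:
                continue
            seen.add(u)
            stack.extend(v for (t, v) in edges if t == u)
        return False

    # conflicting v-structure orientations -> leave the edge undirected
    conflicted = {(a, b) for (a, b) in directed if (b, a) in directed}
    directed -= conflicted

    # Meek rules, iterated to closure
    changed = True
    while changed:
        changed = False
        undir = [
            (i, j)
            for i in range(p) for j in adj[i] if i < j
            and (i, j) not in directed and (j, i) not in directed
        ]
        for a, b in undir:
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, z not adjacent to y  =>  x -> y
                r1 = any(
                    (z, x) in directed and y not in adj[z] and z != y
                    for z in adj[x]
                )
                # R2: x -> w -> y  =>  x -> y
                r2 = any(
                    (x, w) in directed and (w, y) in directed for w in range(p)
                )
                # R3: x - z1 -> y and x - z2 -> y, z1/z2 non-adjacent => x -> y
                r3 = False
                zs = [
                    z for z in adj[x]
                    if (z, y) in directed
                    and (x, z) not in directed and (z, x) not in directed
                ]
                for z1, z2 in itertools.combinations(zs, 2):
                    if z2 not in adj[z1]:
                        r3 = True
                        break
                if (r1 or r2 or r3) and not creates_cycle(directed, x, y):
                    directed.add((x, y))
                    changed = True
                    break
            if changed:
                break

    directed_named = {(cols[a], cols[b]) for a, b in directed}
    undirected_named = {
        frozenset((cols[i], cols[j]))
        for i in range(p) for j in adj[i] if i < j
        and (i, j) not in directed and (j, i) not in directed
    }
    return CausalGraph(
        nodes=cols,
        skeleton=skeleton,
        directed=directed_named,
        undirected=undirected_named,
        alpha=alpha,
        sepsets={
            frozenset((cols[a], cols[b])): tuple(cols[c] for c in cond)
            for key, cond in sepsets.items()
            for a, b in [tuple(key)]
        },
    )


def structural_hamming_distance(
    skeleton: set[frozenset], true_edges: set[frozenset]
) -> int:
    """Number of edge additions/deletions between two skeletons."""
    return len(skeleton.symmetric_difference(true_edges))
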