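"""Temporal profiling: hierarchical clustering of VOC trajectories, sample
PCA, and fatty-acid release-kinetics summaries."""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "ClusterResult",
    "KineticSummary",
    "temporal_profile_matrix",
    "ward_cluster",
    "cut_tree",
    "pca_samples",
    "kinetic_summary",
    "chain_parity",
    "FATTY_ACID_CARBONS",
]


@dataclass
class ClusterResult:
    """Agglomerative merge tree (scipy linkage encoding) with labels."""

    linkage: np.ndarray    # (n-1, 4): merged ids, height, cluster size
    labels: list           # leaf labels in input order
    method: str = "ward"
    metric: str = "euclidean"

    def __post_init__(self):
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights are not non-decreasing")

    @property
    def leaf_order(self) -> list:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> pd.Series:
        return cut_tree(self, k)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "metric": self.metric,
                "labels": list(map(str, self.labels)),
                "merges": self.linkage[:, :2].astype(int).tolist(),
                "heights": self.linkage[:, 2].tolist(),
                "sizes": self.linkage[:, 3].astype(int).tolist(),
                "leaf_order": list(map(str, self.leaf_order)),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def temporal_profile_matrix(table: pd.DataFrame, standardize: bool = True
                            ) -> pd.DataFrame:
    """Compounds x (group, time) matrix of replicate-mean trajectories.

    Columns follow the sample-type x time layout of a clustered heatmap.
    With ``standardize`` (default) each compound row is centred and divided
    by its standard deviation, so clustering compares trajectory *shapes*
    rather than absolute intensities; rows with zero variance are left
    centred only.
    """
    wide = table.pivot_table(index="compound", columns=["group", "time_h"],
                             values="intensity", aggfunc="mean")
    wide = wide.sort_index(axis=1)
    if standardize:
        centred = wide.sub(wide.mean(axis=1), axis=0)
        sd = wide.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        wide = centred.div(sd, axis=0)
    return wide


def ward_cluster(matrix, axis: int = 0, labels=None) -> ClusterResult:
    """Hierarchical clustering with Euclidean distance and Ward linkage.

    Ward's criterion merges, at every step, the pair of clusters whose
    fusion least increases the total within-cluster variance; with Euclidean
    input this makes the merge heights monotone.  ``axis=0`` clusters rows,
    ``axis=1`` columns.
    """
    if isinstance(matrix, pd.DataFrame):
        data = matrix.to_numpy(dtype=float)
        default_labels = list(matrix.index if axis == 0 else matrix.columns)
    else:
        data = np.asarray(matrix, dtype=float)
        default_labels = None
    if axis == 1:
        data = data.T
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in clustering input")
    if labels is None:
        labels = default_labels or [f"item_{i}" for i in range(data.shape[0])]
    Z = hierarchy.linkage(data, method="ward", metric="euclidean")
    return ClusterResult(linkage=Z, labels=list(labels))


def cut_tree(result: ClusterResult, k: int) -> pd.Series:
    """Cut the merge tree into exactly ``k`` clusters.

    Because Ward trees are monotone, cutting at 2 and refining to 4 is
    consistent: the 4-cut is a refinement of the 2-cut.  Cluster ids are
    renumbered 1..k in order of first appearance.
    """
    n = len(result.labels)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = hierarchy.cut_tree(result.linkage, n_clusters=k).ravel()
    seen: dict[int, int] = {}
    assign = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in seen:
            seen[c] = len(seen) + 1
        assign[i] = seen[c]
    return pd.Series(assign, index=result.labels, name=f"cluster_k{k}")


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_pct: np.ndarray


def pca_samples(matrix, n_components: int = 2, center: bool = True) -> PcaResult:
    """Plain SVD-based PCA of an observations x variables matrix.

    Sign convention matches the SCA: each component is oriented so its
    largest-magnitude loading is positive.  Requesting more components than
    the matrix rank truncates with a warning.
    """
    if isinstance(matrix, pd.DataFrame):
        data = matrix.to_numpy(dtype=float)
        row_labels = list(matrix.index)
        col_labels = list(matrix.columns)
    else:
        data = np.asarray(matrix, dtype=float)
        row_labels = list(range(data.shape[0]))
        col_labels = [f"var_{i}" for i in range(data.shape[1])]
    X = data - data.mean(axis=0) if center else data
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2)) or 1.0
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    R = int(n_components)
    if R > rank:
        warnings.warn(f"requested {R} components but rank is {rank}; truncating",
                      stacklevel=2)
        R = rank
    U, s, Vt = U[:, :R], s[:R], Vt[:R]
    loadings = Vt.T
    scores = U * s
    for r in range(R):
        j = int(np.argmax(np.abs(loadings[:, r])))
        if loadings[j, r] < 0:
            loadings[:, r] *= -1.0
            scores[:, r] *= -1.0
    comp = [f"PC{r + 1}" for r in range(R)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=row_labels, columns=comp),
        loadings=pd.DataFrame(loadings, index=col_labels, columns=comp),
        explained_pct=100.0 * s**2 / total,
    )


#: carbon counts for the fermentation acids tracked in the kinetics panels;
#: extensible via the ``class_map`` argument of :func:`kinetic_summary`
FATTY_ACID_CARBONS = {
    "formic acid": 1,
    "acetic acid": 2,
    "propanoic acid": 3,
    "propionic acid": 3,
    "butanoic acid": 4,
    "butyric acid": 4,
    "2-methylpropanoic acid": 4,
    "isobutyric acid": 4,
    "pentanoic acid": 5,
    "valeric acid": 5,
    "3-methylbutanoic acid": 5,
    "isovaleric acid": 5,
    "2-methylbutanoic acid": 5,
    "hexanoic acid": 6,
    "caproic acid": 6,
    "4-methylpentanoic acid": 6,
    "heptanoic acid": 7,
    "enanthic acid": 7,
    "octanoic acid": 8,
    "caprylic acid": 8,
    "nonanoic acid": 9,
    "pelargonic acid": 9,
    "decanoic acid": 10,
    "capric acid": 10,
}

_FORMULA_RE = re.compile(r"^C(\d+)H\d+(?:O\d*)?$")


def chain_parity(compound_name_or_formula: str) -> tuple[int, str]:
    """Carbon chain length and odd/even parity of a fatty acid.

    Resolves via a built-in lookup of common fermentation acids, or a
    molecular formula like ``C4H8O2``.  Unknown compounds raise rather than
    guess.
    """
    name = compound_name_or_formula.strip()
    m = _FORMULA_RE.match(name)
    if m:
        n = int(m.group(1))
        return n, "odd" if n % 2 else "even"
    n = FATTY_ACID_CARBONS.get(name.lower())
    if n is None:
        raise ValueError(
            f"unknown compound {compound_name_or_formula!r}: no chain-length "
            "entry and not a parsable formula"
        )
    return n, "odd" if n % 2 else "even"


@dataclass
class KineticSummary:
    """Release-kinetics summaries for one group's compounds.

    ``curves`` holds the replicate mean ± sd trajectory per compound;
    ``summary`` one row per compound with plateau time, steepest-rise
    window, final-time intensity and (where resolvable) chain length/parity
    plus the within-class intensity rank at the final time point.
    """

    group: str
    curves: pd.DataFrame   # compound, time_h, mean, sd
    summary: pd.DataFrame  # per-compound kinetics descriptors


def kinetic_summary(table: pd.DataFrame, group: str, compounds=None,
                    class_map: dict | None = None,
                    plateau_tol: float = 0.05) -> KineticSummary:
    """Summarise release kinetics of compounds within one group.

    plateau time
        Earliest design time point after which every later mean differs from
        it by at most ``plateau_tol`` x the curve maximum; a curve still
        moving at the last time point has no plateau (None).
    steepest-rise window
        The consecutive time interval with the largest increase in the mean
        curve; ties resolve to the earliest window.
    ranking
        Compounds with a known chain length are ranked by mean intensity at
        the final time point (1 = most abundant).
    """
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} absent from table")
    if compounds is not None:
        missing = set(compounds) - set(sub["compound"].unique())
        if missing:
            raise ValueError(f"compounds absent for group {group!r}: {sorted(missing)}")
        sub = sub[sub["compound"].isin(compounds)]
    times = np.array(sorted(sub["time_h"].unique()), dtype=float)
    if times.size < 3:
        raise ValueError("kinetic summaries need at least 3 time points")
    stats = (
        sub.groupby(["compound", "time_h"], observed=True)["intensity"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    rows = []
    for compound, block in stats.groupby("compound", observed=True):
        block = block.sort_values("time_h")
        means = block["mean"].to_numpy(dtype=float)
        t = block["time_h"].to_numpy(dtype=float)
        cmax = float(np.max(np.abs(means))) if means.size else 0.0
        tol_abs = plateau_tol * cmax
        plateau = None
        for i in range(len(t) - 1):
            if np.all(np.abs(means[i + 1:] - means[i]) <= tol_abs):
                plateau = float(t[i])
                break
        diffs = np.diff(means)
        if diffs.size:
            imax = int(np.argmax(diffs))  # argmax takes earliest on ties
            window = (float(t[imax]), float(t[imax + 1]))
            max_slope = float(diffs[imax])
        else:
            window, max_slope = (None, None), 0.0
        try:
            length, parity = chain_parity(compound)
        except ValueError:
            length, parity = None, None
        rows.append(
            {
                "compound": compound,
                "plateau_time_h": plateau,
                "slope_window_start_h": window[0],
                "slope_window_end_h": window[1],
                "max_increase": max_slope,
                "final_intensity": float(means[-1]),
                "chain_length": length,
                "parity": parity,
            }
        )
    summary = pd.DataFrame(rows).sort_values("compound").reset_index(drop=True)
    in_class = summary["chain_length"].notna()
    summary["rank_in_class"] = np.nan
    if in_class.any():
        summary.loc[in_class, "rank_in_class"] = (
            summary.loc[in_class, "final_intensity"]
            .rank(ascending=False, method="first")
            .astype(int)
        )
    if class_map:
        summary["class"] = summary["compound"].map(class_map)
    return KineticSummary(group=group, curves=stats, summary=summary)
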