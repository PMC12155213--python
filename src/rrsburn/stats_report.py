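"""Per-day group statistics, correlations, and heatmap aggregation.

Inference mirrors the study's analysis plan: one-way fixed-effects ANOVA of
per-wound HI across categories on each assessment day, Tukey HSD pairwise
comparisons within a day (no additional adjustment across days), Pearson
correlations of HI against depth score and time to heal, and a category x
day mean-HI matrix with hierarchical row clustering (k-means labels also
emitted) for the heatmap view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .indices import impute_pod7

__all__ = [
    "per_day_anova",
    "tukey_hsd",
    "pearson",
    "heatmap_matrix",
    "HeatmapResult",
]


def _day_groups(table: pd.DataFrame, kind: str, pod: int) -> dict[str, np.ndarray]:
    sub = table[(table["kind"] == kind) & (table["pod"] == pod)]
    groups = {
        cat: g["value"].to_numpy(dtype=float)
        for cat, g in sub.groupby("category", sort=True)
    }
    return {cat: v for cat, v in groups.items() if v.size >= 2}


def per_day_anova(table: pd.DataFrame, kind: str, pod: int) -> tuple[float, float]:
    """One-way ANOVA of the index across categories on one assessment day.

    ``table`` is the long study table (columns category, pod, kind, value).
    Requires >= 2 categories with >= 2 wounds each.  Identical constant
    groups have zero between-group variance: F = 0, p = 1 by convention.
    """
    groups = _day_groups(table, kind, pod)
    if len(groups) < 2:
        raise ValueError(
            f"ANOVA needs >= 2 categories with >= 2 wounds on POD {pod}, "
            f"got {len(groups)}"
        )
    arrays = list(groups.values())
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):  # zero within-group variance, nonzero between
        return float("inf"), 0.0
    return float(f), float(p)


def tukey_hsd(table: pd.DataFrame, kind: str, pod: int) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons between categories on one day.

    Returns a frame with columns group1, group2, meandiff, p_adj, reject.
    """
    groups = _day_groups(table, kind, pod)
    if len(groups) < 2:
        raise ValueError(f"Tukey HSD needs >= 2 categories on POD {pod}")
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[cat] * len(v) for cat, v in groups.items()])
    res = pairwise_tukeyhsd(values, labels)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    frame = frame.rename(columns={"p-adj": "p_adj"})
    for col in ("meandiff", "p_adj"):
        frame[col] = frame[col].astype(float)
    return frame[["group1", "group2", "meandiff", "p_adj", "reject"]]


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class HeatmapResult:
    matrix: pd.DataFrame            # category x POD mean index (unclamped)
    row_order: list
    linkage_matrix: np.ndarray
    first_merge: tuple              # pair of categories merged first
    kmeans_labels: dict
    imputed_cells: list = field(default_factory=list)
    tie_flag: bool = False
    display_clip: tuple = (0.0, 10.0)


def heatmap_matrix(
    table: pd.DataFrame,
    kind: str = "HI",
    k: int = 2,
    seed: int = 0,
) -> HeatmapResult:
    """Category x day mean-index matrix with row clustering.

    Cell = mean over wounds of that category on that day; a missing POD-7
    cell is imputed as mean(POD 3, POD 14) for this aggregation only.  Rows
    are clustered hierarchically (Euclidean, average linkage) and the first
    merge — the closest pair of category trajectories — is reported;
    seeded k-means labels (k = 2 by default) are also emitted.  The 0-10
    display clamp is a rendering concern: stored values are unclamped.
    """
    sub = table[table["kind"] == kind]
    if sub.empty:
        raise ValueError(f"no records of kind {kind!r}")
    pods = sorted(sub["pod"].unique())
    imputed = []
    series_by_cat = {}
    for cat, g in sub.groupby("category", sort=True):
        series = g.groupby("pod")["value"].mean().to_dict()
        if 7 in pods and 7 not in series:
            series = impute_pod7(series)
            imputed.append((cat, 7))
        missing = [p for p in pods if p not in series]
        if missing:
            raise ValueError(f"category {cat!r} has no values for PODs {missing}")
        series_by_cat[cat] = [series[p] for p in pods]
    matrix = pd.DataFrame.from_dict(series_by_cat, orient="index", columns=pods)
    rows = matrix.to_numpy()
    tie = bool(np.allclose(rows, rows[0]))
    z = linkage(rows, method="average", metric="euclidean")
    order = [matrix.index[i] for i in leaves_list(z)]
    i, j = int(z[0, 0]), int(z[0, 1])
    first_merge = (matrix.index[i], matrix.index[j])
    km = KMeans(n_clusters=min(k, len(matrix)), n_init=10, random_state=seed)
    labels = km.fit_predict(rows)
    return HeatmapResult(
        matrix=matrix,
        row_order=order,
        linkage_matrix=z,
        first_merge=first_merge,
        kmeans_labels=dict(zip(matrix.index, (int(v) for v in labels))),
        imputed_cells=imputed,
        tie_flag=tie,
    )


def plot_heatmap(result: HeatmapResult, path) -> None:
    """Render the clustered heatmap to ``path`` with the 0-10 display clamp."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = result.matrix.loc[result.row_order].clip(*result.display_clip)
    fig, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=result.display_clip[0], vmax=result.display_clip[1])
    ax.set_xticks(range(data.shape[1]), [f"POD {p}" for p in data.columns],
                  rotation=45, ha="right")
    ax.set_yticks(range(data.shape[0]), data.index)
    fig.colorbar(im, ax=ax, label="mean index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
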