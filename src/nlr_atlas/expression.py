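"""Expression-pattern clustering and responsive/broad-spectrum NLR calls.

Replicates are collapsed by arithmetic mean per (experiment, condition,
timepoint, tissue) cell; rows are z-scaled (the "scale by row" convention of
heatmap tools); genes are clustered by agglomerative hierarchical clustering
with Euclidean distance and complete linkage, and the tree is cut into a
user-chosen number of patterns. Responsive calls compare pseudo-count-
stabilised inoculated/control mean ratios against a fold threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core import ConfigError, ExpressionMatrix

DEFAULT_EPSILON = 0.5      # pseudo-TPM stabilising fold changes
DEFAULT_MIN_EXPR = 1.0     # minimal inoculated mean TPM for a call

_CELL_KEYS = ["experiment", "condition", "timepoint", "tissue"]


def collapse_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Mean across replicates per design cell; sample names become cell ids."""
    if m.design.empty:
        raise ConfigError("expression matrix has no design sheet")
    design = m.design.loc[list(m.values.columns)]
    cells = design.groupby(_CELL_KEYS, sort=False).groups
    cols, rows = {}, []
    for key, samples in cells.items():
        if len(samples) == 0:
            raise ConfigError(f"design cell {key} has no samples")
        exp, cond, tp, tissue = key
        name = f"{exp}|{cond}|{tp:g}h|{tissue}"
        cols[name] = m.values[list(samples)].mean(axis=1)
        rows.append({"sample": name, "experiment": exp, "condition": cond,
                     "timepoint": tp, "tissue": tissue, "replicate": 0})
    values = pd.DataFrame(cols, index=m.values.index)
    return ExpressionMatrix(values, pd.DataFrame(rows).set_index("sample"))


def scale_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-scores (sample sd, ddof=1); returns (z, zero-variance genes).

    Zero-variance rows are set to all-zero and reported rather than dropped.
    """
    if values.shape[1] < 2:
        raise ConfigError("row scaling needs at least 2 columns")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (arr - mean) / sd
    z[flat] = 0.0
    return (pd.DataFrame(z, index=values.index, columns=values.columns),
            list(values.index[flat]))


@dataclass
class PatternAssignment:
    assignments: dict[str, int]            # gene -> pattern id in 1..k
    k: int
    heights: np.ndarray = field(default_factory=lambda: np.empty(0))

    def members(self, pattern: int) -> list[str]:
        return [g for g, p in self.assignments.items() if p == pattern]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.assignments), "pattern": list(self.assignments.values())}
        )


def cluster_patterns(z: pd.DataFrame, k: int) -> PatternAssignment:
    """Cut a complete-linkage Euclidean dendrogram of gene rows into k patterns.

    Pattern ids are relabelled 1..k in order of first appearance along the
    input gene order, so the partition (not the labels) is what is invariant
    to row permutation.
    """
    n = len(z)
    if not (1 <= k <= n):
        raise ConfigError(f"k={k} outside [1, {n}]")
    if k == n:
        return PatternAssignment(
            {g: i + 1 for i, g in enumerate(z.index)}, k)
    Z = linkage(z.to_numpy(dtype=float), method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    assignments = {}
    for gene, lab in zip(z.index, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        assignments[gene] = relabel[lab]
    return PatternAssignment(assignments, k, Z[:, 2])


def responsive_genes(m: ExpressionMatrix, experiment: str, fold: float = 2.0,
                     min_expr: float = DEFAULT_MIN_EXPR,
                     epsilon: float = DEFAULT_EPSILON) -> set[str]:
    """Genes whose inoculated/control mean ratio reaches ``fold``.

    Ratio is (mean inoculated + eps) / (mean control + eps); genes must also
    reach ``min_expr`` mean TPM when inoculated.
    """
    design = m.design.loc[list(m.values.columns)]
    sub = design[design["experiment"] == experiment]
    ino = sub.index[sub["condition"] == "inoculated"]
    ctl = sub.index[sub["condition"] == "control"]
    if len(ino) == 0 or len(ctl) == 0:
        raise ConfigError(
            f"experiment {experiment!r} needs inoculated and control samples")
    mi = m.values[list(ino)].mean(axis=1)
    mc = m.values[list(ctl)].mean(axis=1)
    ratio = (mi + epsilon) / (mc + epsilon)
    return set(m.values.index[(ratio >= fold) & (mi >= min_expr)])


def broad_spectrum(calls: dict[str, set[str]],
                   min_experiments: int = 2) -> set[str]:
    """Genes responsive in at least ``min_experiments`` experiments."""
    if len(calls) < 2:
        raise ConfigError("broad-spectrum calls need >= 2 experiments")
    counts: dict[str, int] = {}
    for genes in calls.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, n in counts.items() if n >= min_experiments}


def tissue_specificity(m: ExpressionMatrix) -> pd.DataFrame:
    """Dominant tissue per gene and specificity = max-tissue mean / sum.

    The score lives in [1/T, 1] for T tissues; genes with zero expression in
    every tissue get NaN.
    """
    design = m.design.loc[list(m.values.columns)]
    tissues = list(pd.unique(design["tissue"]))
    if len(tissues) < 2:
        raise ConfigError("tissue specificity needs >= 2 tissues")
    means = pd.DataFrame({
        t: m.values[list(design.index[design["tissue"] == t])].mean(axis=1)
        for t in tissues
    })
    total = means.sum(axis=1)
    dominant = means.idxmax(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = means.max(axis=1) / total
    score[total == 0] = np.nan
    dominant[total == 0] = ""
    return pd.DataFrame({"gene": m.values.index, "tissue": dominant,
                         "specificity": score}).set_index("gene")


def plot_heatmap(z: pd.DataFrame, assignment: PatternAssignment | None,
                 path) -> None:
    """Static heatmap of the scaled matrix, genes ordered by pattern."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if assignment is not None:
        order = sorted(z.index, key=lambda g: (assignment.assignments[g], g))
        z = z.loc[order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * z.shape[1]), max(3, 0.02 * len(z))))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r",
                   interpolation="nearest")
    ax.set_xticks(range(z.shape[1]))
    ax.set_xticklabels(z.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(z)} genes")
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "nlr-atlas"})
    plt.close(fig)
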