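"""Summaries and figures for benchmark results and kernels.

Box-plot statistics use the linear-interpolation quantile convention;
outliers are values strictly outside [q1 - 1.5 IQR, q3 + 1.5 IQR].  Line
series condense a result table to the median metric of the best
algorithm per group, where "best" means winning the most subsample
fractions by median (nearest-neighbour algorithms are excluded from the
contest by convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXCLUDED_FROM_BEST = ("nn1", "simkern-nn1")

_ALGORITHM_ORDER = ("linear-svm", "rbf-svm", "rf", "nn1",
                    "simkern-svm", "simkern-rf", "simkern-nn1")


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    lower_fence: float
    upper_fence: float
    outliers: list = field(default_factory=list)


def boxplot_summary(values) -> BoxplotSummary:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to summarize")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = sorted(values[(values < lo) | (values > hi)].tolist())
    return BoxplotSummary(float(med), float(q1), float(q3), float(lo),
                          float(hi), outliers)


def _medians(results: pd.DataFrame) -> pd.DataFrame:
    return (results.groupby(["algorithm", "fraction"])["value"]
            .median().reset_index())


def best_algorithm(results: pd.DataFrame, group: str,
                   exclude=EXCLUDED_FROM_BEST) -> str:
    """The algorithm that most often has the highest median metric across
    the subsample fractions; ties broken by mean median, then fixed
    order."""
    sub = results[(results["group"] == group) &
                  (~results["algorithm"].isin(exclude))]
    if sub.empty:
        raise ValueError(f"no eligible algorithms in group {group!r}")
    med = _medians(sub)
    order = {a: i for i, a in enumerate(_ALGORITHM_ORDER)}
    wins = {}
    for _, frame in med.groupby("fraction"):
        winner = min(frame.itertuples(),
                     key=lambda t: (-t.value, order.get(t.algorithm, 99))
                     ).algorithm
        wins[winner] = wins.get(winner, 0) + 1
    top = max(wins.values())
    tied = [a for a, w in wins.items() if w == top]
    if len(tied) == 1:
        return tied[0]
    means = med[med["algorithm"].isin(tied)].groupby("algorithm")[
        "value"].mean()
    top_mean = means.max()
    tied = [a for a in tied if means[a] == top_mean]
    return sorted(tied, key=_ALGORITHM_ORDER.index)[0]


@dataclass
class LineSeries:
    group: str
    algorithm: str
    fractions: list
    medians: list


def line_series(results: pd.DataFrame, group: str,
                exclude=EXCLUDED_FROM_BEST) -> LineSeries:
    """Median metric of the group's best algorithm at each fraction."""
    alg = best_algorithm(results, group, exclude)
    med = _medians(results[results["algorithm"] == alg])
    med = med.sort_values("fraction")
    return LineSeries(group, alg, med["fraction"].tolist(),
                      med["value"].tolist())


def group_median_curve(results: pd.DataFrame, group: str,
                       exclude=EXCLUDED_FROM_BEST) -> dict:
    """fraction -> best-algorithm median for the group (the line-plot
    data)."""
    s = line_series(results, group, exclude)
    return dict(zip(s.fractions, s.medians))


# ------------------------------------------------------------------ plots

def kernel_heatmap_export(kernel, path) -> None:
    """Heatmap of K on the fixed [0, 1] colour scale (comparable across
    exports)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(kernel.K, vmin=0.0, vmax=1.0, cmap="viridis",
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, label="similarity")
    ax.set_xlabel("sample")
    ax.set_ylabel("sample")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def convergence_plot(trace, path, start_r: int = 3) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = np.arange(start_r + 1, start_r + 1 + len(trace))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(r, trace, "o-")
    ax.set_xlabel("trial r")
    ax.set_ylabel(r"$\|K^{(r)} - K^{(r-1)}\|_F$")
    ax.set_title("Kernel convergence")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def benchmark_boxplot(results: pd.DataFrame, path) -> None:
    """One panel per subsample fraction, boxes per algorithm, coloured by
    group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fractions = sorted(results["fraction"].unique())
    algs = [a for a in _ALGORITHM_ORDER
            if a in set(results["algorithm"])]
    fig, axes = plt.subplots(1, len(fractions),
                             figsize=(2.6 * len(fractions), 3.6),
                             sharey=True, squeeze=False)
    for ax, frac in zip(axes[0], fractions):
        data = [results[(results["fraction"] == frac) &
                        (results["algorithm"] == a)]["value"].to_numpy()
                for a in algs]
        bp = ax.boxplot(data, tick_labels=algs, whis=1.5, sym="x")
        for box, a in zip(bp["boxes"], algs):
            box.set_color("tab:green" if a.startswith("simkern")
                          else "tab:orange")
        ax.set_title(f"fraction {frac:g}")
        ax.tick_params(axis="x", rotation=90)
    axes[0][0].set_ylabel(results["metric"].iloc[0])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def learning_curve_plot(results: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.6))
    for group, colour in (("standard", "tab:orange"),
                          ("simkern", "tab:green")):
        if not (results["group"] == group).any():
            continue
        s = line_series(results, group)
        ax.plot(s.fractions, s.medians, "o-", color=colour,
                label=f"{group} ({s.algorithm})")
    ax.set_xlabel("training subsample fraction")
    ax.set_ylabel(f"median {results['metric'].iloc[0]}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
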