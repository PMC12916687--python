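"""Published benchmark summary statistics and comparisons against them.

The packaged table carries subject-independent accuracy / macro-F1 summaries
(mean, SD over cross-validation folds) reported for a range of EEG emotion
classifiers on the SEED (15 LOSO folds), THU-EP and FACED (10 leave-n-out
folds each) corpora. Since per-fold accuracy lists are not published, Welch's
t-test and Cohen's d are computed from these summaries.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .training import WelchResult, welch_stats

__all__ = ["load_reference_results", "compare_methods", "comparison_table"]


def load_reference_results(path: str | Path | None = None) -> pd.DataFrame:
    """Benchmark summary table (dataset, method, acc/f1 mean and SD, n folds)."""
    if path is not None:
        return pd.read_csv(path)
    with resources.files("msgm.data").joinpath("reference_results.csv").open() as fh:
        return pd.read_csv(fh)


def _row(df: pd.DataFrame, dataset: str, method: str) -> pd.Series:
    sel = df[(df.dataset == dataset) & (df.method == method)]
    if len(sel) != 1:
        raise KeyError(f"no unique row for {method!r} on {dataset!r}")
    return sel.iloc[0]


def compare_methods(dataset: str, method_a: str, method_b: str,
                    df: pd.DataFrame | None = None,
                    metric: str = "acc") -> WelchResult:
    """Welch comparison of two methods' fold accuracies from their summaries."""
    df = load_reference_results() if df is None else df
    a = _row(df, dataset, method_a)
    b = _row(df, dataset, method_b)
    return welch_stats((a[f"{metric}_mean"], a[f"{metric}_sd"], a.n_folds),
                       (b[f"{metric}_mean"], b[f"{metric}_sd"], b.n_folds))


def comparison_table(method: str = "MSGM",
                     baselines: tuple[str, ...] = ("EmT", "BiDANN", "DMATN",
                                                   "RGNN", "DGCNN"),
                     df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-dataset Welch t / p / Cohen's d of `method` vs each baseline."""
    df = load_reference_results() if df is None else df
    rows = []
    for dataset in df.dataset.unique():
        for base in baselines:
            r = compare_methods(dataset, method, base, df)
            rows.append({"dataset": dataset, "baseline": base,
                         "delta": round(r.delta, 2), "t": round(r.t, 2),
                         "p": round(r.p, 3), "d": round(r.d, 2)})
    return pd.DataFrame(rows)
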