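"""CIN25 signature scoring, clustering and survival stratification.

The workflow: CPM-normalize a gene-by-sample count matrix, log2(CPM+1)
transform, z-scale each gene across samples, and sum the scaled values
of the signature genes per sample so that every gene contributes equally
to the score.  Samples are clustered (k-means, k=3 by default) on the
scaled signature submatrix, or dichotomized at the median score, and the
resulting groups are compared by Kaplan-Meier curves with the log-rank
(Mantel-Cox) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test
from sklearn.cluster import KMeans

__all__ = [
    "LogRankResult",
    "default_signature",
    "cpm_normalize",
    "scale_genes",
    "score_signature",
    "kmeans_cluster",
    "median_split",
    "km_curve",
    "logrank",
]


def default_signature() -> list[str]:
    """The editable default CIN25 gene list shipped with the package."""
    text = resources.files("ccapipe.data").joinpath("cin25_default.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]


def cpm_normalize(matrix: pd.DataFrame, log2: bool = False) -> pd.DataFrame:
    """Counts-per-million per sample; optionally log2(CPM + 1).

    Columns are samples; each is scaled to a total of 10^6.
    """
    if (matrix.values < 0).any():
        raise ValueError("negative values in raw count matrix")
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = matrix / totals * 1e6
    return np.log2(cpm + 1.0) if log2 else cpm


def scale_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-scale each gene (row) across samples; sd with n-1 denominator.

    Zero-variance genes scale to all zeros (with a warning) so they
    contribute nothing to downstream scores.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to scale across")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s) contribute 0 to scores",
            stacklevel=2,
        )
    sd = sd.replace(0, 1.0)
    return matrix.sub(mean, axis=0).div(sd, axis=0)


def _intersect_signature(matrix: pd.DataFrame, genes) -> list[str]:
    present = [g for g in genes if g in matrix.index]
    missing = [g for g in genes if g not in matrix.index]
    if not present:
        raise ValueError(f"no signature genes found in matrix; missing: {missing}")
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}", stacklevel=3)
    return present


def score_signature(matrix: pd.DataFrame, genes) -> pd.Series:
    """Per-sample signature score: sum of per-gene scaled values.

    ``matrix`` should already be on the scale to score (typically
    log2(CPM+1)); scaling happens across all its samples, so the scores
    sum to zero over that population.
    """
    present = _intersect_signature(matrix, genes)
    scaled = scale_genes(matrix.loc[present])
    scores = scaled.sum(axis=0)
    scores.name = "signature_score"
    return scores


def kmeans_cluster(
    matrix: pd.DataFrame,
    genes,
    k: int = 3,
    restarts: int = 25,
    seed: int = 0,
    scale: bool = True,
) -> pd.Series:
    """K-means clustering of samples on the signature submatrix.

    Lloyd's algorithm, best of ``restarts`` seeded initializations by
    within-cluster sum of squares; labels are 1..k.  ``scale`` z-scales
    genes first (what a clustered heatmap displays).
    """
    if k > matrix.shape[1]:
        raise ValueError(f"k={k} exceeds the number of samples ({matrix.shape[1]})")
    present = _intersect_signature(matrix, genes)
    sub = matrix.loc[present]
    if scale:
        sub = scale_genes(sub)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(sub.T.values)
    return pd.Series(labels + 1, index=matrix.columns, name="cluster")


def median_split(scores: pd.Series) -> pd.Series:
    """Dichotomize scores at the median: > median is "high", <= is "low"."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples")
    med = scores.median()
    groups = pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="score_group"
    )
    if (groups == "low").all():
        warnings.warn("all scores at or below the median; high group empty", stacklevel=2)
    return groups


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival curve with right censoring.

    Returns a frame with ``time`` and ``survival`` columns including the
    origin (time 0, survival 1).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("no records")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.values, "survival": sf.iloc[:, 0].values})


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    n_per_group: dict[str, int]


def logrank(groups: dict[str, tuple]) -> LogRankResult:
    """Log-rank (Mantel-Cox) test across groups.

    ``groups`` maps a label to ``(times, events)``.  Requires at least
    two groups and at least one event overall; two groups give a
    chi-square statistic with one degree of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    parsed = {}
    total_events = 0
    for label, (times, events) in groups.items():
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=bool)
        if (t < 0).any():
            raise ValueError(f"negative survival times in group {label!r}")
        parsed[label] = (t, e)
        total_events += int(e.sum())
    if total_events == 0:
        raise ValueError("no events in any group; log-rank undefined")

    labels = list(parsed)
    if len(labels) == 2:
        (ta, ea), (tb, eb) = parsed[labels[0]], parsed[labels[1]]
        res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        df = 1
    else:
        t = np.concatenate([parsed[lab][0] for lab in labels])
        e = np.concatenate([parsed[lab][1] for lab in labels])
        g = np.concatenate([[lab] * len(parsed[lab][0]) for lab in labels])
        res = multivariate_logrank_test(t, g, e)
        df = len(labels) - 1
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=df,
        p_value=float(res.p_value),
        n_per_group={lab: len(parsed[lab][0]) for lab in labels},
    )
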