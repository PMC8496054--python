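"""Semiquantitative IHC scoring of tissue-microarray cores.

Each tumor contributes two cores per marker and compartment.  A core is
coded by a quantity (0 = none, 1 = <1% positive cells, 2 = 1-9%,
3 = 10-50%, 4 = >50%) and an intensity (0 = none, 1 = low, 2 = medium,
3 = strong); the core score is their product (range 0-12) and the tumor
score the arithmetic mean of the two cores.  Tumor scores are binned
into low/no (0-3), intermediate (3.5-7.5) and high (8-12) expression.

Positivity calls, the marker cross-tabulation (per-compartment rows,
columns for each marker, exactly-one-marker and both-markers) and the
Spearman associations with grade and other markers live here as well.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, spearman

__all__ = [
    "QUANTITY_CODES",
    "INTENSITY_CODES",
    "ACHIEVABLE_PRODUCTS",
    "ACHIEVABLE_MEANS",
    "core_score",
    "tumor_mean_score",
    "classify_score",
    "positivity_call",
    "score_cohort",
    "positivity_calls",
    "positivity_table",
    "positivity_table_from_counts",
    "correlate",
    "merge_high_grades",
]

QUANTITY_CODES = (0, 1, 2, 3, 4)
INTENSITY_CODES = (0, 1, 2, 3)

#: Products actually reachable from the code grids (5 is not, for instance).
ACHIEVABLE_PRODUCTS = frozenset(
    q * i for q in QUANTITY_CODES for i in INTENSITY_CODES
)

#: Two-core means reachable from achievable products (a half-step grid,
#: but with holes: e.g. 11.5 cannot occur).
ACHIEVABLE_MEANS = frozenset(
    (a + b) / 2 for a, b in itertools.product(sorted(ACHIEVABLE_PRODUCTS), repeat=2)
)

SCORE_CLASS_BINS = {"low": (0.0, 3.0), "intermediate": (3.5, 7.5), "high": (8.0, 12.0)}


def core_score(quantity: int, intensity: int, *, row: object | None = None) -> int:
    """Product score of one core; ``row`` names the source row in errors."""
    where = "" if row is None else f" (row {row})"
    if quantity not in QUANTITY_CODES:
        raise ValueError(f"quantity code {quantity!r} outside 0-4{where}")
    if intensity not in INTENSITY_CODES:
        raise ValueError(f"intensity code {intensity!r} outside 0-3{where}")
    return int(quantity) * int(intensity)


def tumor_mean_score(core_products) -> tuple[float, bool]:
    """Mean of the available core products.

    Returns ``(mean_score, single_core)``; a tumor with a single
    evaluable core keeps that core's score and is flagged rather than
    dropped.
    """
    products = [p for p in core_products if p is not None and not pd.isna(p)]
    if len(products) == 0:
        raise ValueError("no evaluable cores for tumor")
    if len(products) > 2:
        raise ValueError(f"expected at most two cores, got {len(products)}")
    for p in products:
        if p not in ACHIEVABLE_PRODUCTS:
            raise ValueError(f"core product {p!r} not an achievable score")
    return float(np.mean(products)), len(products) == 1


def classify_score(mean_score: float) -> str:
    """Bin an achievable mean score into low / intermediate / high."""
    if mean_score not in ACHIEVABLE_MEANS:
        raise ValueError(
            f"mean score {mean_score!r} is not achievable from two core products"
        )
    if mean_score <= 3.0:
        return "low"
    if 3.5 <= mean_score <= 7.5:
        return "intermediate"
    return "high"


def positivity_call(
    mean_score: float, threshold: float = 0.0, mode: str = "greater"
) -> bool:
    """Call a tumor positive from its mean score.

    The default (``> 0``) counts any staining as positive; ``mode`` can be
    ``"greater"`` or ``"at_least"`` and ``threshold`` any achievable value,
    so stricter criteria (e.g. at least intermediate) remain expressible.
    """
    if threshold not in ACHIEVABLE_MEANS:
        raise ValueError(f"threshold {threshold!r} not on the achievable score grid")
    if mode == "greater":
        return mean_score > threshold
    if mode == "at_least":
        return mean_score >= threshold
    raise ValueError(f"unknown mode: {mode!r}")


def score_cohort(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor scores from a long table of core observations.

    ``observations`` needs columns ``tumor_id, core_id, marker,
    compartment, quantity, intensity`` (``grade`` is carried through if
    present).  Returns one row per (tumor, marker, compartment) with the
    core products, mean score, class and single-core flag.
    """
    required = {"tumor_id", "core_id", "marker", "compartment", "quantity", "intensity"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")

    obs = observations.copy()
    obs["product"] = [
        core_score(int(q), int(i), row=idx)
        for idx, q, i in zip(obs.index, obs["quantity"], obs["intensity"])
    ]

    rows = []
    for (tumor, marker, compartment), grp in obs.groupby(
        ["tumor_id", "marker", "compartment"], sort=False
    ):
        if len(grp) > 2:
            raise ValueError(
                f"more than two cores for tumor {tumor!r}, {marker}/{compartment}"
            )
        mean, single = tumor_mean_score(list(grp["product"]))
        row = {
            "tumor_id": tumor,
            "marker": marker,
            "compartment": compartment,
            "core_1": grp["product"].iloc[0],
            "core_2": grp["product"].iloc[1] if len(grp) == 2 else np.nan,
            "mean_score": mean,
            "score_class": classify_score(mean),
            "single_core": single,
        }
        if "grade" in grp.columns:
            row["grade"] = grp["grade"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def positivity_calls(
    scores: pd.DataFrame, threshold: float = 0.0, mode: str = "greater"
) -> pd.DataFrame:
    """Add a boolean ``positive`` column to a per-tumor score table."""
    out = scores.copy()
    out["positive"] = [
        positivity_call(m, threshold=threshold, mode=mode) for m in out["mean_score"]
    ]
    return out


def _pct(count: int, n: int) -> float:
    return round(100.0 * count / n, 1)


@dataclass(frozen=True)
class PositivityTable:
    """Cross-tabulation of marker positivity by compartment.

    Rows: nuclear, cytoplasmic and their union ("nuclear or cytoplasmic"
    per marker).  Columns per row: counts and percentages for each
    marker, for exactly one of the two markers, and for both.
    """

    label: str
    n: int
    counts: pd.DataFrame
    percentages: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        merged = self.counts.copy().astype(object)
        for row in merged.index:
            for col in merged.columns:
                merged.loc[row, col] = (
                    f"{self.counts.loc[row, col]} ({self.percentages.loc[row, col]}%)"
                )
        return merged


_TABLE_ROWS = ("nuclear", "cytoplasmic", "nuclear_or_cytoplasmic")


def positivity_table_from_counts(
    marker_a: int,
    marker_b: int,
    both: int,
    n: int,
    *,
    row: str = "nuclear",
    label: str = "",
    names: tuple[str, str] = ("YAP", "TAZ"),
) -> dict[str, float]:
    """One cross-tabulation row from marginal counts.

    ``exactly_one = marker_a + marker_b - 2 * both`` (each marginal
    includes the doubly positive tumors once).  Percentages are
    ``100 * count / n`` rounded to one decimal.
    """
    if not (0 <= both <= min(marker_a, marker_b) <= max(marker_a, marker_b) <= n):
        raise ValueError("inconsistent marginal counts")
    exactly_one = marker_a + marker_b - 2 * both
    a, b = names
    return {
        "row": row,
        "label": label,
        "n": n,
        f"{a}_count": marker_a,
        f"{b}_count": marker_b,
        "exactly_one_count": exactly_one,
        "both_count": both,
        f"{a}_pct": _pct(marker_a, n),
        f"{b}_pct": _pct(marker_b, n),
        "exactly_one_pct": _pct(exactly_one, n),
        "both_pct": _pct(both, n),
    }


def positivity_table(
    calls: pd.DataFrame,
    label: str = "",
    markers: tuple[str, str] = ("YAP", "TAZ"),
) -> PositivityTable:
    """Cross-tabulate per-tumor positivity calls for two markers.

    ``calls`` is long-format with columns ``tumor_id, marker,
    compartment, positive`` covering both markers in both compartments
    for every tumor.  The third row is the per-marker union over
    compartments (positive in either), and the exactly-one column is the
    symmetric difference of the two marker sets.
    """
    required = {"tumor_id", "marker", "compartment", "positive"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls missing columns: {sorted(missing)}")
    dupes = calls.duplicated(subset=["tumor_id", "marker", "compartment"])
    if dupes.any():
        raise ValueError("duplicated (tumor, marker, compartment) calls")

    wide = calls.pivot(
        index="tumor_id", columns=["marker", "compartment"], values="positive"
    )
    for marker in markers:
        for compartment in ("nuclear", "cytoplasmic"):
            if (marker, compartment) not in wide.columns:
                raise ValueError(f"missing calls for {marker}/{compartment}")
    if wide.isna().any().any():
        raise ValueError("incomplete calls: every tumor needs all four calls")

    n = len(wide)
    a, b = markers
    flags = {}
    for row in _TABLE_ROWS:
        if row == "nuclear_or_cytoplasmic":
            fa = wide[(a, "nuclear")] | wide[(a, "cytoplasmic")]
            fb = wide[(b, "nuclear")] | wide[(b, "cytoplasmic")]
        else:
            fa = wide[(a, row)]
            fb = wide[(b, row)]
        flags[row] = (fa.astype(bool), fb.astype(bool))

    columns = [a, b, "exactly_one", "both"]
    counts = pd.DataFrame(index=list(_TABLE_ROWS), columns=columns, dtype=int)
    for row, (fa, fb) in flags.items():
        counts.loc[row, a] = int(fa.sum())
        counts.loc[row, b] = int(fb.sum())
        counts.loc[row, "both"] = int((fa & fb).sum())
        counts.loc[row, "exactly_one"] = int((fa ^ fb).sum())
    counts = counts.astype(int)
    pcts = counts.map(lambda c: _pct(int(c), n))
    return PositivityTable(label=label, n=n, counts=counts, percentages=pcts)


def correlate(x, y) -> TestResult:
    """Spearman association between two per-tumor variables."""
    return spearman(x, y)


def merge_high_grades(grades: pd.Series) -> pd.Series:
    """Collapse G4 into G3 (sparse G4 strata) for grade associations."""
    return grades.replace({"G4": "G3/G4", "G3": "G3/G4"})
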