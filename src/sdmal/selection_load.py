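"""Genetic-load comparisons: N/S ratios and TE insertion-density statistics.

Elevated nonsynonymous/synonymous (N/S) polymorphism ratios and excess
transposable-element (TE) insertions both indicate reduced efficacy of
purifying selection, expected for a low-frequency, low-recombination
supergene.  SNP effect classes and TE calls are consumed as annotation
tables; calling/annotation itself is upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

TE_COLUMNS = ["chrom", "start", "end", "family", "library"]


@dataclass(frozen=True)
class NSCounts:
    """Nonsynonymous and synonymous SNP counts for one panel and scope."""

    group: str
    N: int
    S: int
    scope: str = "all"  # all | private | shared

    def __post_init__(self) -> None:
        if self.N < 0 or self.S < 0:
            raise ConfigError("counts must be >= 0")
        if self.scope not in ("all", "private", "shared"):
            raise ConfigError(f"unknown scope {self.scope!r}")

    @property
    def ratio(self) -> float:
        if self.S == 0:
            raise DataError(f"{self.group}: N/S undefined with S = 0")
        return self.N / self.S


def ns_fold_change(a: NSCounts, b: NSCounts) -> tuple[float, float, float]:
    """(ratio_a, ratio_b, fold) with fold = (N_a/S_a)/(N_b/S_b)."""
    ra, rb = a.ratio, b.ratio
    if rb == 0:
        raise DataError(f"{b.group}: zero N/S ratio; fold change undefined")
    return ra, rb, ra / rb


def chisq_independence(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square of independence on a 2x2 table, no continuity
    correction, df = 1, upper-tail p."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ConfigError("need a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DataError("zero margin; test undefined")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def ns_table_report(pairs: Sequence[tuple[NSCounts, NSCounts]]) -> pd.DataFrame:
    """Tidy report of N/S ratios, fold changes and chi-square p per scope."""
    rows = []
    for a, b in pairs:
        ra, rb, fold = ns_fold_change(a, b)
        chi2, p = chisq_independence([[a.N, a.S], [b.N, b.S]])
        rows.append(
            {
                "scope": a.scope,
                "group_a": a.group, "N_a": a.N, "S_a": a.S, "ratio_a": ra,
                "group_b": b.group, "N_b": b.N, "S_b": b.S, "ratio_b": rb,
                "fold": fold, "chi2": chi2, "p": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TE windows and arm ratios
# ---------------------------------------------------------------------------


def load_te_table(path) -> pd.DataFrame:
    """Read TE insertion calls from a BED-like TSV with a library column."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"TE table missing columns {sorted(missing)}")
    return df


def te_window_counts(
    te: pd.DataFrame, window: int = 100_000, arms: Sequence[str] | None = None
) -> pd.DataFrame:
    """Insertion counts per (library, arm, window); windows tile each arm.

    Insertions are assigned to the window containing their start (1-based
    inclusive coordinates).
    """
    if window < 1:
        raise ConfigError("window must be positive")
    df = te if arms is None else te[te["chrom"].isin(arms)]
    if df.empty:
        raise DataError("no TE records in the requested arms")
    df = df.assign(window_start=((df["start"] - 1) // window) * window + 1)
    counts = (
        df.groupby(["library", "chrom", "window_start"])
        .size()
        .rename("n_te")
        .reset_index()
    )
    counts["window_end"] = counts["window_start"] + window - 1
    return counts[["library", "chrom", "window_start", "window_end", "n_te"]]


def te_arm_ratio(
    te: pd.DataFrame,
    euchromatin: Mapping[str, tuple[int, int]],
    num_arm: str = "2R",
    den_arm: str = "2L",
) -> pd.Series:
    """Per-library ratio of TE counts on two arms within euchromatic bounds."""
    for arm in (num_arm, den_arm):
        if arm not in euchromatin:
            raise ConfigError(f"no euchromatin bounds for {arm}")

    def arm_counts(arm: str) -> pd.Series:
        lo, hi = euchromatin[arm]
        sub = te[(te["chrom"] == arm) & (te["start"] >= lo) & (te["end"] <= hi)]
        return sub.groupby("library").size()

    num = arm_counts(num_arm)
    den = arm_counts(den_arm)
    libraries = sorted(set(te["library"]))
    out = {}
    for lib in libraries:
        d = den.get(lib, 0)
        if d == 0:
            raise DataError(f"library {lib}: zero TE count on {den_arm}")
        out[lib] = num.get(lib, 0) / d
    return pd.Series(out, name=f"{num_arm}/{den_arm}")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square-approximation p over >= 2 groups."""
    if len(groups) < 2:
        raise ConfigError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise DataError("empty group")
    flat = [x for g in groups for x in g]
    if len(set(flat)) == 1:
        return 0.0, 1.0  # all values tied: no rank variation
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
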