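"""Recombination-history analyses within a non-recombining arrangement.

Pairwise r^2 and its decay with distance, the Hudson-Kaplan lower bound on
the number of historical crossover events (four-gamete incompatibilities),
and the classification of SNPs as shared with a reference panel (candidate
gene-conversion tracts) vs private, with run statistics over the resulting
labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, EmptyResultError
from .hapio import MISSING, HaplotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairLD:
    """r^2 for one ordered SNP pair."""

    pos_i: int
    pos_j: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.pos_i >= self.pos_j:
            raise ValueError("pos_i must be < pos_j")

    @property
    def distance(self) -> int:
        return self.pos_j - self.pos_i


@dataclass(frozen=True)
class RunRecord:
    """A maximal stretch of same-label SNPs (shared or private)."""

    label: str
    start: int
    end: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def density_per_kb(self) -> float:
        """SNPs per kb; defined only for runs of positive length."""
        if self.length_bp == 0:
            raise DataError("density undefined for a zero-length run")
        return 1000.0 * self.n_snps / self.length_bp


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------


def pairwise_r2(
    m: HaplotypeMatrix,
    exclusions: Sequence[tuple[int, int]] = (),
    *,
    thin_per_kb: bool = False,
) -> list[PairLD]:
    """r^2 for every SNP pair, optionally dropping breakpoint-straddling pairs.

    Expects a matrix already filtered to biallelic, non-singleton, fully
    genotyped sites; r^2 is the squared Pearson correlation of the two 0/1
    haplotype vectors (identical to D^2/(p_A q_A p_B q_B) for haploids).
    A pair is dropped when its two positions straddle any exclusion
    interval (pos_i < start and pos_j > end).  ``thin_per_kb`` keeps at
    most one SNP per kb (the first) to bound the pair count on large
    panels.
    """
    if np.any(m.alleles == MISSING):
        raise ConfigError("pairwise_r2 requires fully genotyped sites")
    if thin_per_kb:
        keep = np.flatnonzero(np.diff(np.concatenate([[-10_000], m.positions // 1000])) != 0)
        m = m.take_sites(keep)
    if m.n_sites < 2:
        raise EmptyResultError("need >= 2 usable sites for pairwise LD")
    x = m.alleles.astype(float)
    x -= x.mean(axis=0)
    norm = np.sqrt((x**2).sum(axis=0))
    if np.any(norm == 0):
        raise ConfigError("monomorphic site present; filter to biallelic sites first")
    corr = (x.T @ x) / np.outer(norm, norm)
    r2 = corr**2
    pos = m.positions
    out: list[PairLD] = []
    for i in range(m.n_sites - 1):
        for j in range(i + 1, m.n_sites):
            if any(pos[i] < s and pos[j] > e for s, e in exclusions):
                continue
            out.append(PairLD(int(pos[i]), int(pos[j]), float(r2[i, j])))
    if not out:
        raise EmptyResultError("every SNP pair was excluded")
    return out


def mean_r2_by_distance(
    pairs: Sequence[PairLD], bin_width: int = 10_000
) -> pd.DataFrame:
    """Mean r^2 and pair count per distance bin [0,w), [w,2w), ...

    Empty bins up to the largest occupied one are emitted with count 0.
    """
    if not pairs:
        raise EmptyResultError("no pairs to bin")
    if bin_width < 1:
        raise ConfigError("bin_width must be positive")
    dist = np.array([p.distance for p in pairs])
    r2 = np.array([p.r_squared for p in pairs])
    idx = dist // bin_width
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=r2, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_width,
            "bin_end": (np.arange(n_bins) + 1) * bin_width,
            "mean_r2": means,
            "n_pairs": counts,
        }
    )


# ---------------------------------------------------------------------------
# minimum recombination events (Hudson-Kaplan)
# ---------------------------------------------------------------------------


def _incompatible_pairs(alleles: np.ndarray) -> np.ndarray:
    """Boolean S x S matrix: four-gamete failure for each site pair."""
    a = (alleles == 1).astype(np.int32)
    b = 1 - a
    n11 = a.T @ a
    n10 = a.T @ b
    n01 = b.T @ a
    n00 = b.T @ b
    return (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)


def min_recombination_events(m: HaplotypeMatrix) -> int:
    """Hudson-Kaplan lower bound Rm on historical crossover events.

    (1) four-gamete test on every site pair; (2) keep only minimal
    incompatible intervals (discard any containing another); (3) Rm is the
    maximum number of pairwise-disjoint intervals, found by the greedy
    earliest-right-endpoint scan.  Requires complete (no-missing) sites.
    """
    if np.any(m.alleles == MISSING):
        raise ConfigError("Rm requires fully genotyped sites")
    S = m.n_sites
    if S < 2:
        return 0
    inc = _incompatible_pairs(m.alleles)
    intervals = [(i, j) for i in range(S - 1) for j in range(i + 1, S) if inc[i, j]]
    if not intervals:
        return 0
    # minimal intervals: drop any (i, j) strictly containing another (i', j')
    minimal = [
        (i, j)
        for i, j in intervals
        if not any(
            (i2, j2) != (i, j) and i <= i2 and j2 <= j for i2, j2 in intervals
        )
    ]
    minimal.sort(key=lambda ij: ij[1])
    rm = 0
    last_right = -1
    for i, j in minimal:
        if i >= last_right:  # open intervals (i, j): touching endpoints are disjoint
            rm += 1
            last_right = j
    return rm


def events_per_generation(age_generations: float, rm: int) -> float:
    """Average generations per observed recombination event."""
    if rm < 1:
        raise DataError("no recombination event observed; interval undefined")
    return age_generations / rm


# ---------------------------------------------------------------------------
# shared/private classification and runs
# ---------------------------------------------------------------------------


def label_shared_private(
    sd: HaplotypeMatrix,
    panel: HaplotypeMatrix,
    *,
    alt_sd: Sequence[str] | None = None,
    alt_panel: Sequence[str] | None = None,
) -> np.ndarray:
    """Label each focal-panel SNP 'shared' or 'private' vs a reference panel.

    A focal SNP is shared iff the same position carries the derived allele
    in at least one reference haplotype; otherwise private.  When alternate
    alleles are supplied for both panels (joint genotyping not guaranteed),
    a nucleotide mismatch at a common position is flagged 'unassigned'.
    """
    labels = np.full(sd.n_sites, "private", dtype=object)
    panel_pos = {int(p): k for k, p in enumerate(panel.positions)}
    panel_derived = panel.derived_counts()
    for j, pos in enumerate(sd.positions):
        k = panel_pos.get(int(pos))
        if k is None:
            continue
        if alt_sd is not None and alt_panel is not None and alt_sd[j] != alt_panel[k]:
            labels[j] = "unassigned"
            logger.info("allele mismatch at %s:%d; flagged unassigned", sd.chrom, pos)
            continue
        if panel_derived[k] >= 1:
            labels[j] = "shared"
    return labels


def snp_runs(labels: Sequence[str], positions: Sequence[int]) -> list[RunRecord]:
    """Maximal same-label stretches of consecutive SNPs (5' to 3').

    Labels must be 'shared' or 'private'; positions strictly increasing.
    Single-SNP runs carry length 0.
    """
    labels = list(labels)
    positions = [int(p) for p in positions]
    if len(labels) != len(positions):
        raise ConfigError("labels and positions must align")
    if any(l not in ("shared", "private") for l in labels):
        raise ConfigError("labels must be 'shared' or 'private'")
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ConfigError("positions must be strictly increasing")
    runs: list[RunRecord] = []
    start_idx = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start_idx]:
            runs.append(
                RunRecord(
                    label=labels[start_idx],
                    start=positions[start_idx],
                    end=positions[k - 1],
                    n_snps=k - start_idx,
                )
            )
            start_idx = k
    return runs


def run_summary(runs: Sequence[RunRecord]) -> dict[str, dict[str, float]]:
    """Per-label run statistics.

    density_per_kb pools SNPs and span over runs of positive length;
    fractions below 1 kb / 10 kb and the longest run include every run
    (single-SNP runs have length 0).
    """
    out: dict[str, dict[str, float]] = {}
    for label in ("shared", "private"):
        sub = [r for r in runs if r.label == label]
        if not sub:
            continue
        lengths = np.array([r.length_bp for r in sub])
        long_runs = [r for r in sub if r.length_bp > 0]
        density = (
            1000.0 * sum(r.n_snps for r in long_runs) / sum(r.length_bp for r in long_runs)
            if long_runs
            else float("nan")
        )
        out[label] = {
            "n_runs": len(sub),
            "n_snps": int(sum(r.n_snps for r in sub)),
            "density_per_kb": density,
            "frac_lt_1kb": float(np.mean(lengths < 1_000)),
            "frac_lt_10kb": float(np.mean(lengths < 10_000)),
            "longest_bp": int(lengths.max()),
        }
    return out
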