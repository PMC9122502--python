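"""Windowed diversity, site-frequency-spectrum and differentiation statistics.

Implements the per-site and per-window estimators used to scan chromosome
arms: mean pairwise diversity (pi), Watterson's theta, Tajima's D and its
theoretical minimum, the haploid Weir-Cockerham (1984) F_ST variance-component
estimator, and between-panel divergence d_XY.  Missing calls are excluded
pairwise via per-site non-missing sample counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .hapio import GenomeWindow, HaplotypeMatrix, depth_callable_mask

#: fixed column order of the window-scan output table
WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_callable", "S",
    "pi_per_site", "theta_w", "D", "D_over_Dmin", "fst", "dxy",
]


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 normalising constants of Tajima's D for sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 4:
            raise ConfigError(f"Tajima's D requires n >= 4, got {n}")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class WindowStats:
    """Summary statistics for one genome window (two-panel fields optional)."""

    window: GenomeWindow
    S: int
    pi_sum: float
    pi_per_site: float
    theta_w: float
    D: float  # nan when undefined (S = 0)
    D_over_Dmin: float
    fst: float = math.nan
    dxy: float = math.nan
    low_coverage: bool = False


# ---------------------------------------------------------------------------
# per-site / per-region building blocks
# ---------------------------------------------------------------------------


def site_pi(derived_count: int, n_called: int) -> float:
    """Mean pairwise difference at one biallelic site.

    Equals 2*j*(n-j)/(n*(n-1)): the fraction of the n*(n-1)/2 sample pairs
    that differ, for j copies of the derived allele among n called samples.
    """
    if n_called < 2:
        raise DataError(f"site_pi undefined for n_called={n_called}")
    if not 0 <= derived_count <= n_called:
        raise DataError("derived_count outside [0, n_called]")
    j, n = derived_count, n_called
    return 2.0 * j * (n - j) / (n * (n - 1))


def matrix_pi_sum(m: HaplotypeMatrix) -> float:
    """Sum of per-site mean pairwise differences, missing excluded per site."""
    n = m.called_counts().astype(float)
    j = m.derived_counts().astype(float)
    ok = n >= 2
    n, j = n[ok], j[ok]
    return float(np.sum(2.0 * j * (n - j) / (n * (n - 1))))


def tajimas_D(S: int, pi_sum: float, n: int) -> float:
    """Tajima's D from segregating sites S and summed pairwise diversity.

    Returns nan (flagged undefined) when S = 0.
    """
    if S == 0:
        return math.nan
    c = TajimaConstants.from_n(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (pi_sum - S / c.a1) / math.sqrt(var)


def tajima_Dmin(S: int, n: int) -> float:
    """Theoretical minimum of D: the value when all S sites are singletons."""
    return tajimas_D(S, 2.0 * S / n, n)


# ---------------------------------------------------------------------------
# two-panel statistics
# ---------------------------------------------------------------------------


def _shared_site_freqs(a: HaplotypeMatrix, b: HaplotypeMatrix, window: GenomeWindow | None):
    """Align the two panels on shared positions (optionally within a window)."""
    if window is not None:
        a, b = a.in_window(window), b.in_window(window)
    pos, ia, ib = np.intersect1d(a.positions, b.positions, return_indices=True)
    na = a.called_counts()[ia].astype(float)
    nb = b.called_counts()[ib].astype(float)
    ja = a.derived_counts()[ia].astype(float)
    jb = b.derived_counts()[ib].astype(float)
    ok = (na >= 2) & (nb >= 2)
    return pos[ok], na[ok], nb[ok], ja[ok], jb[ok]


def weir_cockerham_fst(
    a: HaplotypeMatrix, b: HaplotypeMatrix, window: GenomeWindow | None = None
) -> float:
    """Haploid Weir-Cockerham (1984) F_ST for two panels over a window.

    Per site the between- and within-population variance components are
        MSP = sum_i n_i (p_i - pbar)^2 / (r - 1)
        MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1)
        n_c = (sum n_i - sum n_i^2 / sum n_i) / (r - 1)
    and the window estimate is the ratio of summed numerators to summed
    denominators (ratio of averages):
        F_ST = sum(MSP - MSG) / sum(MSP + (n_c - 1) MSG).
    The raw value is returned and may be negative (finite-sample correction);
    nan flags a window with no shared polymorphic site.
    """
    pos, na, nb, ja, jb = _shared_site_freqs(a, b, window)
    if len(pos) == 0:
        return math.nan
    pa, pb = ja / na, jb / nb
    poly = (ja + jb > 0) & (ja + jb < na + nb)
    if not poly.any():
        return math.nan
    na, nb, pa, pb = na[poly], nb[poly], pa[poly], pb[poly]
    ntot = na + nb
    pbar = (na * pa + nb * pb) / ntot
    msp = na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2  # r - 1 = 1
    msg = (na * pa * (1 - pa) + nb * pb * (1 - pb)) / (ntot - 2)
    n_c = ntot - (na**2 + nb**2) / ntot
    num = float(np.sum(msp - msg))
    den = float(np.sum(msp + (n_c - 1) * msg))
    if den == 0.0:
        return math.nan
    return num / den


def dxy(
    a: HaplotypeMatrix,
    b: HaplotypeMatrix,
    window: GenomeWindow | None = None,
    n_callable: int | None = None,
) -> float:
    """Mean between-panel pairwise difference per callable site.

    (1/n_callable) * sum_sites (1/(n_a n_b)) * #cross-panel mismatches; sites
    fixed identical in both panels contribute 0, so only shared variant
    positions need enumerating.  ``n_callable`` defaults to the window span.
    """
    if n_callable is None:
        if window is None:
            raise ConfigError("dxy needs a window or an explicit n_callable")
        n_callable = window.n_callable or window.span
    if n_callable == 0:
        return math.nan
    pos, na, nb, ja, jb = _shared_site_freqs(a, b, window)
    # cross-panel mismatches at a site: ja*(nb-jb) + (na-ja)*jb
    total = float(np.sum((ja * (nb - jb) + (na - ja) * jb) / (na * nb)))
    return total / n_callable


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowScheme:
    """Window layout: fixed coordinate width or equal callable-site count."""

    kind: str = "fixed"  # "fixed" | "equal_sites"
    width: int = 10_000
    sites_per_window: int = 100

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "equal_sites"):
            raise ConfigError(f"unknown window scheme {self.kind!r}")
        if self.kind == "fixed" and self.width < 1:
            raise ConfigError("window width must be positive")
        if self.kind == "equal_sites" and self.sites_per_window < 1:
            raise ConfigError("sites_per_window must be positive")


def _layout_windows(
    m: HaplotypeMatrix, scheme: WindowScheme, span: tuple[int, int] | None
) -> list[GenomeWindow]:
    lo, hi = span if span is not None else (1, int(m.positions[-1]))
    if scheme.kind == "fixed":
        out = []
        for start in range(lo, hi + 1, scheme.width):
            end = min(start + scheme.width - 1, hi)
            out.append(GenomeWindow(m.chrom, start, end, end - start + 1))
        return out
    # equal_sites: window edges at every sites_per_window-th retained site
    out = []
    pos = m.positions
    for k in range(0, len(pos), scheme.sites_per_window):
        chunk = pos[k : k + scheme.sites_per_window]
        start = lo if k == 0 else int(chunk[0])
        end = hi if k + scheme.sites_per_window >= len(pos) else int(pos[k + scheme.sites_per_window] - 1)
        out.append(GenomeWindow(m.chrom, start, end, end - start + 1))
    return out


def scan_windows(
    panel: HaplotypeMatrix,
    other: HaplotypeMatrix | None = None,
    scheme: WindowScheme = WindowScheme(),
    *,
    span: tuple[int, int] | None = None,
    min_depth: int | None = 8,
    depth_dialect: str = "per_sample",
    min_callable: int = 1,
) -> list[WindowStats]:
    """Scan one (or two) panels in windows, emitting one WindowStats each.

    With two panels, F_ST and d_XY are filled on shared positions.  Sites
    failing the depth filter are removed first; windows whose n_callable
    falls below ``min_callable`` are flagged ``low_coverage``.
    """
    if other is not None and other.chrom != panel.chrom:
        raise ConfigError(
            f"panels on different arms: {panel.chrom} vs {other.chrom}"
        )
    if min_depth is not None:
        keep = depth_callable_mask(panel, min_depth, depth_dialect)
        panel = panel.take_sites(np.flatnonzero(keep))
        if other is not None:
            keep_b = depth_callable_mask(other, min_depth, depth_dialect)
            other = other.take_sites(np.flatnonzero(keep_b))
    windows = _layout_windows(panel, scheme, span)
    out: list[WindowStats] = []
    for w in windows:
        sub = panel.in_window(w)
        seg = sub.is_segregating()
        S = int(seg.sum())
        pi_sum = matrix_pi_sum(sub)
        n = panel.n_samples
        D = tajimas_D(S, pi_sum, n) if S > 0 else math.nan
        dmin = tajima_Dmin(S, n) if S > 0 else math.nan
        theta_w = S / TajimaConstants.from_n(n).a1
        stats = WindowStats(
            window=w,
            S=S,
            pi_sum=pi_sum,
            pi_per_site=pi_sum / w.n_callable if w.n_callable else math.nan,
            theta_w=theta_w,
            D=D,
            D_over_Dmin=D / dmin if S > 0 else math.nan,
            low_coverage=w.n_callable < min_callable,
        )
        if other is not None:
            stats.fst = weir_cockerham_fst(panel, other, w)
            stats.dxy = dxy(panel, other, w)
        out.append(stats)
    return out


def windows_to_frame(stats: list[WindowStats]) -> pd.DataFrame:
    """Tidy window table with the fixed downstream column order."""
    rows = [
        {
            "chrom": s.window.chrom,
            "start": s.window.start,
            "end": s.window.end,
            "n_callable": s.window.n_callable,
            "S": s.S,
            "pi_per_site": s.pi_per_site,
            "theta_w": s.theta_w,
            "D": s.D,
            "D_over_Dmin": s.D_over_Dmin,
            "fst": s.fst,
            "dxy": s.dxy,
        }
        for s in stats
    ]
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)
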