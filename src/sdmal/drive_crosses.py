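"""Drive-cross genetics, two-locus linkage disequilibrium, and the
inversion-order block model.

Covers the experimental-genetics side of the analysis: Kosambi map
distances from recombinant counts, transmission-ratio (drive) statistics
with a viability correction estimated from female-transmission crosses,
two-locus LD between the driver and the inversion with its neutral decay,
the probability bound for an enhancer escaping a recombinant screen, and
sequential application of chromosomal inversions to derive the rearranged
block structure of a double-inverted arm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: D. melanogaster chromosome arm 2R length (release 6 assembly), bp
CHROM_2R_LENGTH = 25_286_936

#: the double inversion of the studied supergene, as sequential intervals on
#: the *current* arrangement: first the distal inversion on the reference
#: axis, then the proximal inversion on the once-inverted arrangement
IN2RMAL_SPEC: tuple[tuple[int, int], ...] = (
    (14_591_034, 18_774_475),
    (8_855_601, 15_616_195),
)


# ---------------------------------------------------------------------------
# map distances
# ---------------------------------------------------------------------------


def kosambi_distance(n_rec: int, n_total: int) -> float:
    """Kosambi-corrected genetic distance (cM) from recombinant counts.

    d = 25 * ln((1 + 2r)/(1 - 2r)) with r = n_rec / n_total; defined for
    r < 0.5 (the Kosambi map function diverges at free recombination).
    """
    if n_total <= 0 or n_rec < 0:
        raise ConfigError("counts must satisfy n_total > 0, n_rec >= 0")
    r = n_rec / n_total
    if r >= 0.5:
        raise ConfigError(f"recombination fraction {r:.3f} outside Kosambi domain [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_to_r(d_cm: float) -> float:
    """Inverse Kosambi map: recombination fraction from distance in cM."""
    if d_cm < 0:
        raise ConfigError("distance must be >= 0")
    return 0.5 * math.tanh(d_cm / 50.0)


def percent_reduction(d_control: float, d_test: float) -> float:
    """Percent reduction of a test map distance relative to a control."""
    if d_control <= 0:
        raise ConfigError("control distance must be > 0")
    return 100.0 * (1.0 - d_test / d_control)


# ---------------------------------------------------------------------------
# drive statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossCount:
    """Progeny of one cross, split into focal-chromosome vs tester classes.

    ``n_focal`` counts progeny inheriting the focal (driving/recombinant)
    chromosome; ``n_tester`` the homozygous-tester class.  ``parent_sex``
    is the transmitting parent ('male' crosses measure drive; 'female'
    crosses measure viability only, since drive is male-specific).
    """

    cross_id: str
    n_focal: int
    n_tester: int
    parent_sex: str = "male"

    def __post_init__(self) -> None:
        if self.n_focal < 0 or self.n_tester < 0:
            raise ConfigError("progeny counts must be >= 0")
        if self.parent_sex not in ("male", "female"):
            raise ConfigError("parent_sex must be 'male' or 'female'")

    @property
    def total(self) -> int:
        return self.n_focal + self.n_tester

    @property
    def k(self) -> float:
        if self.total == 0:
            raise DataError(f"cross {self.cross_id}: zero scored progeny")
        return self.n_focal / self.total


@dataclass
class DriveEstimate:
    """Transmission-ratio summary across crosses.

    k is the mean per-cross proportion inheriting the focal chromosome;
    k_star corrects k with the viability weight w = n_focal/n_tester pooled
    over female-transmission crosses: k* = n_focal/(w*n_tester + n_focal).
    """

    k: float
    se_k: float
    w: float
    k_star: float
    se_kstar: float
    p_vs_half: float
    n_crosses: int


def viability_weight(female_crosses: Sequence[CrossCount]) -> float:
    """Pooled viability weight w from female-transmission crosses."""
    focal = sum(c.n_focal for c in female_crosses)
    tester = sum(c.n_tester for c in female_crosses)
    if tester == 0:
        raise DataError("no tester progeny in female crosses; w undefined")
    w = focal / tester
    if w == 0:
        raise DataError("viability weight w = 0; focal class never survives")
    return w


def drive_estimates(
    crosses: Sequence[CrossCount],
    female_control_crosses: Sequence[CrossCount] | None = None,
    w: float | None = None,
) -> DriveEstimate:
    """k and viability-corrected k* averaged over male-transmission crosses.

    The viability weight may be given directly or estimated from pooled
    female crosses; crosses with zero scored progeny are excluded with a
    log entry.  p_vs_half is a two-sided one-sample t-test of per-cross
    k* against the Mendelian expectation 0.5.
    """
    if w is None:
        if not female_control_crosses:
            raise ConfigError("need either w or female_control_crosses")
        w = viability_weight(female_control_crosses)
    usable = []
    for c in crosses:
        if c.total == 0:
            logger.info("excluding cross %s: zero scored progeny", c.cross_id)
            continue
        usable.append(c)
    if not usable:
        raise DataError("no usable male-transmission crosses")
    k_i = np.array([c.k for c in usable])
    kstar_i = np.array([c.n_focal / (w * c.n_tester + c.n_focal) for c in usable])
    m = len(usable)

    def se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / math.sqrt(m)) if m > 1 else math.nan

    if m > 1:
        p = float(stats.ttest_1samp(kstar_i, 0.5).pvalue)
    else:
        p = math.nan
    return DriveEstimate(
        k=float(k_i.mean()),
        se_k=se(k_i),
        w=w,
        k_star=float(kstar_i.mean()),
        se_kstar=se(kstar_i),
        p_vs_half=p,
        n_crosses=m,
    )


# ---------------------------------------------------------------------------
# two-locus LD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoLocusCounts:
    """2x2 haplotype counts for loci A and B (uppercase = focal allele)."""

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int

    def __post_init__(self) -> None:
        if min(self.n_AB, self.n_Ab, self.n_aB, self.n_ab) < 0:
            raise ConfigError("haplotype counts must be >= 0")
        if self.total < 2:
            raise ConfigError("need at least 2 haplotypes")

    @property
    def total(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab

    @property
    def p_A(self) -> float:
        return (self.n_AB + self.n_Ab) / self.total

    @property
    def p_B(self) -> float:
        return (self.n_AB + self.n_aB) / self.total


def ld_from_counts(c: TwoLocusCounts) -> tuple[float, float]:
    """(D, r^2) from 2x2 haplotype counts.

    D = p_AB - p_A*p_B; r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)).  Requires both
    loci polymorphic in the counts.
    """
    p_a, p_b = c.p_A, c.p_B
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise DataError("LD undefined: a locus is monomorphic in the counts")
    D = c.n_AB / c.total - p_a * p_b
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return D, r2


def ld_decay(D0: float, r: float, t: float) -> float:
    """Expected LD after t generations of recombination at fraction r."""
    if not 0 < r < 1:
        raise ConfigError("recombination fraction must lie in (0, 1)")
    if t < 0:
        raise ConfigError("t must be >= 0")
    return D0 * (1.0 - r) ** t


def ld_half_life(r: float) -> int:
    """Smallest integer generation count t with (1-r)^t <= 1/2."""
    if not 0 < r < 1:
        raise ConfigError("recombination fraction must lie in (0, 1)")
    return int(math.ceil(math.log(0.5) / math.log(1.0 - r)))


def fisher_exact_two_sided(c: TwoLocusCounts) -> float:
    """Two-sided Fisher exact p for the 2x2 haplotype table.

    Sums hypergeometric probabilities of all tables (margins fixed) whose
    probability does not exceed the observed table's.
    """
    _, p = stats.fisher_exact(
        [[c.n_AB, c.n_Ab], [c.n_aB, c.n_ab]], alternative="two-sided"
    )
    return float(p)


def enhancer_escape_probability(n_recombinants: int) -> float:
    """P(no crossover separates a uniformly placed enhancer in n recombinants).

    With crossover points and the enhancer position independently uniform on
    the interval, P = integral_0^1 (1-u)^n du = 1/(n+1).
    """
    if n_recombinants < 0:
        raise ConfigError("n_recombinants must be >= 0")
    return 1.0 / (n_recombinants + 1)


# ---------------------------------------------------------------------------
# inversion block model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    """A maximal run of reference sequence in one orientation."""

    ref_start: int
    ref_end: int
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise ValueError("ref_start > ref_end")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1

    def flipped(self) -> "Block":
        orient = "reverse" if self.orientation == "forward" else "forward"
        return Block(self.ref_start, self.ref_end, orient)

    def split(self, k: int) -> tuple["Block", "Block"]:
        """Split after k leading bases in the *current* orientation."""
        if not 0 < k < self.length:
            raise ValueError("split point outside block")
        if self.orientation == "forward":
            return (
                Block(self.ref_start, self.ref_start + k - 1, "forward"),
                Block(self.ref_start + k, self.ref_end, "forward"),
            )
        return (
            Block(self.ref_end - k + 1, self.ref_end, "reverse"),
            Block(self.ref_start, self.ref_end - k, "reverse"),
        )


@dataclass
class BlockArrangement:
    """Ordered blocks tiling a chromosome relative to the reference."""

    length: int
    blocks: list[Block]

    def __post_init__(self) -> None:
        if sum(b.length for b in self.blocks) != self.length:
            raise DataError("blocks do not tile the chromosome")

    @classmethod
    def identity(cls, length: int) -> "BlockArrangement":
        return cls(length, [Block(1, length, "forward")])

    def is_identity(self) -> bool:
        return self.blocks == [Block(1, self.length, "forward")]

    def _merged(self, blocks: list[Block]) -> list[Block]:
        out: list[Block] = []
        for b in blocks:
            if out:
                a = out[-1]
                if (
                    a.orientation == b.orientation == "forward"
                    and b.ref_start == a.ref_end + 1
                ):
                    out[-1] = Block(a.ref_start, b.ref_end, "forward")
                    continue
                if (
                    a.orientation == b.orientation == "reverse"
                    and b.ref_end == a.ref_start - 1
                ):
                    out[-1] = Block(b.ref_start, a.ref_end, "reverse")
                    continue
            out.append(b)
        return out

    def invert(self, start: int, end: int) -> "BlockArrangement":
        """Invert the current-coordinate interval [start, end] (1-based incl.)."""
        if not 1 <= start <= end <= self.length:
            raise ConfigError(
                f"inversion [{start}, {end}] outside chromosome of length {self.length}"
            )
        before: list[Block] = []
        middle: list[Block] = []
        after: list[Block] = []
        cur = 1  # current coordinate of the next block's first base
        for b in self.blocks:
            b_start, b_end = cur, cur + b.length - 1
            cur = b_end + 1
            pieces = [(b_start, b)]
            # split off the part left of `start`
            refined: list[tuple[int, Block]] = []
            for s, blk in pieces:
                e = s + blk.length - 1
                if s < start <= e:
                    left, right = blk.split(start - s)
                    refined += [(s, left), (start, right)]
                else:
                    refined.append((s, blk))
            pieces, refined = refined, []
            for s, blk in pieces:
                e = s + blk.length - 1
                if s <= end < e:
                    left, right = blk.split(end - s + 1)
                    refined += [(s, left), (end + 1, right)]
                else:
                    refined.append((s, blk))
            for s, blk in refined:
                e = s + blk.length - 1
                if e < start:
                    before.append(blk)
                elif s > end:
                    after.append(blk)
                else:
                    middle.append(blk)
        inverted = [blk.flipped() for blk in reversed(middle)]
        return BlockArrangement(
            self.length, self._merged(before + inverted + after)
        )

    def current_offsets(self) -> list[int]:
        """Current-coordinate start of each block."""
        out, cur = [], 1
        for b in self.blocks:
            out.append(cur)
            cur += b.length
        return out

    def rearranged_blocks(self) -> list[Block]:
        """Blocks that are inverted or displaced relative to the reference."""
        out = []
        for offset, b in zip(self.current_offsets(), self.blocks):
            if b.orientation == "reverse" or offset != b.ref_start:
                out.append(b)
        return out


def apply_inversions(
    chrom_length: int, spec: Sequence[tuple[int, int]]
) -> BlockArrangement:
    """Apply inversions sequentially; each interval is read on the
    arrangement existing at its turn.  Returns the minimal block
    decomposition relative to the reference."""
    arr = BlockArrangement.identity(chrom_length)
    for start, end in spec:
        arr = arr.invert(start, end)
    return arr
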