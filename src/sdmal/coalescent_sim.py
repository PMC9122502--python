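"""Hudson-style coalescent simulator with fixed-S infinite-sites mutations.

Three demographic histories are supported, all in ``ms`` time units of
4*N_e generations (so with k lineages the coalescence rate is k*(k-1) and
the expected pairwise TMRCA is 0.5):

``constant``
    Standard neutral coalescent in a constant-size population.
``growth``
    Exponential growth at rate alpha per 4*N_e generations; backward in
    time the population shrinks as exp(-alpha*t), so the coalescence
    hazard grows as exp(alpha*t) and waiting times come from inverting the
    cumulative hazard in closed form.
``sweep``
    Absolute bottleneck to a single chromosome at time t_sweep: the
    constant-rate process runs until t_sweep, then every surviving lineage
    is merged into one (multifurcating) ancestor at exactly t_sweep.  This
    models a hard sweep in which all sampled haplotypes descend from a
    single chromosome at the sweep onset.

Mutations are placed conditional on a fixed number of segregating sites S
(``ms -s`` semantics): S mutations are assigned to branches multinomially
with probability proportional to branch length; only branches subtending
1..n-1 tips carry polymorphism.

Two code paths compute replicate summaries: an explicit per-tree simulator
(:func:`simulate_genealogy` / :func:`place_mutations_fixed_S`) and a
vectorized batch kernel (:func:`batch_summaries`) that tracks only the
block-size partition of the sample through coalescence levels.  Both sample
the same process; the batch path exists because rejection-sampling ABC
needs millions of replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .hapio import HaplotypeMatrix
from .popgen_windows import TajimaConstants


@dataclass(frozen=True)
class DemographicModel:
    """Demographic history: constant size, exponential growth, or hard sweep."""

    kind: str = "constant"
    t_sweep: float | None = None  # sweep onset, units of 4*N_e generations
    alpha: float = 0.26  # growth rate per 4*N_e generations

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sweep", "growth"):
            raise ConfigError(f"unknown demographic model {self.kind!r}")
        if self.kind == "sweep":
            if self.t_sweep is None or self.t_sweep <= 0:
                raise ConfigError("sweep model requires t_sweep > 0")
        if self.kind == "growth" and self.alpha < 0:
            raise ConfigError("growth rate alpha must be >= 0")

    @classmethod
    def sweep(cls, t_sweep: float) -> "DemographicModel":
        return cls(kind="sweep", t_sweep=t_sweep)

    @classmethod
    def growth(cls, alpha: float = 0.26) -> "DemographicModel":
        return cls(kind="growth", alpha=alpha)


@dataclass
class CoalescentTree:
    """Genealogy as parent pointers with node times in 4*N_e generations.

    Nodes 0..n-1 are tips at time 0; internal nodes are appended in
    coalescence order, so ``times`` is non-decreasing over the internal
    range.  The root has parent -1.  A sweep genealogy may end in a single
    multifurcating root at exactly t_sweep.
    """

    n: int
    times: np.ndarray
    parent: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        if (self.parent == -1).sum() != 1:
            raise DataError("tree must have exactly one root")

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def root_time(self) -> float:
        return float(self.times[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        non_root = self.parent >= 0
        out[non_root] = self.times[self.parent[non_root]] - self.times[non_root]
        return out

    def tip_counts(self) -> np.ndarray:
        """Number of descendant tips per node (1 for tips)."""
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        counts[: self.n] = 1
        # nodes are created in time order, so a single ascending pass works
        for node in range(self.n_nodes):
            p = self.parent[node]
            if p >= 0:
                counts[p] += counts[node]
        return counts

    def descendant_tips(self) -> list[np.ndarray]:
        """Tip index sets per node."""
        sets: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for tip in range(self.n):
            sets[tip] = [tip]
        for node in range(self.n_nodes):
            p = self.parent[node]
            if p >= 0:
                sets[p].extend(sets[node])
        return [np.asarray(sorted(s), dtype=np.int64) for s in sets]

    def total_polymorphic_length(self) -> float:
        """Summed length of branches subtending 1..n-1 tips."""
        lens = self.branch_lengths()
        j = self.tip_counts()
        keep = (j >= 1) & (j <= self.n - 1)
        return float(lens[keep].sum())


@dataclass(frozen=True)
class SimConfig:
    """One simulation setting: sample size, fixed S, demography, region."""

    n: int = 9
    S: int = 100
    model: DemographicModel = field(default_factory=DemographicModel)
    region_length: int = 9_920_000  # bp available for SNP positions
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("n must be >= 2")
        if self.S < 0:
            raise ConfigError("S must be >= 0")
        if self.region_length < self.S:
            raise ConfigError("region_length must be >= S (infinite sites)")


# ---------------------------------------------------------------------------
# per-tree simulation
# ---------------------------------------------------------------------------


def _growth_wait(e: float, rate: float, t0: float, alpha: float) -> float:
    """Invert the cumulative hazard rate*(e^{a(t0+T)} - e^{a t0})/a = e."""
    if alpha == 0.0:
        return e / rate
    return float(np.log(np.exp(alpha * t0) + alpha * e / rate) / alpha - t0)


def simulate_genealogy(
    n: int, model: DemographicModel, rng: np.random.Generator
) -> CoalescentTree:
    """Simulate one genealogy for n tips under the given demography."""
    if n < 2:
        raise ConfigError("n must be >= 2")
    times = [0.0] * n
    parent = [-1] * n
    active = list(range(n))
    t = 0.0
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1)
        e = rng.exponential(1.0)
        if model.kind == "growth":
            wait = _growth_wait(e, rate, t, model.alpha)
        else:
            wait = e / rate
        if model.kind == "sweep" and t + wait >= model.t_sweep:
            # absolute bottleneck: all survivors merge at exactly t_sweep
            node = len(times)
            times.append(model.t_sweep)
            parent.append(-1)
            for lin in active:
                parent[lin] = node
            active = [node]
            break
        t += wait
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        node = len(times)
        times.append(t)
        parent.append(-1)
        parent[active[i]] = node
        parent[active[j]] = node
        # replace the pair by the new node, preserving list compactness
        hi, lo = max(i, j), min(i, j)
        active[lo] = node
        active[hi] = active[-1]
        active.pop()
    return CoalescentTree(n=n, times=np.asarray(times), parent=np.asarray(parent))


def place_mutations_fixed_S(
    tree: CoalescentTree,
    S: int,
    region_length: int,
    rng: np.random.Generator,
    *,
    chrom: str = "sim",
    group: str = "sim",
) -> HaplotypeMatrix:
    """Drop exactly S infinite-sites mutations onto the genealogy.

    Mutations go to polymorphism-capable branches (1..n-1 descendant tips)
    multinomially by branch length; positions are uniform without
    replacement on [1, region_length].
    """
    samples = [f"hap{i + 1}" for i in range(tree.n)]
    if S == 0:
        return HaplotypeMatrix(
            chrom=chrom,
            positions=np.empty(0, dtype=np.int64),
            samples=samples,
            alleles=np.zeros((tree.n, 0), dtype=np.int8),
            group=group,
        )
    lens = tree.branch_lengths()
    j = tree.tip_counts()
    ok = (j >= 1) & (j <= tree.n - 1)
    lens = np.where(ok, lens, 0.0)
    total = lens.sum()
    if total <= 0:
        raise DataError("degenerate tree: zero polymorphic branch length")
    counts = rng.multinomial(S, lens / total)
    branch_of_site = np.repeat(np.arange(tree.n_nodes), counts)
    rng.shuffle(branch_of_site)
    positions = np.sort(rng.choice(region_length, size=S, replace=False)) + 1
    tipsets = tree.descendant_tips()
    alleles = np.zeros((tree.n, S), dtype=np.int8)
    for col, branch in enumerate(branch_of_site):
        alleles[tipsets[branch], col] = 1
    return HaplotypeMatrix(
        chrom=chrom,
        positions=positions,
        samples=samples,
        alleles=alleles,
        group=group,
    )


# ---------------------------------------------------------------------------
# batch kernel
# ---------------------------------------------------------------------------


def batch_summaries(
    n: int,
    model: DemographicModel,
    S: int,
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(pi_sum, D) for `reps` independent fixed-S replicates, vectorized.

    Tracks, for each replicate, the coalescent waiting time at every lineage
    level k = n..2 and the block-size partition of the sample (which blocks
    of tips each lineage subtends).  A mutation landing on a lineage at
    level k is carried by all tips of its block, so the S mutations are
    multinomial over (level, block) segments with probability proportional
    to segment length, and pi follows from the block sizes alone -- no
    explicit tree is built.  Sweep truncation clips segment lengths at
    t_sweep (lineages surviving to t_sweep join the root there; the branch
    above the root carries no polymorphism).
    """
    if S < 1:
        raise ConfigError("batch_summaries requires S >= 1")
    levels = np.arange(n, 1, -1)  # k = n, n-1, ..., 2
    rates = (levels * (levels - 1)).astype(float)
    e = rng.exponential(1.0, size=(reps, n - 1))
    if model.kind == "growth" and model.alpha > 0:
        a = model.alpha
        starts = np.zeros((reps, n - 1))
        t0 = np.zeros(reps)
        waits = np.empty((reps, n - 1))
        for lv in range(n - 1):
            starts[:, lv] = t0
            w = np.log(np.exp(a * t0) + a * e[:, lv] / rates[lv]) / a - t0
            waits[:, lv] = w
            t0 = t0 + w
        ends = starts + waits
    else:
        waits = e / rates
        ends = np.cumsum(waits, axis=1)
        starts = ends - waits
    if model.kind == "sweep":
        ts = model.t_sweep
        seg_len = np.clip(np.minimum(ends, ts) - np.minimum(starts, ts), 0.0, None)
    else:
        seg_len = waits

    # evolve the block-size partition; record sizes at every level
    sizes = np.ones((reps, n), dtype=np.int64)
    rows = np.arange(reps)
    n_seg = n * (n + 1) // 2 - 1
    seg_sizes = np.empty((reps, n_seg), dtype=np.int64)
    seg_prob = np.empty((reps, n_seg))
    col = 0
    for lv, k in enumerate(levels):  # partition state while k lineages exist
        seg_sizes[:, col : col + k] = sizes[:, :k]
        seg_prob[:, col : col + k] = seg_len[:, lv][:, None]
        col += k
        # merge a uniformly chosen pair to reach k-1 lineages
        i1 = rng.integers(0, k, size=reps)
        i2 = rng.integers(0, k - 1, size=reps)
        i2 = i2 + (i2 >= i1)
        sizes[rows, i1] += sizes[rows, i2]
        sizes[rows, i2] = sizes[rows, k - 1]

    seg_prob /= seg_prob.sum(axis=1, keepdims=True)
    counts = rng.multinomial(S, seg_prob)
    h = 2.0 * seg_sizes * (n - seg_sizes) / (n * (n - 1))
    pi = (counts * h).sum(axis=1)
    c = TajimaConstants.from_n(n)
    denom = np.sqrt(c.e1 * S + c.e2 * S * (S - 1))
    D = (pi - S / c.a1) / denom
    return pi, D


# ---------------------------------------------------------------------------
# replicate summaries (per-tree path)
# ---------------------------------------------------------------------------


@dataclass
class ReplicateSummaries:
    """Per-replicate (pi_sum, D) and their means for one SimConfig."""

    pi_sum: np.ndarray
    D: np.ndarray

    @property
    def mean_pi(self) -> float:
        return float(np.mean(self.pi_sum))

    @property
    def mean_D(self) -> float:
        """Mean over defined (S > 0) replicates; nan if none defined."""
        ok = ~np.isnan(self.D)
        return float(np.mean(self.D[ok])) if ok.any() else float("nan")


def summarise_replicates(
    config: SimConfig, reps: int, rng: np.random.Generator | None = None
) -> ReplicateSummaries:
    """Simulate `reps` genealogies under `config` and summarise each.

    Uses the per-tree simulator; mutation placement collapses to per-branch
    multinomial counts (positions are irrelevant to pi and D).
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    c = TajimaConstants.from_n(n) if n >= 4 else None
    pi_out = np.empty(reps)
    d_out = np.full(reps, np.nan)
    for r in range(reps):
        tree = simulate_genealogy(n, config.model, rng)
        if config.S == 0:
            pi_out[r] = 0.0
            continue
        lens = tree.branch_lengths()
        j = tree.tip_counts()
        ok = (j >= 1) & (j <= n - 1)
        lens = np.where(ok, lens, 0.0)
        counts = rng.multinomial(config.S, lens / lens.sum())
        pi_out[r] = float(np.sum(counts * 2.0 * j * (n - j) / (n * (n - 1))))
        if c is not None:
            denom = np.sqrt(c.e1 * config.S + c.e2 * config.S * (config.S - 1))
            d_out[r] = (pi_out[r] - config.S / c.a1) / denom
    return ReplicateSummaries(pi_sum=pi_out, D=d_out)
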