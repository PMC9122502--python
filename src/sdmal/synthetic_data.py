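"""Synthetic-data generators for every input the pipeline consumes.

The generators reproduce the statistical structure the analyses assume:
coalescent haplotype panels (neutral, exponential growth, hard sweep),
gene-conversion tracts copied from a donor panel into a recipient panel,
multinomial drive-cross progeny counts, and a clean two-population split
for differentiation statistics.  Defaults mirror the study conditions:
panels of n = 9 haplotypes over a ~9.92 Mb non-recombining region, tract
lengths geometric with mean 1 kb, cross sizes in the hundreds of progeny.
Every file fixture embeds its generating seed and parameters in its header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .coalescent_sim import (
    CoalescentTree,
    SimConfig,
    place_mutations_fixed_S,
    simulate_genealogy,
)
from .errors import ConfigError
from .hapio import HaplotypeMatrix, write_haplotype_vcf


@dataclass(frozen=True)
class ConversionTractTruth:
    """Ground truth for one injected gene-conversion tract."""

    sample: str
    start: int
    end: int
    donor_haplotype: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("tract start > end")


# ---------------------------------------------------------------------------
# coalescent panels
# ---------------------------------------------------------------------------


def gen_panel(
    config: SimConfig,
    reps: int = 1,
    out_dir: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> list[HaplotypeMatrix]:
    """Generate seeded haplotype-panel fixtures (optionally written as VCF).

    One matrix per replicate; files (when ``out_dir`` is given) are named
    ``panel_<kind>_rep<k>.vcf`` and embed seed and parameters in their
    headers for provenance.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: list[HaplotypeMatrix] = []
    for k in range(reps):
        tree = simulate_genealogy(config.n, config.model, rng)
        m = place_mutations_fixed_S(
            tree, config.S, config.region_length, rng, group=config.model.kind
        )
        out.append(m)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            meta = {
                "seed": config.seed,
                "model": config.model.kind,
                "t_sweep": config.model.t_sweep,
                "alpha": config.model.alpha,
                "n": config.n,
                "S": config.S,
                "region_length": config.region_length,
                "replicate": k,
            }
            write_haplotype_vcf(
                m, out_dir / f"panel_{config.model.kind}_rep{k}.vcf", meta=meta
            )
    return out


# ---------------------------------------------------------------------------
# gene-conversion tracts
# ---------------------------------------------------------------------------


def align_union(a: HaplotypeMatrix, b: HaplotypeMatrix) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Expand two panels onto the union of their positions (0-filled).

    Positions absent from one panel are ancestral (0) there, mimicking
    joint genotyping of the two panels against a common reference.
    """
    union = np.union1d(a.positions, b.positions)

    def expand(m: HaplotypeMatrix) -> HaplotypeMatrix:
        alleles = np.zeros((m.n_samples, len(union)), dtype=np.int8)
        idx = np.searchsorted(union, m.positions)
        alleles[:, idx] = m.alleles
        return HaplotypeMatrix(
            chrom=m.chrom, positions=union, samples=list(m.samples),
            alleles=alleles, group=m.group,
        )

    return expand(a), expand(b)


def inject_conversion_tracts(
    recipient: HaplotypeMatrix,
    donor: HaplotypeMatrix,
    tracts_per_sample: float,
    mean_tract_bp: float,
    region_length: int,
    rng: np.random.Generator,
) -> tuple[HaplotypeMatrix, list[ConversionTractTruth]]:
    """Copy random donor tracts into recipient haplotypes.

    Per recipient haplotype the tract count is Poisson(``tracts_per_sample``)
    and each tract length is geometric with the given mean (memoryless, the
    standard model for conversion tracts); tract starts are uniform.
    Overlapping tracts within one recipient are redrawn (up to 100 tries),
    then skipped.  Requires both panels on identical positions (see
    :func:`align_union`).
    """
    if mean_tract_bp < 1:
        raise ConfigError("mean tract length must be >= 1 bp")
    if not np.array_equal(recipient.positions, donor.positions):
        raise ConfigError("recipient and donor must share positions (align_union)")
    alleles = recipient.alleles.copy()
    truth: list[ConversionTractTruth] = []
    pos = recipient.positions
    for i, sample in enumerate(recipient.samples):
        n_tracts = rng.poisson(tracts_per_sample)
        placed: list[tuple[int, int]] = []
        for _ in range(n_tracts):
            for _attempt in range(100):
                length = int(rng.geometric(1.0 / mean_tract_bp))
                start = int(rng.integers(1, max(region_length - length, 1) + 1))
                end = min(start + length - 1, region_length)
                if all(end < s or start > e for s, e in placed):
                    break
            else:
                continue
            placed.append((start, end))
            donor_idx = int(rng.integers(donor.n_samples))
            cols = np.flatnonzero((pos >= start) & (pos <= end))
            alleles[i, cols] = donor.alleles[donor_idx, cols]
            truth.append(
                ConversionTractTruth(sample, start, end, donor.samples[donor_idx])
            )
    out = HaplotypeMatrix(
        chrom=recipient.chrom, positions=pos.copy(), samples=list(recipient.samples),
        alleles=alleles, group=recipient.group,
    )
    return out, truth


# ---------------------------------------------------------------------------
# drive-cross fixtures
# ---------------------------------------------------------------------------

CROSS_CLASSES = ("focal_par", "focal_rec", "tester_par", "tester_rec")


@dataclass(frozen=True)
class CrossFixture:
    """Progeny counts of one simulated cross, by transmission class."""

    cross_id: str
    counts: Mapping[str, int]
    parent_sex: str = "male"

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_recombinant(self) -> int:
        return self.counts["focal_rec"] + self.counts["tester_rec"]

    @property
    def n_focal(self) -> int:
        return self.counts["focal_par"] + self.counts["focal_rec"]

    @property
    def n_tester(self) -> int:
        return self.counts["tester_par"] + self.counts["tester_rec"]


def gen_cross_counts(
    n_progeny: int,
    r: float,
    k: float,
    n_crosses: int,
    rng: np.random.Generator,
    viabilities: Mapping[str, float] | None = None,
    parent_sex: str = "male",
) -> list[CrossFixture]:
    """Multinomial progeny counts under drive k, recombination r, viability.

    Transmission probabilities before viability: focal gametes with
    probability k (parental 1-r, recombinant r), tester with 1-k likewise;
    per-class viability weights multiply and the vector is renormalized.
    """
    if not (0 <= r < 1 and 0 <= k <= 1):
        raise ConfigError("need 0 <= r < 1 and 0 <= k <= 1")
    if n_progeny < 1 or n_crosses < 1:
        raise ConfigError("n_progeny and n_crosses must be >= 1")
    v = {c: 1.0 for c in CROSS_CLASSES}
    v.update(viabilities or {})
    probs = np.array(
        [k * (1 - r) * v["focal_par"], k * r * v["focal_rec"],
         (1 - k) * (1 - r) * v["tester_par"], (1 - k) * r * v["tester_rec"]]
    )
    total = probs.sum()
    assert total > 0, "viability weighting removed all probability mass"
    probs = probs / total
    out = []
    for c in range(n_crosses):
        draws = rng.multinomial(n_progeny, probs)
        out.append(
            CrossFixture(
                cross_id=f"cross{c + 1}",
                counts=dict(zip(CROSS_CLASSES, (int(x) for x in draws))),
                parent_sex=parent_sex,
            )
        )
    return out


def pooled_recombinants(crosses: Sequence[CrossFixture]) -> tuple[int, int]:
    """(n_recombinant, n_total) pooled over crosses, for map distances."""
    return (
        sum(c.n_recombinant for c in crosses),
        sum(c.n_total for c in crosses),
    )


# ---------------------------------------------------------------------------
# two-population split
# ---------------------------------------------------------------------------


def gen_two_pop_split(
    n_a: int,
    n_b: int,
    split_time: float,
    S: int,
    rng: np.random.Generator,
    region_length: int = 1_000_000,
) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Clean-split (no migration) coalescent fixture for F_ST / d_XY tests.

    Two demes coalesce independently until ``split_time`` (4*N_e units,
    each deme at the reference size), then merge into one ancestral pool.
    Returns the two sub-panels on shared positions.
    """
    if n_a < 2 or n_b < 2:
        raise ConfigError("need >= 2 samples per deme")
    if split_time < 0:
        raise ConfigError("split_time must be >= 0")
    n = n_a + n_b
    times = [0.0] * n
    parent = [-1] * n
    demes: list[list[int]] = [list(range(n_a)), list(range(n_a, n))]
    t = 0.0

    def coalesce(pool: list[int], when: float) -> None:
        i = int(rng.integers(len(pool)))
        j = int(rng.integers(len(pool) - 1))
        if j >= i:
            j += 1
        node = len(times)
        times.append(when)
        parent.append(-1)
        parent[pool[i]] = node
        parent[pool[j]] = node
        hi, lo = max(i, j), min(i, j)
        pool[lo] = node
        pool[hi] = pool[-1]
        pool.pop()

    while True:
        rates = [len(d) * (len(d) - 1) for d in demes]
        total_rate = sum(rates)
        if total_rate == 0:
            break
        wait = rng.exponential(1.0) / total_rate
        if t + wait >= split_time:
            break
        t += wait
        which = 0 if rng.uniform() * total_rate < rates[0] else 1
        coalesce(demes[which], t)
    pool = demes[0] + demes[1]
    t = max(t, split_time)
    while len(pool) > 1:
        k = len(pool)
        t += rng.exponential(1.0) / (k * (k - 1))
        coalesce(pool, t)
    tree = CoalescentTree(n=n, times=np.asarray(times), parent=np.asarray(parent))
    m = place_mutations_fixed_S(tree, S, region_length, rng)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n)
    mk = lambda idx, group: HaplotypeMatrix(
        chrom=m.chrom,
        positions=m.positions.copy(),
        samples=[m.samples[i] for i in idx],
        alleles=m.alleles[idx],
        group=group,
    )
    return mk(idx_a, "deme_a"), mk(idx_b, "deme_b")
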