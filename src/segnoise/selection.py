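"""Forward simulation of the alternating extreme-tail selection regime.

The evolution experiment alternates between sorting the top and bottom
few percent of a reporter's fluorescence distribution, with chemical
mutagenesis before each cycle.  Cells whose genotype inflates
expression *variance* occupy both tails more often than average, so the
alternating regime enriches variance-increasing (noise) alleles while
purging consistent mean shifts — the in-silico question this module
answers is when that enrichment wins against drift through the sorting
bottleneck.

The model: a population of lineages (genotypes), each carrying a set of
mutations with additive effects on the Fano percentage (and optionally
the mean) of the log-scale signal.  Per cycle: mutations arise Poisson
per cell; the population grows deterministically to the census size;
every cell draws a phenotype ``log-signal ~ Normal(mu_g, var_g)`` with
``var_g = max(base_fano + sum effects, 0) * mu_g / 100``; the selected
tail is sorted and ``n_sorted`` cells seed the next cycle.

The regime's effective population size follows the serial-bottleneck
harmonic-mean formula ``2 / Ne = 1 / (N01 * g) + 1 / (N02 * g)`` over
the two phase-initial sizes and the generations per growth period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NeResult",
    "EffectDistribution",
    "RegimeSpec",
    "Trajectory",
    "effective_population_size",
    "run_alternating_selection",
    "summarize_trajectory",
]

# generations per growth phase implied by inverting the harmonic-mean
# formula at Ne = 1.33e5 with N01 = 1e6 (mutagenized census) and
# N02 = 5e3 (sorted cells); derived, not directly measured
DEFAULT_GENERATIONS_PER_PHASE = 13.4


@dataclass(frozen=True)
class NeResult:
    """Effective population size of a two-phase serial-bottleneck regime."""

    ne: float
    n01: float
    n02: float
    g: float


def effective_population_size(n01: float, n02: float, g: float) -> NeResult:
    """Harmonic-mean effective size: ``Ne = 2 g N01 N02 / (N01 + N02)``.

    ``n01`` and ``n02`` are the initial census sizes of the two growth
    phases of each cycle and ``g`` the generations per growth period.
    Symmetric in the two sizes, linear in ``g``, and equal to ``N * g``
    when both phases start at ``N``.
    """
    if n01 <= 0 or n02 <= 0 or g <= 0:
        raise ValueError("n01, n02 and g must all be positive")
    return NeResult(ne=2.0 * g * n01 * n02 / (n01 + n02),
                    n01=n01, n02=n02, g=g)


@dataclass(frozen=True)
class EffectDistribution:
    """Distribution of mutational effects on the noise phenotype.

    Fano-percent effects have exponential magnitude (scale
    ``fano_scale``) with probability ``p_positive`` of increasing noise.
    A fraction ``mean_frac`` of mutations instead shifts the mean
    log-signal (normal with sd ``mean_scale``).
    """

    fano_scale: float = 5.0
    p_positive: float = 0.5
    mean_frac: float = 0.0
    mean_scale: float = 0.1

    def draw(self, n: int, rng: np.random.Generator):
        fano = rng.exponential(self.fano_scale, n) * np.where(
            rng.random(n) < self.p_positive, 1.0, -1.0)
        mean = np.zeros(n)
        is_mean = rng.random(n) < self.mean_frac
        fano[is_mean] = 0.0
        mean[is_mean] = rng.normal(0.0, self.mean_scale, int(is_mean.sum()))
        return fano, mean


@dataclass(frozen=True)
class RegimeSpec:
    """Parameters of the alternating-selection evolution experiment.

    Defaults mirror the bench regime: 35 cycles, 5% tails, 5,000 sorted
    cells seeding each cycle, one million cells entering mutagenesis.
    ``standing_variants`` optionally pre-seeds tracked mutations as
    ``(initial_frequency, fano_effect, mean_effect)`` triples.
    """

    n_cycles: int = 35
    tail_frac: float = 0.05
    n_sorted: int = 5000
    n_mutagenized: int = 1_000_000
    mutation_rate: float = 1e-4
    effect_distribution: EffectDistribution = field(
        default_factory=EffectDistribution)
    generations_per_phase: float = DEFAULT_GENERATIONS_PER_PHASE
    base_fano: float = 10.0
    base_mu: float = 2.0
    standing_variants: tuple[tuple[float, float, float], ...] = ()
    first_tail: str = "top"
    track_de_novo: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_frac < 0.5:
            raise ValueError("tail_frac must be in (0, 0.5)")
        if self.n_sorted > self.n_mutagenized:
            raise ValueError("n_sorted cannot exceed the grown census")
        if self.generations_per_phase <= 0:
            raise ValueError("generations_per_phase must be > 0")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if self.first_tail not in ("top", "bottom"):
            raise ValueError("first_tail must be 'top' or 'bottom'")


@dataclass
class Trajectory:
    """Per-cycle state of one selection run.

    ``cycles`` has columns cycle, tail, fano_pct, mean_log plus one
    ``freq_<id>`` column per tracked mutation (standing variants are
    ids ``s0, s1, ...``; de-novo mutations ``m0, m1, ...``).
    ``mutation_effects`` maps mutation id to its (fano, mean) effect.
    """

    cycles: pd.DataFrame
    mutation_effects: dict[str, tuple[float, float]]
    ne: NeResult


def _scale_counts(counts: np.ndarray, target: int) -> np.ndarray:
    """Deterministic proportional growth to the target census size.

    Largest-remainder rounding keeps the counts integral and exactly
    summing to ``target`` while preserving genotype proportions.
    """
    total = counts.sum()
    if total == 0:
        raise ValueError("population went extinct")
    quotas = counts * (target / total)
    scaled = np.floor(quotas).astype(np.int64)
    short = target - scaled.sum()
    if short > 0:
        order = np.argsort(-(quotas - scaled), kind="stable")
        scaled[order[:short]] += 1
    return scaled


def run_alternating_selection(spec: RegimeSpec) -> Trajectory:
    """Run the alternating-tail selection regime and track mutations.

    Returns one row per cycle with the census phenotype statistics
    (Fano percent and mean of the drawn log-signals, measured after
    growth and before sorting) and the census frequency of every
    tracked mutation.
    """
    rng = np.random.default_rng(spec.seed)

    # genotype table: parallel lists of effect sums, counts, mutation sets
    fano_eff = [0.0]
    mean_eff = [0.0]
    muts: list[frozenset] = [frozenset()]
    counts = np.array([spec.n_sorted], dtype=np.int64)
    effects: dict[str, tuple[float, float]] = {}

    for j, (freq, fe, me) in enumerate(spec.standing_variants):
        mid = f"s{j}"
        effects[mid] = (float(fe), float(me))
        n_carriers = int(np.rint(freq * counts.sum()))
        if n_carriers > 0:
            counts[0] -= n_carriers
            fano_eff.append(fe)
            mean_eff.append(me)
            muts.append(frozenset({mid}))
            counts = np.append(counts, n_carriers)
    if (counts < 0).any():
        raise ValueError("standing variant frequencies sum past 1")

    tracked = set(effects)
    n_denovo = 0
    records = []
    floored_warned = False
    for cycle in range(1, spec.n_cycles + 1):
        # 1) deterministic growth to the census size entering mutagenesis
        counts = _scale_counts(counts, spec.n_mutagenized)

        # 2) mutagenesis: Poisson(count * rate) mutation events per
        # genotype, each converting one cell into a new genotype
        if spec.mutation_rate > 0:
            events = rng.poisson(counts * spec.mutation_rate)
            events = np.minimum(events, counts)
            total = int(events.sum())
            if total:
                fanos, means = spec.effect_distribution.draw(total, rng)
                pos = 0
                new_counts = []
                for gi in np.flatnonzero(events):
                    for _ in range(int(events[gi])):
                        mid = f"m{n_denovo}"
                        n_denovo += 1
                        effects[mid] = (float(fanos[pos]), float(means[pos]))
                        if spec.track_de_novo:
                            tracked.add(mid)
                        counts[gi] -= 1
                        fano_eff.append(fano_eff[gi] + fanos[pos])
                        mean_eff.append(mean_eff[gi] + means[pos])
                        muts.append(muts[gi] | {mid})
                        new_counts.append(1)
                        pos += 1
                counts = np.concatenate(
                    [counts, np.ones(len(new_counts), dtype=np.int64)])
        live = counts > 0

        # 3) per-cell phenotype draws
        fe = np.asarray(fano_eff)
        me = np.asarray(mean_eff)
        mu_g = spec.base_mu + me
        var_g = np.maximum(spec.base_fano + fe, 0.0) * mu_g / 100.0
        if not floored_warned:
            floored = counts[(spec.base_fano + fe < 0) & live].sum()
            if floored > 0.01 * spec.n_mutagenized:
                import warnings
                warnings.warn(
                    "variance floor engaged for > 1% of cells; effect "
                    "distribution drives Fano below zero", stacklevel=2)
                floored_warned = True
        geno_of_cell = np.repeat(np.arange(counts.size), counts)
        pheno = rng.normal(mu_g[geno_of_cell],
                           np.sqrt(var_g[geno_of_cell]))

        # census statistics and tracked-mutation frequencies
        mean_log = float(pheno.mean())
        fano_pct = float(100.0 * pheno.var(ddof=1) / mean_log) \
            if mean_log > 0 else float("nan")
        freq_row = {}
        census = counts.sum()
        for mid in sorted(tracked):
            carriers = sum(int(c) for c, ms in zip(counts, muts) if mid in ms)
            freq_row[f"freq_{mid}"] = carriers / census

        # 4) sort the selected tail, sample n_sorted seeds
        tails = ("top", "bottom") if spec.first_tail == "top" \
            else ("bottom", "top")
        tail = tails[(cycle - 1) % 2]
        n_tail = int(np.rint(spec.tail_frac * pheno.size))
        if n_tail == 0:
            raise ValueError("tail_frac selects zero cells")
        key = -pheno if tail == "top" else pheno
        order = np.lexsort((np.arange(pheno.size), key))
        tail_cells = order[:n_tail]
        if n_tail > spec.n_sorted:
            seeds = rng.choice(tail_cells, size=spec.n_sorted, replace=False)
        else:
            seeds = tail_cells
        counts = np.bincount(geno_of_cell[seeds], minlength=counts.size)

        records.append({"cycle": cycle, "tail": tail,
                        "fano_pct": fano_pct, "mean_log": mean_log,
                        **freq_row})

        # compact extinct genotypes to keep the table small
        live = counts > 0
        if not live.all():
            counts = counts[live]
            fano_eff = [f for f, a in zip(fano_eff, live) if a]
            mean_eff = [m for m, a in zip(mean_eff, live) if a]
            muts = [ms for ms, a in zip(muts, live) if a]

    ne = effective_population_size(spec.n_mutagenized, spec.n_sorted,
                                   spec.generations_per_phase)
    cycles = pd.DataFrame(records)
    # mutations may appear mid-run; absent-at-cycle means frequency 0
    freq_cols = [c for c in cycles.columns if c.startswith("freq_")]
    cycles[freq_cols] = cycles[freq_cols].fillna(0.0)
    return Trajectory(cycles=cycles, mutation_effects=effects, ne=ne)


def summarize_trajectory(traj: Trajectory) -> dict:
    """Per-cycle table plus final/initial fold-changes in noise and mean.

    Fold-changes compare the last cycle's census statistics to the first
    cycle's; the mean fold-change is on the linear signal scale.
    """
    cyc = traj.cycles
    if cyc.empty:
        raise ValueError("empty trajectory")
    first, last = cyc.iloc[0], cyc.iloc[-1]
    freq_cols = [c for c in cyc.columns if c.startswith("freq_")]
    return {
        "cycles": cyc,
        "noise_fold_change": float(last["fano_pct"] / first["fano_pct"]),
        "mean_fold_change": float(10.0 ** (last["mean_log"]
                                           - first["mean_log"])),
        "final_frequencies": {c.removeprefix("freq_"): float(last[c])
                              for c in freq_cols},
        "ne": traj.ne.ne,
    }
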