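"""Synthetic flow-cytometry events, haploid crosses and pooled reads.

Every downstream stage of the pipeline (gating, noise measurement,
extreme-segregant screening, pooled-read threshold calling) can be run
against data from this module, with known ground truth planted in it:

* :func:`simulate_flow_events` draws singlet cells whose log10
  fluorescence has a prescribed mean and Fano factor, optionally
  contaminated with debris and doublets that the gate hierarchy is
  expected to remove.
* :func:`simulate_cross` produces haploid F1 segregants of an
  evolved x ancestral cross, with one or more causal loci that shift the
  noise phenotype additively.
* :func:`simulate_pooled_reads` turns two phenotype-selected segregant
  pools into a per-marker read-count table at Poisson coverage, the
  input format of the bulk-segregant caller.

All generators use :class:`numpy.random.Generator` (PCG64) seeded from
the spec, so identical specs give bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FlowPopulationSpec",
    "CrossSpec",
    "SegregantSet",
    "PoolAssignment",
    "simulate_flow_events",
    "simulate_cross",
    "simulate_noise_runs",
    "simulate_pooled_reads",
    "spike_background_mutations",
    "default_genome_layout",
    "MUTATION_CLASS_FRACTIONS",
]

# Pulse-shape channels are affine in FSC for single cells; doublets sit on
# a band with ~1.8x the width, which is what the constant-band gate keys on.
_PW_INTERCEPT = 1000.0
_PW_SLOPE = 0.02
_PW_NOISE_SD = 25.0
_FSCW_INTERCEPT = 600.0
_FSCW_SLOPE = 0.01
_FSCW_NOISE_SD = 15.0
_DOUBLET_WIDTH_FACTOR = 1.8
# Debris scatters at a few percent of the singlet scale (mostly below the
# sorter trigger) and fluoresces at the autofluorescence baseline.
_DEBRIS_SCATTER_FACTOR = 0.03
_AUTOFLUOR_LOG10_OFFSET = -2.0
_AUTOFLUOR_LOG10_SD = 0.1

# Mutation-class mix observed in an EMS-mutagenized evolved yeast genome:
# 494 nonsynonymous, 256 synonymous and 271 intergenic out of 1,022 total;
# the one remaining mutation falls outside those three classes.
MUTATION_CLASS_FRACTIONS = {
    "nonsynonymous": 494 / 1022,
    "synonymous": 256 / 1022,
    "intergenic": 271 / 1022,
    "other": 1 / 1022,
}


@dataclass(frozen=True)
class FlowPopulationSpec:
    """Parameters of one synthetic cell population on the cytometer.

    ``mu_log`` and ``fano_pct`` define the fluorescence channel on the
    log10 scale: log10 signal ~ Normal(mu_log, fano_pct * mu_log / 100).
    Scatter channels are log-normal with correlation ``scatter_corr``.
    ``debris_frac`` / ``doublet_frac`` fractions of events are replaced
    by contaminants.
    """

    n_events: int
    mu_log: float = 2.0
    fano_pct: float = 5.0
    scatter_mu: float = math.log(5e4)
    scatter_sigma: float = 0.2
    scatter_corr: float = 0.0
    debris_frac: float = 0.0
    doublet_frac: float = 0.0
    seed: int = 0
    channel: str = "GFP"

    def __post_init__(self) -> None:
        if not (self.n_events >= 1):
            raise ValueError("n_events must be >= 1")
        for name in ("mu_log", "fano_pct", "scatter_mu", "scatter_sigma",
                     "scatter_corr", "debris_frac", "doublet_frac"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.fano_pct < 0:
            raise ValueError("fano_pct must be >= 0")
        if not -1.0 <= self.scatter_corr <= 1.0:
            raise ValueError("scatter_corr must be in [-1, 1]")
        for name in ("debris_frac", "doublet_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.debris_frac + self.doublet_frac > 1.0:
            raise ValueError("debris_frac + doublet_frac must be <= 1")


def _singlet_core(spec: FlowPopulationSpec, n: int, rng: np.random.Generator):
    """Draw (FSC, SSC, fluor_raw) for n singlet cells."""
    var_log = spec.fano_pct * spec.mu_log / 100.0
    log_fluor = rng.normal(spec.mu_log, math.sqrt(max(var_log, 0.0)), size=n)
    cov = spec.scatter_corr * spec.scatter_sigma ** 2
    cov_mat = [[spec.scatter_sigma ** 2, cov], [cov, spec.scatter_sigma ** 2]]
    ln_sc = rng.multivariate_normal(
        [spec.scatter_mu, spec.scatter_mu - 0.7], cov_mat, size=n,
        method="cholesky" if abs(spec.scatter_corr) < 1 else "svd")
    fsc = np.exp(ln_sc[:, 0])
    ssc = np.exp(ln_sc[:, 1])
    return fsc, ssc, 10.0 ** log_fluor


def _widths(fsc: np.ndarray, rng: np.random.Generator):
    pw = _PW_INTERCEPT + _PW_SLOPE * fsc + rng.normal(0, _PW_NOISE_SD, fsc.size)
    fw = _FSCW_INTERCEPT + _FSCW_SLOPE * fsc + rng.normal(0, _FSCW_NOISE_SD, fsc.size)
    return pw, fw


def simulate_flow_events(spec: FlowPopulationSpec) -> pd.DataFrame:
    """Generate an event table (columns FSC, SSC, PW, FSC_W, <channel>).

    Singlets carry the prescribed log10-scale fluorescence statistics;
    doublets are sums of two independent singlets with pulse-shape
    channels inflated by a constant factor; debris scatters low and
    fluoresces at the autofluorescence baseline.  Rows are shuffled so
    event order carries no information about the event class.
    """
    rng = np.random.default_rng(spec.seed)
    n_debris = int(np.rint(spec.debris_frac * spec.n_events))
    n_doublet = int(np.rint(spec.doublet_frac * spec.n_events))
    n_singlet = spec.n_events - n_debris - n_doublet

    fsc, ssc, fluor = _singlet_core(spec, n_singlet, rng)
    pw, fw = _widths(fsc, rng)
    parts = [(fsc, ssc, pw, fw, fluor)]

    if n_doublet:
        f1, s1, g1 = _singlet_core(spec, n_doublet, rng)
        f2, s2, g2 = _singlet_core(spec, n_doublet, rng)
        dfsc, dssc, dfluor = f1 + f2, s1 + s2, g1 + g2
        dpw, dfw = _widths(dfsc, rng)
        parts.append((dfsc, dssc, dpw * _DOUBLET_WIDTH_FACTOR,
                      dfw * _DOUBLET_WIDTH_FACTOR, dfluor))
    if n_debris:
        mu = spec.scatter_mu + math.log(_DEBRIS_SCATTER_FACTOR)
        bfsc = np.exp(rng.normal(mu, spec.scatter_sigma, n_debris))
        bssc = np.exp(rng.normal(mu - 0.7, spec.scatter_sigma, n_debris))
        bpw, bfw = _widths(bfsc, rng)
        bfluor = 10.0 ** rng.normal(spec.mu_log + _AUTOFLUOR_LOG10_OFFSET,
                                    _AUTOFLUOR_LOG10_SD, n_debris)
        parts.append((bfsc, bssc, bpw, bfw, bfluor))

    cols = [np.concatenate([p[i] for p in parts]) for i in range(5)]
    order = rng.permutation(spec.n_events)
    table = pd.DataFrame({
        "FSC": cols[0][order],
        "SSC": cols[1][order],
        "PW": cols[2][order],
        "FSC_W": cols[3][order],
        spec.channel: cols[4][order],
    })
    return table


# ---------------------------------------------------------------------------
# F1 haploid cross


@dataclass(frozen=True)
class CrossSpec:
    """An evolved x ancestral haploid cross with planted causal loci.

    ``causal_markers`` are 0-based indices into the marker list;
    ``causal_effects`` are the additive shifts (Fano-percent units) the
    evolved allele adds to the noise phenotype. ``linkage_model`` is
    either ``"unlinked"`` or a sequence of ``n_markers - 1``
    recombination fractions in [0, 0.5] between adjacent markers.
    """

    n_segregants: int
    n_markers: int
    causal_markers: tuple[int, ...] = ()
    causal_effects: tuple[float, ...] = ()
    residual_sd: float = 1.0
    base_noise: float = 10.0
    base_mean: float = 2.0
    mean_measurement_sd: float = 0.05
    linkage_model: object = "unlinked"
    marker_positions: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segregants < 1 or self.n_markers < 1:
            raise ValueError("n_segregants and n_markers must be >= 1")
        if len(self.causal_markers) != len(self.causal_effects):
            raise ValueError("causal_markers and causal_effects lengths differ")
        for m in self.causal_markers:
            if not 0 <= m < self.n_markers:
                raise ValueError(f"causal marker index {m} out of range")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not isinstance(self.linkage_model, str):
            r = np.asarray(self.linkage_model, dtype=float)
            if r.shape != (self.n_markers - 1,):
                raise ValueError("linkage_model needs n_markers - 1 fractions")
            if np.any((r < 0) | (r > 0.5)):
                raise ValueError("recombination fractions must be in [0, 0.5]")


@dataclass
class SegregantSet:
    """Genotypes and phenotypes of simulated F1 haploid segregants.

    ``genotypes`` is n_segregants x n_markers over {0 = ancestral,
    1 = evolved}.  ``genetic_noise`` is the noise-free genetic value of
    the noise phenotype, retained so repeated measurement runs can draw
    fresh environmental noise around it.
    """

    genotypes: np.ndarray
    noise_phenotype: np.ndarray
    mean_phenotype: np.ndarray
    genetic_noise: np.ndarray
    markers: pd.DataFrame
    spec: CrossSpec

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.genotypes.shape[0])


@dataclass(frozen=True)
class PoolAssignment:
    """Disjoint 'evolved-like' and 'ancestral-like' segregant id sets."""

    evolved_like_ids: tuple[int, ...]
    ancestral_like_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.evolved_like_ids) & set(self.ancestral_like_ids):
            raise ValueError("pools must be disjoint")


def default_genome_layout(n_chroms: int = 16,
                          total_bp: int = 12_000_000) -> dict[str, int]:
    """A yeast-like nuclear genome layout: 16 chromosomes, ~12 Mb."""
    size = total_bp // n_chroms
    return {f"chr{i + 1:02d}": size for i in range(n_chroms)}


def _default_markers(n_markers: int, rng: np.random.Generator) -> pd.DataFrame:
    layout = default_genome_layout()
    return spike_background_mutations(n_markers, genome_layout=layout, rng=rng)


def simulate_cross(spec: CrossSpec) -> SegregantSet:
    """Simulate Mendelian segregation of markers into haploid F1 progeny.

    Each segregant inherits the evolved allele at the first marker with
    probability 0.5; under a genetic map, adjacent markers recombine
    with the stated fraction (a Markov chain along the marker order).
    The noise phenotype is base + sum of causal effects + N(0, residual).
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_segregants, spec.n_markers
    if isinstance(spec.linkage_model, str):
        if spec.linkage_model != "unlinked":
            raise ValueError(f"unknown linkage model {spec.linkage_model!r}")
        geno = rng.integers(0, 2, size=(n, m), dtype=np.int8)
    else:
        r = np.asarray(spec.linkage_model, dtype=float)
        geno = np.empty((n, m), dtype=np.int8)
        geno[:, 0] = rng.integers(0, 2, size=n)
        flips = rng.random((n, m - 1)) < r[None, :]
        geno[:, 1:] = geno[:, [0]] ^ (np.cumsum(flips, axis=1) % 2)

    effects = np.zeros(m)
    for idx, eff in zip(spec.causal_markers, spec.causal_effects):
        effects[idx] += eff
    genetic = spec.base_noise + geno @ effects
    noise = genetic + rng.normal(0.0, spec.residual_sd, size=n)
    mean = np.full(n, spec.base_mean) + rng.normal(
        0.0, spec.mean_measurement_sd, size=n)

    if spec.marker_positions is not None:
        markers = spec.marker_positions.reset_index(drop=True).copy()
        if len(markers) != m:
            raise ValueError("marker_positions length != n_markers")
    else:
        markers = _default_markers(m, rng)
    return SegregantSet(genotypes=geno, noise_phenotype=noise,
                        mean_phenotype=mean, genetic_noise=genetic,
                        markers=markers, spec=spec)


def measure_segregants(segregants: SegregantSet,
                       rng: np.random.Generator,
                       ids: np.ndarray | None = None) -> pd.DataFrame:
    """One noise-measurement run over (a subset of) the segregants.

    Re-draws environmental noise around each segregant's genetic value
    and measurement noise around its mean phenotype, emulating an
    independent cytometry session.  Returns an ``(id, noise, mean)``
    frame.
    """
    spec = segregants.spec
    if ids is None:
        ids = np.arange(segregants.genotypes.shape[0])
    ids = np.asarray(ids, dtype=int)
    noise = segregants.genetic_noise[ids] + rng.normal(
        0, spec.residual_sd, ids.size)
    mean = spec.base_mean + rng.normal(0, spec.mean_measurement_sd, ids.size)
    return pd.DataFrame({"id": ids, "noise": noise, "mean": mean})


def simulate_noise_runs(segregants: SegregantSet, n_runs: int,
                        seed: int) -> list[pd.DataFrame]:
    """Repeated full-population noise-measurement runs (no selection)."""
    rng = np.random.default_rng(seed)
    return [measure_segregants(segregants, rng) for _ in range(n_runs)]


def simulate_segregant_screen(segregants: SegregantSet, n_runs: int = 3,
                              tail_frac: float = 0.20, n_sd: float = 3.0,
                              seed: int = 0,
                              control_mean: float | None = None,
                              control_sd: float | None = None):
    """Emulate the iterative extreme-segregant screen on a synthetic cross.

    Run 1 measures every segregant; each later run re-measures only the
    survivors of the previous run, exactly as on the bench.  Control
    mean / SD default to the cross's ancestral mean and its measurement
    SD.  Returns the :class:`~segnoise.bsa.ScreenResult`.
    """
    from segnoise.bsa import iterate_segregant_screen

    spec = segregants.spec
    if control_mean is None:
        control_mean = spec.base_mean
    if control_sd is None:
        control_sd = spec.mean_measurement_sd
    rng = np.random.default_rng(seed)
    runs: list[pd.DataFrame] = []
    ids: np.ndarray | None = None
    result = None
    for _ in range(n_runs):
        runs.append(measure_segregants(segregants, rng, ids))
        result = iterate_segregant_screen(runs, control_mean, control_sd,
                                          tail_frac=tail_frac, n_sd=n_sd)
        ids = np.array(sorted(set(result.evolved_like_ids)
                              | set(result.ancestral_like_ids)), dtype=int)
        if ids.size == 0:
            break
    return result


# ---------------------------------------------------------------------------
# Pooled sequencing


def simulate_pooled_reads(segregants: SegregantSet, pools: PoolAssignment,
                          mean_coverage: float = 150.0,
                          seed: int = 0) -> pd.DataFrame:
    """Binomial read sampling of two pooled segregant DNA libraries.

    Per marker and pool: coverage ~ Poisson(mean_coverage) truncated at
    1, alt reads ~ Binomial(coverage, evolved-allele frequency in the
    pool).  Control-clone alt reads come from a ``ctrl_alt`` column of
    the marker table if present, else default to 0 (markers private to
    the evolved line).
    """
    if mean_coverage < 1:
        raise ValueError("mean_coverage must be >= 1")
    evo = np.asarray(pools.evolved_like_ids, dtype=int)
    anc = np.asarray(pools.ancestral_like_ids, dtype=int)
    if evo.size == 0 or anc.size == 0:
        raise ValueError("both pools must be non-empty")
    n = segregants.genotypes.shape[0]
    if evo.max(initial=-1) >= n or anc.max(initial=-1) >= n or \
            evo.min(initial=0) < 0 or anc.min(initial=0) < 0:
        raise ValueError("pool ids outside segregant set")

    rng = np.random.default_rng(seed)
    markers = segregants.markers
    m = segregants.genotypes.shape[1]
    out = pd.DataFrame({
        "chrom": markers["chrom"].to_numpy(),
        "pos": markers["pos"].to_numpy(),
        "ref": markers["ref"].to_numpy(),
        "alt": markers["alt"].to_numpy(),
        "effect": markers["effect"].to_numpy(),
    })
    for label, ids in (("evo", evo), ("anc", anc)):
        freq = segregants.genotypes[ids].mean(axis=0)
        cov = np.maximum(rng.poisson(mean_coverage, size=m), 1)
        alt = rng.binomial(cov, freq)
        out[f"{label}_alt"] = alt
        out[f"{label}_cov"] = cov
    if "ctrl_alt" in markers.columns:
        out["ctrl_alt"] = markers["ctrl_alt"].to_numpy()
    else:
        out["ctrl_alt"] = 0
    return out


def spike_background_mutations(
        n_total: int,
        class_fractions: dict[str, float] | None = None,
        genome_layout: dict[str, int] | None = None,
        seed: int | None = None,
        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Neutral marker definitions with realistic effect-class mix.

    Positions are unique across a chromosome layout; substitutions carry
    an EMS-like G:C -> A:T signature.  Class counts are apportioned by
    the largest-remainder rule, so fractions that are exact multiples of
    1/n_total reproduce their counts exactly.
    """
    if class_fractions is None:
        class_fractions = MUTATION_CLASS_FRACTIONS
    total_frac = sum(class_fractions.values())
    if abs(total_frac - 1.0) > 1e-6:
        raise ValueError(f"class fractions sum to {total_frac}, expected 1")
    if genome_layout is None:
        genome_layout = default_genome_layout()
    if rng is None:
        rng = np.random.default_rng(seed)

    if n_total == 0:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "effect"])

    total_bp = sum(genome_layout.values())
    if n_total > total_bp:
        raise ValueError("n_total exceeds available genome positions")

    # largest-remainder apportionment of class counts
    names = list(class_fractions)
    quotas = np.array([class_fractions[k] * n_total for k in names])
    counts = np.floor(quotas).astype(int)
    short = n_total - counts.sum()
    for i in np.argsort(-(quotas - counts))[:short]:
        counts[i] += 1

    flat = rng.choice(total_bp, size=n_total, replace=False)
    flat.sort()
    chroms = np.empty(n_total, dtype=object)
    pos = np.empty(n_total, dtype=int)
    offset = 0
    for chrom, size in genome_layout.items():
        sel = (flat >= offset) & (flat < offset + size)
        chroms[sel] = chrom
        pos[sel] = flat[sel] - offset + 1  # 1-based
        offset += size

    effect = np.concatenate([np.repeat(name, c)
                             for name, c in zip(names, counts)])
    rng.shuffle(effect)
    ref = np.where(rng.random(n_total) < 0.5, "G", "C")
    alt = np.where(ref == "G", "A", "T")
    return pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref,
                         "alt": alt, "effect": effect})
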