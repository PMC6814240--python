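"""Bulk-segregant mapping of causal loci from pooled sequencing.

The mapping strategy: cross the evolved line to its ancestor, screen the
F1 haploid segregants through repeated noise-measurement runs to collect
an "evolved-like" and an "ancestral-like" pool of phenotypic extremes,
sequence both pools, and call candidate causal mutations as those whose
pooled allele frequencies are incompatible with neutral 1:1 segregation.

The neutral expectation is derived by Monte Carlo: a neutral SNP enters
each of ``pool_size`` haploid segregants with probability 0.5, and read
sampling at ``coverage`` adds binomial noise on top, so the observed
pool frequency of a neutral marker follows a two-stage binomial mixture.
Empirical quantiles of that mixture (nearest-rank definition) are the
enrichment thresholds; an exact enumeration of the finite outcome
lattice is also provided and doubles as a calibration calculator for the
expected neutral false-positive rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenResult",
    "CandidateResult",
    "iterate_segregant_screen",
    "simulate_pool_threshold",
    "build_threshold_table",
    "exact_pool_frequency_distribution",
    "exact_pool_threshold",
    "neutral_pass_rate",
    "filter_control_variants",
    "call_candidates",
]


# ---------------------------------------------------------------------------
# Extreme-segregant screen


@dataclass
class ScreenResult:
    """Outcome of the iterative extreme-segregant screen.

    The two id sets are disjoint by construction; ``audit`` holds one
    row per (run, segregant) with the measured values and the per-run
    survival decisions.
    """

    evolved_like_ids: tuple[int, ...]
    ancestral_like_ids: tuple[int, ...]
    audit: pd.DataFrame

    @property
    def n_evolved_like(self) -> int:
        return len(self.evolved_like_ids)

    @property
    def n_ancestral_like(self) -> int:
        return len(self.ancestral_like_ids)


def _tail_ids(run: pd.DataFrame, frac: float, top: bool) -> set:
    """Ids in the extreme ``frac`` of this run's noise values.

    Count is round(frac * n); ties broken by position in the run table.
    """
    n = len(run)
    n_keep = int(np.rint(frac * n))
    noise = run["noise"].to_numpy(float)
    key = -noise if top else noise
    order = np.lexsort((np.arange(n), key))
    return set(run["id"].to_numpy()[order[:n_keep]])


def iterate_segregant_screen(runs: list[pd.DataFrame], control_mean: float,
                             control_sd: float, tail_frac: float = 0.20,
                             n_sd: float = 3.0) -> ScreenResult:
    """Iterative screen for evolved-like and ancestral-like segregants.

    Each element of ``runs`` is one noise-measurement run, a frame with
    columns ``id``, ``noise``, ``mean``; run 1 must cover all screened
    segregants and each later run only survivors of the previous run.
    Per run, a segregant stays on the evolved-like (resp.
    ancestral-like) track if its noise ranks in the top (resp. bottom)
    ``tail_frac`` of that run's measured set AND its mean signal is
    within ``n_sd`` control standard deviations of the control mean.
    Survivors of the final run form the two pools.
    """
    if not runs:
        raise ValueError("need at least one run")
    if not 0.0 < tail_frac < 0.5:
        raise ValueError("tail_frac must be in (0, 0.5)")
    if control_sd < 0:
        raise ValueError("control_sd must be >= 0")

    evolved: set | None = None
    ancestral: set | None = None
    audit_rows = []
    for r, run in enumerate(runs, start=1):
        for col in ("id", "noise", "mean"):
            if col not in run.columns:
                raise KeyError(f"run {r} missing column {col!r}")
        ids = run["id"].to_numpy()
        if len(set(ids)) != len(ids):
            raise ValueError(f"run {r} has duplicate segregant ids")
        if r > 1:
            allowed = evolved | ancestral
            alien = set(ids) - allowed
            if alien:
                raise ValueError(
                    f"run {r} measures ids not surviving run {r - 1}: "
                    f"{sorted(alien)[:5]}...")
        top = _tail_ids(run, tail_frac, top=True)
        bottom = _tail_ids(run, tail_frac, top=False)
        mean_ok = set(ids[np.abs(run["mean"].to_numpy(float) - control_mean)
                          <= n_sd * control_sd])
        new_e = top & mean_ok
        new_a = bottom & mean_ok
        evolved = new_e if evolved is None else evolved & new_e
        ancestral = new_a if ancestral is None else ancestral & new_a
        # a segregant cannot ride both tracks (possible only in
        # degenerate all-tied runs); evolved track wins
        ancestral -= evolved
        audit_rows.append(pd.DataFrame({
            "run": r, "id": ids,
            "noise": run["noise"].to_numpy(float),
            "mean": run["mean"].to_numpy(float),
            "in_top": [i in top for i in ids],
            "in_bottom": [i in bottom for i in ids],
            "mean_ok": [i in mean_ok for i in ids],
            "evolved_track": [i in evolved for i in ids],
            "ancestral_track": [i in ancestral for i in ids],
        }))
    return ScreenResult(
        evolved_like_ids=tuple(sorted(evolved)),
        ancestral_like_ids=tuple(sorted(ancestral)),
        audit=pd.concat(audit_rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Allele-frequency thresholds for pooled sequencing


def _nearest_rank(sorted_vals: np.ndarray, level: float) -> float:
    """Smallest order statistic whose cumulative fraction reaches level."""
    n = sorted_vals.size
    idx = max(int(np.ceil(level * n)) - 1, 0)
    return float(sorted_vals[idx])


def simulate_pool_threshold(pool_size: int, coverage: int = 150,
                            p_seg: float = 0.5, side: str = "upper",
                            confidence: float = 0.90,
                            n_reps: int = 200_000,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo allele-frequency threshold for a neutral pooled SNP.

    Per replicate: carriers ``k ~ Binomial(pool_size, p_seg)``, alt
    reads ``r ~ Binomial(coverage, k / pool_size)``, observed frequency
    ``r / coverage``.  Returns the empirical nearest-rank quantile of
    the replicate frequencies: the ``confidence`` quantile for
    ``side="upper"`` or the ``1 - confidence`` quantile for
    ``side="lower"``.
    """
    if pool_size < 1 or coverage < 1:
        raise ValueError("pool_size and coverage must be >= 1")
    if not 0.5 < confidence < 1.0:
        raise ValueError("confidence must be in (0.5, 1)")
    if side not in ("upper", "lower"):
        raise ValueError("side must be 'upper' or 'lower'")
    level = confidence if side == "upper" else 1.0 - confidence
    tail_mass = min(level, 1.0 - level)
    if n_reps * tail_mass < 50:
        warnings.warn(
            f"n_reps={n_reps} puts only ~{n_reps * tail_mass:.0f} replicates "
            f"in the {tail_mass:.3f} tail; quantile resolution is coarse",
            stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(seed)
    k = rng.binomial(pool_size, p_seg, size=n_reps)
    r = rng.binomial(coverage, k / pool_size)
    freqs = np.sort(r / coverage)
    return _nearest_rank(freqs, level)


# Default threshold settings: the upper bound comes from the 90%
# one-sided quantile of a 10-segregant pool, the lower bound from the
# 95% one-sided quantile of a 20-segregant pool.
DEFAULT_THRESHOLD_SETTINGS = (
    {"pool_size": 10, "side": "upper", "confidence": 0.90},
    {"pool_size": 20, "side": "lower", "confidence": 0.95},
)


def build_threshold_table(settings=DEFAULT_THRESHOLD_SETTINGS,
                          coverage: int = 150, p_seg: float = 0.5,
                          n_reps: int = 200_000,
                          seed: int = 0) -> pd.DataFrame:
    """One threshold row per requested (pool_size, side, confidence).

    The default settings reproduce the published pair of enrichment
    thresholds (evolved-like pool frequency above ~0.70, ancestral-like
    pool frequency below ~0.32) and their difference.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for setting, child in zip(settings, ss.spawn(len(settings))):
        rng = np.random.default_rng(child)
        thr = simulate_pool_threshold(
            setting["pool_size"], coverage=setting.get("coverage", coverage),
            p_seg=p_seg, side=setting["side"],
            confidence=setting["confidence"], n_reps=n_reps, rng=rng)
        rows.append({
            "pool_size": setting["pool_size"],
            "coverage": setting.get("coverage", coverage),
            "side": setting["side"],
            "confidence": setting["confidence"],
            "threshold": thr,
            "n_reps": n_reps,
            "seed": seed,
        })
    return pd.DataFrame(rows)


def exact_pool_frequency_distribution(pool_size: int, coverage: int,
                                      p_seg: float = 0.5
                                      ) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the observed pooled allele frequency.

    Marginalizes the carrier count out of the two-stage binomial model:
    ``P(r) = sum_k Binom(pool_size, p_seg).pmf(k)
    * Binom(coverage, k / pool_size).pmf(r)``.  Returns the support
    ``r / coverage`` and its probabilities.
    """
    ks = np.arange(pool_size + 1)
    pk = stats.binom.pmf(ks, pool_size, p_seg)
    rs = np.arange(coverage + 1)
    pr = np.zeros(coverage + 1)
    for k, w in zip(ks, pk):
        pr += w * stats.binom.pmf(rs, coverage, k / pool_size)
    return rs / coverage, pr


def exact_pool_threshold(pool_size: int, coverage: int, side: str,
                         confidence: float, p_seg: float = 0.5) -> float:
    """Nearest-rank quantile of the exact pooled-frequency distribution."""
    if side not in ("upper", "lower"):
        raise ValueError("side must be 'upper' or 'lower'")
    level = confidence if side == "upper" else 1.0 - confidence
    freqs, probs = exact_pool_frequency_distribution(pool_size, coverage, p_seg)
    cdf = np.cumsum(probs)
    idx = int(np.searchsorted(cdf, level - 1e-12))
    return float(freqs[min(idx, freqs.size - 1)])


def neutral_pass_rate(evo_pool_size: int, anc_pool_size: int,
                      coverage: int = 150, evo_min_freq: float = 0.70,
                      anc_max_freq: float = 0.32,
                      min_diff: float | None = 0.38,
                      p_seg: float = 0.5) -> float:
    """Exact probability that a neutral SNP passes the frequency filters.

    The two pools are disjoint sets of segregants, so their observed
    frequencies are independent; the joint pass probability is computed
    on the product of the two exact frequency lattices, including the
    frequency-difference criterion when ``min_diff`` is given.  All
    comparisons are strict, matching the caller.
    """
    f1, p1 = exact_pool_frequency_distribution(evo_pool_size, coverage, p_seg)
    f2, p2 = exact_pool_frequency_distribution(anc_pool_size, coverage, p_seg)
    pass1 = f1 > evo_min_freq
    pass2 = f2 < anc_max_freq
    if min_diff is None:
        return float(p1[pass1].sum() * p2[pass2].sum())
    joint = np.outer(p1[pass1], p2[pass2])
    diff_ok = f1[pass1][:, None] - f2[pass2][None, :] > min_diff
    return float(joint[diff_ok].sum())


# ---------------------------------------------------------------------------
# Variant filters


def filter_control_variants(table: pd.DataFrame,
                            max_ctrl_reads: int = 2) -> pd.DataFrame:
    """Remove SNPs supported by the ancestral control clone.

    Keeps rows with strictly fewer than ``max_ctrl_reads`` control-clone
    alt reads (default: 0 or 1 pass), eliminating variants present in
    both ancestral and evolved lines.
    """
    if "ctrl_alt" not in table.columns:
        raise KeyError("table missing 'ctrl_alt' column")
    return table.loc[table["ctrl_alt"] < max_ctrl_reads].reset_index(drop=True)


@dataclass
class CandidateResult:
    """Candidate causal SNPs with a per-filter audit trail.

    ``candidates`` are the rows passing every enabled filter;
    ``audit`` is the full input with one boolean column per filter plus
    the computed pool frequencies; ``n_invalid`` counts rows dropped for
    zero coverage in either pool.
    """

    candidates: pd.DataFrame
    audit: pd.DataFrame
    n_invalid: int


def call_candidates(table: pd.DataFrame, evo_min_freq: float = 0.70,
                    anc_max_freq: float = 0.32,
                    min_diff: float | None = 0.38,
                    require_effect: str | None = "nonsynonymous",
                    warn_unfiltered_control: bool = True) -> CandidateResult:
    """Call candidate causal SNPs from pooled allele frequencies.

    A row is a candidate when (all comparisons strict):

    * evolved-like pool frequency ``evo_alt / evo_cov`` > ``evo_min_freq``
    * ancestral-like pool frequency < ``anc_max_freq``
    * their difference > ``min_diff`` (skipped when ``min_diff`` is None)
    * its effect annotation equals ``require_effect`` (skipped when None)

    Frequencies are computed from read counts at call time.  Rows with
    zero coverage in either pool are flagged invalid and excluded.
    """
    required = {"evo_alt", "evo_cov", "anc_alt", "anc_cov", "effect"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"table missing column(s) {sorted(missing)}")
    if warn_unfiltered_control and "ctrl_alt" in table.columns and \
            (table["ctrl_alt"] >= 2).any():
        warnings.warn(
            "table contains rows with >= 2 control reads; run "
            "filter_control_variants first", stacklevel=2)

    audit = table.reset_index(drop=True).copy()
    valid = (audit["evo_cov"] > 0) & (audit["anc_cov"] > 0)
    n_invalid = int((~valid).sum())
    evo_freq = np.where(valid, audit["evo_alt"] / audit["evo_cov"].replace(0, 1),
                        np.nan)
    anc_freq = np.where(valid, audit["anc_alt"] / audit["anc_cov"].replace(0, 1),
                        np.nan)
    audit["evo_freq"] = evo_freq
    audit["anc_freq"] = anc_freq
    audit["valid"] = valid
    audit["pass_evo"] = valid & (evo_freq > evo_min_freq)
    audit["pass_anc"] = valid & (anc_freq < anc_max_freq)
    audit["pass_diff"] = valid if min_diff is None else \
        valid & (evo_freq - anc_freq > min_diff)
    audit["pass_effect"] = True if require_effect is None else \
        (audit["effect"] == require_effect)
    audit["candidate"] = (audit["pass_evo"] & audit["pass_anc"]
                          & audit["pass_diff"] & audit["pass_effect"])
    candidates = audit.loc[audit["candidate"]].reset_index(drop=True)
    return CandidateResult(candidates=candidates, audit=audit,
                           n_invalid=n_invalid)
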