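"""Forward-in-time non-Wright-Fisher simulation of a selection/backcross design.

The experimental design modelled here crosses a tropical donor line (SK) into
a temperate recipient background (VT) and alternates, over 16 generations,
free recombination (odd generations) with an 80% bottleneck plus a backcross
of 300 recipient-line individuals (even generations). Each recombination
window of the genome is simulated as an independent "virtual chromosome" of
diploid individuals, and sequencing of the final generation is emulated with
a two-step binomial pool-seq noise model.

Under the neutral-introgression mode the expected allele-frequency trajectory
has a closed form: each backcross event halves the residual donor (SK)
ancestry, so after ``n`` events the expected frequency is
``(1 - a) * p_vt + a * p_sk`` with ``a = (1/2)**(n+1)``. The simulator is
validated against this recurrence and against the drift-martingale property.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .windows import WindowSpec

__all__ = [
    "SimParams",
    "TrajectoryResult",
    "synthetic_cross",
    "expected_backcross_frequency",
    "poolseq_noise",
    "simulate_introgression",
    "build_envelope",
]


@dataclass(frozen=True)
class SimParams:
    """Design constants of the introgression experiment.

    Defaults are the experimental values: carrying capacity ~1500, 16
    generations, 80% embryonic mortality at even generations, 300 backcrossed
    recipient individuals per event, pools of 30 diploids sequenced at ~85x,
    and a 95% neutral envelope built from 100 replicates per window.
    """

    carrying_capacity: int = 1500
    n_generations: int = 16
    bottleneck_fraction: float = 0.80
    n_migrants: int = 300
    mutation_rate: float = 1.0e-7
    pool_diploids: int = 30
    mean_depth: float = 85.0
    envelope_quantile: float = 0.95
    n_replicates: int = 100
    constant_depth: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.bottleneck_fraction < 1.0):
            raise ValueError("bottleneck_fraction must be in (0, 1)")
        if self.n_migrants > self.carrying_capacity:
            raise ValueError("n_migrants cannot exceed carrying_capacity")
        if self.pool_diploids < 1:
            raise ValueError("pool_diploids must be >= 1")
        if self.carrying_capacity < 2:
            raise ValueError("carrying_capacity must be >= 2")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not (0.0 < self.envelope_quantile <= 1.0):
            raise ValueError("envelope_quantile must be in (0, 1]")


@dataclass
class TrajectoryResult:
    """Per-generation allele frequencies and final pooled read counts."""

    window_id: str
    mode: str
    freqs: np.ndarray  # shape (n_generations + 1, n_sites)
    alt_reads: np.ndarray  # shape (n_sites,)
    total_reads: np.ndarray  # shape (n_sites,)
    replicate: int = 0
    seed: int | None = None

    @property
    def final_freqs(self) -> np.ndarray:
        return self.freqs[-1]


def synthetic_cross(p_vt: np.ndarray, p_sk: np.ndarray) -> np.ndarray:
    """Expected F1 allele frequencies of a cross: the parental mean.

    Symmetric in its arguments; fixation in both parents is preserved.
    """
    p_vt = np.asarray(p_vt, dtype=float)
    p_sk = np.asarray(p_sk, dtype=float)
    if p_vt.shape != p_sk.shape:
        raise ValueError("parental frequency vectors must have equal length")
    for name, v in (("p_vt", p_vt), ("p_sk", p_sk)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} has entries outside [0, 1]")
    return 0.5 * (p_vt + p_sk)


def expected_backcross_frequency(
    p_vt: np.ndarray | float, p_sk: np.ndarray | float, n_backcross_events: int
) -> np.ndarray | float:
    """Closed-form expected frequency after repeated backcrossing into VT.

    Donor (SK) ancestry starts at 1/2 in the F1 and is halved by each
    backcross event: ``a = (1/2)**(n+1)``; the expected allele frequency is
    ``(1 - a) * p_vt + a * p_sk``. With ``n = 0`` this is the F1 cross.
    """
    if n_backcross_events < 0:
        raise ValueError("n_backcross_events must be >= 0")
    a = 0.5 ** (n_backcross_events + 1)
    return (1.0 - a) * np.asarray(p_vt, dtype=float) + a * np.asarray(p_sk, dtype=float)


def poolseq_noise(
    p: np.ndarray | float,
    pool_diploids: int,
    depth: np.ndarray | int,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-step binomial pool-seq noise.

    Step 1 samples ``2 * pool_diploids`` chromosomes from the population
    (Binomial on the true frequency); step 2 samples reads from the pooled
    chromosomes (Binomial on the step-1 frequency). Returns
    ``(alt_reads, total_reads)`` arrays. The compound variance of the read
    frequency is ``p(1-p) [1/n + (1 - 1/n)/depth]`` with ``n = 2*pool_diploids``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must be in [0, 1]")
    if pool_diploids < 1:
        raise ValueError("pool_diploids must be >= 1")
    depth = np.broadcast_to(np.atleast_1d(np.asarray(depth, dtype=int)), p.shape)
    if np.any(depth < 0):
        raise ValueError("depth must be >= 0")
    n_chrom = 2 * pool_diploids
    pool_freq = rng.binomial(n_chrom, p) / n_chrom
    alt = rng.binomial(depth, pool_freq)
    return alt, depth.copy()


def _recombine(
    haplos: np.ndarray,
    parent_idx: np.ndarray,
    interval_lambda: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce one gamete per entry of ``parent_idx`` with crossovers.

    Crossovers follow a Poisson process along the window: the number of
    breakpoints between adjacent tracked sites is Poisson(rho * d) per meiosis,
    realized jointly as Poisson(n_gametes * rho * d) events assigned to
    uniformly random gametes (an exact, sparse equivalent of drawing
    Poisson(rho * length) uniform breakpoints per gamete). The inherited
    haplotype at each site follows the crossover-count parity.
    """
    n_gam = len(parent_idx)
    n_sites = haplos.shape[1]
    start = rng.integers(0, 2, size=n_gam)
    # no-crossover baseline: each gamete copies one parental haplotype whole
    gametes = haplos[2 * parent_idx + start].copy()
    if n_sites > 1:
        counts = rng.poisson(n_gam * interval_lambda)
        hit = np.nonzero(counts)[0]
        if hit.size:
            ev_rows = np.concatenate(
                [rng.integers(0, n_gam, size=counts[j]) for j in hit]
            )
            ev_intervals = np.repeat(hit, counts[hit])
            for r in np.unique(ev_rows):
                flips = np.zeros(n_sites - 1, dtype=np.int64)
                np.add.at(flips, ev_intervals[ev_rows == r], 1)
                parity = np.concatenate(([start[r]], start[r] + np.cumsum(flips))) % 2
                p = parent_idx[r]
                gametes[r] = np.where(parity == 0, haplos[2 * p], haplos[2 * p + 1])
    return gametes


def _reproduce(
    haplos: np.ndarray,
    n_offspring: int,
    interval_lambda: np.ndarray,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random mating with replacement back to ``n_offspring`` individuals."""
    n_parents = haplos.shape[0] // 2
    mothers = rng.integers(0, n_parents, size=n_offspring)
    fathers = rng.integers(0, n_parents, size=n_offspring)
    gam_m = _recombine(haplos, mothers, interval_lambda, rng)
    gam_f = _recombine(haplos, fathers, interval_lambda, rng)
    offspring = np.empty((2 * n_offspring, haplos.shape[1]), dtype=np.uint8)
    offspring[0::2] = gam_m
    offspring[1::2] = gam_f
    if mutation_rate > 0:
        n_cells = offspring.size
        n_mut = rng.binomial(n_cells, mutation_rate)
        if n_mut:
            flat = rng.integers(0, n_cells, size=n_mut)
            offspring.flat[flat] = 1 - offspring.flat[flat]
    return offspring


def _draw_haplotypes(p: np.ndarray, n_individuals: int, rng: np.random.Generator) -> np.ndarray:
    """Site-independent haplotypes from a frequency vector (linkage equilibrium)."""
    return (rng.random((2 * n_individuals, len(p))) < p).astype(np.uint8)


def simulate_introgression(
    window: WindowSpec,
    params: SimParams,
    p_vt: np.ndarray,
    p_sk: np.ndarray,
    mode: str = "neutral_introgression",
    seed: int | np.random.Generator | None = None,
    replicate: int = 0,
    _survivor_weight_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> TrajectoryResult:
    """Simulate one window of the 16-generation backcross design.

    Generation 0 is a population of ``carrying_capacity`` F1 individuals whose
    haplotypes are drawn from the synthetic-cross frequencies. Odd generations
    reproduce by random mating with recombination; at even generations the
    parental pool first loses ``bottleneck_fraction`` of individuals at random
    and (``neutral_introgression`` mode only) receives ``n_migrants``
    individuals drawn from the VT frequency vector before reproducing back to
    carrying capacity. ``drift_only`` mode applies the bottleneck without
    migrants. Final pooled read counts are produced by :func:`poolseq_noise`.

    ``_survivor_weight_fn`` maps the population haplotype array (2N x L) to a
    per-individual sampling weight for bottleneck survival; it is reserved for
    the synthetic-data wrapper that layers viability selection on top of this
    otherwise neutral engine.
    """
    if mode not in ("drift_only", "neutral_introgression"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(window.sites) < 1:
        raise ValueError("window must contain at least one tracked site")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_vt = np.asarray(p_vt, dtype=float)
    p_sk = np.asarray(p_sk, dtype=float)
    if p_vt.shape != (len(window.sites),) or p_sk.shape != (len(window.sites),):
        raise ValueError("frequency vectors must match the window's site count")

    sites = np.asarray(window.sites, dtype=float)
    interval_lambda = window.rho * np.diff(sites)

    K = params.carrying_capacity
    p_f1 = synthetic_cross(p_vt, p_sk)
    pop = _draw_haplotypes(p_f1, K, rng)

    freqs = np.empty((params.n_generations + 1, len(sites)))
    freqs[0] = pop.mean(axis=0)

    n_survivors = max(1, int(round(K * (1.0 - params.bottleneck_fraction))))
    for t in range(1, params.n_generations + 1):
        parents = pop
        if t % 2 == 0:
            n_ind = parents.shape[0] // 2
            if _survivor_weight_fn is not None:
                w = np.asarray(_survivor_weight_fn(parents), dtype=float)
                w = np.clip(w, 0, None)
                if w.sum() <= 0:
                    raise RuntimeError("all survivor weights are zero")
                keep = rng.choice(n_ind, size=n_survivors, replace=False, p=w / w.sum())
            else:
                keep = rng.choice(n_ind, size=n_survivors, replace=False)
            idx = np.empty(2 * n_survivors, dtype=int)
            idx[0::2] = 2 * keep
            idx[1::2] = 2 * keep + 1
            parents = parents[idx]
            if mode == "neutral_introgression":
                migrants = _draw_haplotypes(p_vt, params.n_migrants, rng)
                parents = np.concatenate([parents, migrants], axis=0)
            if parents.shape[0] == 0:
                raise RuntimeError("no surviving parents")
        pop = _reproduce(parents, K, interval_lambda, params.mutation_rate, rng)
        freqs[t] = pop.mean(axis=0)

    if params.constant_depth:
        depth = np.full(len(sites), int(round(params.mean_depth)))
    else:
        depth = rng.poisson(params.mean_depth, size=len(sites))
    alt, total = poolseq_noise(freqs[-1], params.pool_diploids, depth, rng)
    return TrajectoryResult(
        window_id=window.id,
        mode=mode,
        freqs=freqs,
        alt_reads=alt,
        total_reads=total,
        replicate=replicate,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def build_envelope(
    replicate_stats: Mapping[str, np.ndarray], quantile: float = 0.95
) -> dict[str, float]:
    """Per-window nearest-rank quantile of a replicate statistic.

    The threshold for each window is the ``ceil(q * n)``-th order statistic of
    its replicate values — the neutral envelope against which observed window
    statistics are compared.
    """
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must be in (0, 1]")
    out: dict[str, float] = {}
    for wid, vals in replicate_stats.items():
        v = np.sort(np.asarray(vals, dtype=float))
        if v.size == 0:
            raise ValueError(f"window {wid}: empty replicate set")
        k = int(np.ceil(quantile * v.size))
        out[wid] = float(v[k - 1])
    return out
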