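"""End-to-end synthetic introgression-scan pipeline.

Chains: synthesize parents and F16 pools -> per-replicate FST vs the VT
parent -> genome-wide top-quantile flags -> per-window enrichment -> neutral
simulation envelope -> window calls -> synthetic-pool Fisher scan ->
multiplicity adjustment. Every artifact is written with the seed and a config
hash; identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .poolstats import PoolSample, pairwise_fst
from .scan import adjust_pvalues, call_significant_windows, fet_scan, flag_top_quantile, window_enrichment
from .simulate import SimParams, build_envelope, simulate_introgression
from .synth import FocalLocus, ParentalScenario, gen_f16_pools, gen_parental_pools, subseed_rng
from .windows import WindowMap, build_window_map

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "replicate_flag_counts",
    "neutral_envelope",
    "run_scan",
]


@dataclass
class RunConfig:
    """Configuration of one synthetic pipeline run."""

    seed: int = 0
    out_dir: str | None = None
    arm_window_counts: dict[str, int] = field(default_factory=lambda: {"2R": 4, "X": 4})
    arm_lengths: dict[str, int] = field(default_factory=lambda: {"2R": 600_000, "X": 600_000})
    sites_per_window: int = 25
    n_f16: int = 6
    focal_loci: list[dict] = field(default_factory=list)
    sim: SimParams = field(default_factory=SimParams)
    top_quantile: float = 0.01
    alpha: float = 0.01
    min_maf: float = 0.05
    envelope_replicates: int = 100

    def validate(self) -> None:
        if not (0 < self.top_quantile < 1):
            raise ValueError("top_quantile must lie in (0, 1)")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must lie in [0, 0.5)")
        if self.n_f16 < 1 or self.envelope_replicates < 2 or self.sites_per_window < 1:
            raise ValueError("replicate/site counts out of range")

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def replicate_flag_counts(
    f16_pools: list[PoolSample],
    vt_pool: PoolSample,
    window_ids: np.ndarray,
    top_quantile: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(window, replicate) count of genome-wide top-quantile FST SNPs.

    Each F16 pool is compared with the VT parent; flags are assigned within
    that replicate's genome-wide FST distribution; returns the long
    per-replicate table and the per-window binomial enrichment of the first
    replicate's flags pooled across replicates.
    """
    rows = []
    flags_any = []
    for pool in f16_pools:
        fst = pairwise_fst(pool, vt_pool).per_site
        flags = flag_top_quantile(fst, q=top_quantile)
        flags_any.append(flags)
        df = pd.DataFrame({"window": window_ids, "flag": flags})
        counts = df.groupby("window", sort=False)["flag"].sum()
        for wid, x in counts.items():
            rows.append({"window": wid, "replicate": pool.sample_id, "value": int(x)})
    stats_df = pd.DataFrame(rows)
    mean_flags = np.mean(flags_any, axis=0)
    enrich = window_enrichment(np.stack(flags_any).any(axis=0), window_ids, null_rate=top_quantile)
    stats_df.attrs["mean_flag_rate"] = float(np.mean(mean_flags))
    return stats_df, enrich


def neutral_envelope(
    scenario: ParentalScenario,
    vt_pool: PoolSample,
    sim: SimParams,
    n_replicates: int,
    quantile: float,
    top_quantile: float,
    seed: int | None,
) -> dict[str, float]:
    """Envelope of the per-window flag-count statistic under neutrality.

    Each envelope replicate simulates one neutral-introgression F16 genome,
    computes FST against the VT parent pool, flags the top quantile within
    the simulated genome-wide distribution, and counts flags per window; the
    envelope is the per-window nearest-rank ``quantile`` of those counts.
    """
    offsets = scenario.window_offsets()
    window_ids = np.concatenate(
        [np.repeat(w.id, len(w.sites)) for w in scenario.window_map]
    )
    per_window: dict[str, list[float]] = {w.id: [] for w in scenario.window_map}
    for e in range(n_replicates):
        alts, totals = [], []
        for wi, w in enumerate(scenario.window_map):
            lo = offsets[w.id]
            res = simulate_introgression(
                w,
                sim,
                scenario.vt_freqs[lo : lo + len(w.sites)],
                scenario.sk_freqs[lo : lo + len(w.sites)],
                "neutral_introgression",
                subseed_rng(seed, 7, e, wi),
                replicate=e,
            )
            alts.append(res.alt_reads)
            totals.append(res.total_reads)
        sim_pool = PoolSample(
            sample_id=f"sim_{e}",
            role="F16",
            alt=np.concatenate(alts),
            total=np.concatenate(totals),
            n_chromosomes=2 * sim.pool_diploids,
        )
        fst = pairwise_fst(sim_pool, vt_pool).per_site
        flags = flag_top_quantile(fst, q=top_quantile)
        counts = pd.DataFrame({"window": window_ids, "flag": flags}).groupby(
            "window", sort=False
        )["flag"].sum()
        for wid, x in counts.items():
            per_window[wid].append(float(x))
    return build_envelope({k: np.array(v) for k, v in per_window.items()}, quantile)


def run_scan(
    scenario: ParentalScenario,
    sim: SimParams | None = None,
    n_f16: int = 6,
    envelope_replicates: int = 25,
    top_quantile: float = 0.01,
    seed: int | None = None,
) -> dict:
    """One full window-scan on a parental scenario: pools, flags, envelope, calls.

    Returns a dict with the parental truth, per-replicate flag counts, the
    neutral envelope, and the window call table (merged with truth labels).
    """
    sim = sim or SimParams()
    vt_pool, sk_pool, truth = gen_parental_pools(scenario, seed=seed)
    f16_pools, window_truth = gen_f16_pools(scenario, sim, n_replicates=n_f16, seed=seed)
    stats_df, enrich = replicate_flag_counts(
        f16_pools, vt_pool, truth["window"].to_numpy(), top_quantile
    )
    envelope = neutral_envelope(
        scenario, vt_pool, sim, envelope_replicates,
        sim.envelope_quantile, top_quantile, seed,
    )
    calls = call_significant_windows(stats_df, envelope).merge(window_truth, on="window")
    return {
        "truth": truth,
        "window_truth": window_truth,
        "replicate_stats": stats_df,
        "enrichment": enrich,
        "envelope": envelope,
        "calls": calls,
        "pools": {"VT": vt_pool, "SK": sk_pool, "F16": f16_pools},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic scan; returns the result bundle.

    Stage order: windows -> parental truth -> F16 simulation -> FST -> flags
    -> enrichment -> neutral envelope -> window calls -> FET -> adjustment.
    When ``config.out_dir`` is set, every table is written as TSV along with
    a JSON run record (seed, config hash).
    """
    config.validate()
    stage = "windows"
    try:
        wmap: WindowMap = build_window_map(
            config.arm_window_counts,
            config.arm_lengths,
            n_sites_per_window=config.sites_per_window,
            seed=config.seed,
        )
        stage = "synthesize"
        focal = [FocalLocus(**d) for d in config.focal_loci]
        scenario = ParentalScenario.random(
            wmap, focal_loci=focal, seed=config.seed,
            pool_diploids=config.sim.pool_diploids, mean_depth=config.sim.mean_depth,
        )
        stage = "scan"
        scan = run_scan(
            scenario,
            config.sim,
            n_f16=config.n_f16,
            envelope_replicates=config.envelope_replicates,
            top_quantile=config.top_quantile,
            seed=config.seed,
        )
        truth = scan["truth"]
        window_truth = scan["window_truth"]
        stats_df, enrich = scan["replicate_stats"], scan["enrichment"]
        envelope, calls = scan["envelope"], scan["calls"]
        vt_pool, sk_pool = scan["pools"]["VT"], scan["pools"]["SK"]
        f16_pools = scan["pools"]["F16"]
        stage = "fet"
        fet = fet_scan(
            f16_pools,
            vt_pool,
            min_maf=config.min_maf,
            arms=truth["arm"].to_numpy(),
            positions=truth["pos"].to_numpy(),
        ).table
        if len(fet):
            fet["bonferroni_threshold"] = adjust_pvalues(
                fet["p"].to_numpy(), method="bonferroni", alpha=config.alpha
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "truth": truth,
        "window_truth": window_truth,
        "replicate_stats": stats_df,
        "enrichment": enrich,
        "envelope": envelope,
        "calls": calls,
        "fet": fet,
        "pools": {"VT": vt_pool, "SK": sk_pool, "F16": f16_pools},
    }
    if config.out_dir:
        out = pio.ensure_dir(config.out_dir)
        record = {"seed": config.seed, "config_hash": bundle["config_hash"]}
        (out / "run.json").write_text(json.dumps(record, indent=2, sort_keys=True))
        for name in ("truth", "window_truth", "replicate_stats", "enrichment", "calls", "fet"):
            bundle[name].to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        pd.Series(envelope, name="threshold").rename_axis("window").reset_index().to_csv(
            out / "envelope.tsv", sep="\t", index=False, float_format="%.6g"
        )
        pio.write_sync(out / "pools.sync", [vt_pool, sk_pool, *f16_pools])
        logger.info("pipeline run %s written to %s", bundle["config_hash"], out)
    return bundle
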