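"""Synthetic-data generators with the statistical structure the analyses assume.

Every generator is seeded and emits a truth table alongside the observable
data, so each downstream stage can be tested against a known ground truth
without any external download. Sub-streams are derived from the master seed
by seeding ``numpy`` generators with ``[master_seed, *counters]``, making
replicates independent yet reproducible.

What is emulated: two divergent parental pools (SK fixed at focal loci, VT
polymorphic), six F16 pools that are VT-like genome-wide except in selected
windows, two-step binomial read noise at ~85x from 30 diploids, seasonal
allele-frequency series driven by a lagged environmental summary on the logit
scale, line panels with a purely epistatic two-locus survival effect, and
negative-binomial expression counts with a background x temperature
interaction. Real linkage structure, inversions and demography are not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .eco import lag_summary
from .poolstats import PoolSample, effective_coverage
from .simulate import SimParams, poolseq_noise, simulate_introgression
from .windows import WindowMap

__all__ = [
    "FocalLocus",
    "ParentalScenario",
    "SeasonalScenario",
    "PanelScenario",
    "subseed_rng",
    "gen_parental_pools",
    "gen_f16_pools",
    "gen_seasonal_series",
    "gen_line_panel",
    "gen_expression_counts",
]

GENOTYPE_CLASSES = (
    "tropical_tropical",
    "tropical_temperate",
    "temperate_tropical",
    "temperate_temperate",
)
_CLASS_ALLELES = {
    "tropical_tropical": ("C", "T"),
    "tropical_temperate": ("C", "A"),
    "temperate_tropical": ("A", "T"),
    "temperate_temperate": ("A", "A"),
}


def subseed_rng(
    master_seed: int | list[int] | tuple[int, ...] | None, *stream: int
) -> np.random.Generator:
    """Independent reproducible sub-stream: seeded with [*master, *counters]."""
    if master_seed is None:
        return np.random.default_rng()
    base = list(master_seed) if isinstance(master_seed, (list, tuple)) else [master_seed]
    return np.random.default_rng([*base, *stream])


@dataclass(frozen=True)
class FocalLocus:
    """A selected site: window id, site index within the window, parental
    frequencies of the scored allele, and viability selection strength."""

    window_id: str
    site_index: int
    vt_freq: float
    sk_freq: float
    selection_strength: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("vt_freq", self.vt_freq), ("sk_freq", self.sk_freq)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")


@dataclass
class ParentalScenario:
    """Parental allele-frequency truth over a window map.

    ``vt_freqs``/``sk_freqs`` are per-site vectors in window order (each
    window contributes ``len(window.sites)`` entries). Non-focal background
    sites are intended to be intermediate-frequency in both parents; focal
    loci typically have the SK parent fixed for the tropical allele.
    """

    window_map: WindowMap
    vt_freqs: np.ndarray
    sk_freqs: np.ndarray
    focal_loci: list[FocalLocus] = field(default_factory=list)
    pool_diploids: int = 30
    mean_depth: float = 85.0

    def __post_init__(self) -> None:
        self.vt_freqs = np.asarray(self.vt_freqs, dtype=float)
        self.sk_freqs = np.asarray(self.sk_freqs, dtype=float)
        if self.n_snps == 0:
            raise ValueError("scenario has no sites")
        if self.vt_freqs.shape != (self.n_snps,) or self.sk_freqs.shape != (self.n_snps,):
            raise ValueError("frequency vectors must match total site count")
        for v in (self.vt_freqs, self.sk_freqs):
            if np.any((v < 0) | (v > 1)):
                raise ValueError("frequencies outside [0, 1]")
        offsets = self.window_offsets()
        for loc in self.focal_loci:
            if loc.window_id not in offsets:
                raise ValueError(f"focal locus window {loc.window_id!r} not in map")
            w = self.window_map[loc.window_id]
            if not (0 <= loc.site_index < len(w.sites)):
                raise ValueError(f"focal site index {loc.site_index} outside {loc.window_id}")
            gi = offsets[loc.window_id] + loc.site_index
            self.vt_freqs[gi] = loc.vt_freq
            self.sk_freqs[gi] = loc.sk_freq

    @property
    def n_snps(self) -> int:
        return sum(len(w.sites) for w in self.window_map)

    def window_offsets(self) -> dict[str, int]:
        off, total = {}, 0
        for w in self.window_map:
            off[w.id] = total
            total += len(w.sites)
        return off

    def site_frame(self) -> pd.DataFrame:
        arms, pos, wins = [], [], []
        for w in self.window_map:
            arms += [w.arm] * len(w.sites)
            pos += list(w.sites)
            wins += [w.id] * len(w.sites)
        sel = {(l.window_id, l.site_index): l.selection_strength for l in self.focal_loci}
        offsets = self.window_offsets()
        s = np.zeros(self.n_snps)
        for (wid, si), v in sel.items():
            s[offsets[wid] + si] = v
        return pd.DataFrame(
            {
                "arm": arms,
                "pos": pos,
                "window": wins,
                "vt_freq": self.vt_freqs,
                "sk_freq": self.sk_freqs,
                "selection_strength": s,
            }
        )

    @classmethod
    def random(
        cls,
        window_map: WindowMap,
        focal_loci: list[FocalLocus] | None = None,
        seed: int | None = None,
        **kwargs,
    ) -> "ParentalScenario":
        """Background parental divergence: independent Beta(0.8, 0.8)
        frequencies truncated to [0.05, 0.95] in each parent, emulating the
        intermediate-frequency SNP spectrum that pool-seq variant filters
        retain."""
        rng = subseed_rng(seed, 0)
        n = sum(len(w.sites) for w in window_map)

        def draw() -> np.ndarray:
            out = rng.beta(0.8, 0.8, size=n)
            while True:
                bad = (out < 0.05) | (out > 0.95)
                if not bad.any():
                    return out
                out[bad] = rng.beta(0.8, 0.8, size=int(bad.sum()))

        return cls(window_map, draw(), draw(), focal_loci or [], **kwargs)

    @classmethod
    def correlated(
        cls,
        window_map: WindowMap,
        parental_fst: float = 0.1,
        focal_loci: list[FocalLocus] | None = None,
        seed: int | None = None,
        **kwargs,
    ) -> "ParentalScenario":
        """Backgrounds with shared ancestry: both parents drawn around one
        ancestral frequency with Balding-Nichols divergence ``parental_fst``.

        This is the variant used for scan power studies: most of the genome
        is moderately divergent shared polymorphism, so differentiation
        signal is concentrated at planted focal loci, as in a real parental
        pair."""
        if not (0.0 < parental_fst < 1.0):
            raise ValueError("parental_fst must lie in (0, 1)")
        rng = subseed_rng(seed, 6)
        n = sum(len(w.sites) for w in window_map)
        anc = np.clip(rng.beta(0.8, 0.8, n), 0.1, 0.9)
        a = anc * (1 - parental_fst) / parental_fst
        b = (1 - anc) * (1 - parental_fst) / parental_fst
        vt = np.clip(rng.beta(a, b), 0.02, 0.98)
        sk = np.clip(rng.beta(a, b), 0.02, 0.98)
        return cls(window_map, vt, sk, focal_loci or [], **kwargs)


def demo_scan_scenario(
    seed: int | None = None,
    selected: bool = True,
    arm_window_counts: dict[str, int] | None = None,
    sites_per_window: int = 60,
    n_selected: int = 8,
    selection_strength: float = 100.0,
) -> tuple[ParentalScenario, str]:
    """Standard planted-window scenario for end-to-end scan studies.

    Twelve ~75 kb windows across two arms; one window on 2R carries
    ``n_selected`` SK-fixed differences (absent from VT) under strong
    viability selection — the configuration that mimics a mapped
    heat-tolerance haplotype. With ``selected=False`` the same genome evolves
    neutrally (for false-call calibration). Returns the scenario and the
    planted window's id.
    """
    from .windows import build_window_map

    counts = arm_window_counts or {"2R": 6, "X": 6}
    lengths = {arm: 150_000 * k // 2 for arm, k in counts.items()}
    wmap = build_window_map(counts, lengths, n_sites_per_window=sites_per_window, seed=seed)
    wid = wmap[2].id
    sel_idx = np.unique(np.linspace(3, sites_per_window - 3, n_selected).astype(int))
    s = selection_strength if selected else 0.0
    focal = [FocalLocus(wid, int(si), 0.0, 1.0, s) for si in sel_idx]
    return ParentalScenario.correlated(wmap, 0.1, focal, seed), wid


def gen_parental_pools(
    scenario: ParentalScenario,
    seed: int | None = None,
    constant_depth: bool = False,
) -> tuple[PoolSample, PoolSample, pd.DataFrame]:
    """Sequence the two parental pools under the two-step binomial noise model.

    Returns (VT pool, SK pool, truth table with per-site parental
    frequencies). Depth is Poisson around the scenario's mean unless
    ``constant_depth`` is set.
    """
    if scenario.mean_depth <= 0:
        raise ValueError("mean depth must be > 0")
    truth = scenario.site_frame()
    samples = []
    for k, (role, freqs) in enumerate(
        [("parent_VT", scenario.vt_freqs), ("parent_SK", scenario.sk_freqs)]
    ):
        rng = subseed_rng(seed, 1, k)
        if constant_depth:
            depth = np.full(scenario.n_snps, int(round(scenario.mean_depth)))
        else:
            depth = rng.poisson(scenario.mean_depth, size=scenario.n_snps)
        alt, total = poolseq_noise(freqs, scenario.pool_diploids, depth, rng)
        samples.append(
            PoolSample(
                sample_id=role.split("_")[1],
                role=role,
                alt=alt,
                total=total,
                n_chromosomes=2 * scenario.pool_diploids,
                arms=truth["arm"].to_numpy(),
                positions=truth["pos"].to_numpy(),
            )
        )
    return samples[0], samples[1], truth


def _selection_weight_fn(focal_idx: np.ndarray, orientation: np.ndarray, s: np.ndarray):
    """Viability weight 1 + s * (tropical-allele dosage) per individual.

    ``orientation`` is +1 where the scored allele is the tropical (SK) one
    and -1 where the tropical allele is the reference.
    """

    def weights(haplos: np.ndarray) -> np.ndarray:
        geno = haplos[0::2][:, focal_idx] + haplos[1::2][:, focal_idx]
        dosage = np.where(orientation > 0, geno, 2 - geno)
        return 1.0 + dosage @ s

    return weights


def gen_f16_pools(
    scenario: ParentalScenario,
    sim: SimParams | None = None,
    n_replicates: int = 6,
    seed: int | None = None,
) -> tuple[list[PoolSample], pd.DataFrame]:
    """Simulate replicate F16 introgression pools over the scenario's windows.

    Windows without a selected focal locus evolve under the neutral backcross
    design; in windows with ``selection_strength > 0`` bottleneck survivors
    are sampled with weight ``1 + s * tropical_dosage``, the genotype-level
    stand-in for selection on the heat-tolerance phenotype. Returns the F16
    pools and a per-window truth table with ``true_positive`` labels.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sim = sim or SimParams()
    offsets = scenario.window_offsets()
    truth_rows = []
    window_focals: dict[str, list[FocalLocus]] = {w.id: [] for w in scenario.window_map}
    for loc in scenario.focal_loci:
        window_focals[loc.window_id].append(loc)
    pools: list[PoolSample] = []
    for r in range(n_replicates):
        alts, totals, arms, positions = [], [], [], []
        for wi, w in enumerate(scenario.window_map):
            lo = offsets[w.id]
            p_vt = scenario.vt_freqs[lo : lo + len(w.sites)]
            p_sk = scenario.sk_freqs[lo : lo + len(w.sites)]
            focals = [l for l in window_focals[w.id] if l.selection_strength > 0]
            weight_fn = None
            if focals:
                idx = np.array([l.site_index for l in focals])
                orient = np.array(
                    [1.0 if l.sk_freq >= l.vt_freq else -1.0 for l in focals]
                )
                s = np.array([l.selection_strength for l in focals])
                weight_fn = _selection_weight_fn(idx, orient, s)
            rng = subseed_rng(seed, 2, r, wi)
            res = simulate_introgression(
                w, sim, p_vt, p_sk, "neutral_introgression", rng,
                replicate=r, _survivor_weight_fn=weight_fn,
            )
            alts.append(res.alt_reads)
            totals.append(res.total_reads)
            arms += [w.arm] * len(w.sites)
            positions += list(w.sites)
        pools.append(
            PoolSample(
                sample_id=f"F16_{r + 1}",
                role="F16",
                alt=np.concatenate(alts),
                total=np.concatenate(totals),
                n_chromosomes=2 * sim.pool_diploids,
                arms=np.array(arms, dtype=object),
                positions=np.array(positions),
            )
        )
    for w in scenario.window_map:
        truth_rows.append(
            {
                "window": w.id,
                "true_positive": any(
                    l.selection_strength > 0 for l in window_focals[w.id]
                ),
            }
        )
    return pools, pd.DataFrame(truth_rows)


@dataclass
class SeasonalScenario:
    """Seasonal sampling design for one focal SNP.

    The true allele frequency at each collection is
    ``invlogit(logit(baseline) + beta_seasonal * z)`` where ``z`` is the
    z-scored lagged environmental summary; the observed frequency adds
    two-step binomial pool noise. The environmental series is a sinusoidal
    annual cycle plus AR(1) noise — seasonal structure without real weather.
    """

    localities: list[str] = field(default_factory=lambda: ["Charlottesville"])
    latitudes: dict[str, float] = field(default_factory=lambda: {"Charlottesville": 38.03})
    years: list[int] = field(default_factory=lambda: [2016, 2017, 2018])
    collections_per_year: int = 10
    beta_seasonal: float = -0.089
    baseline_freq: float = 0.6
    lag_days: int = 45
    statistic: str = "sd"
    pool_diploids: int = 30
    mean_depth: float = 85.0
    env_mean: float = 18.0
    env_amplitude: float = 8.0
    ar_phi: float = 0.7
    ar_sd: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_freq < 1.0):
            raise ValueError("baseline_freq must lie in (0, 1)")
        if not np.isfinite(self.beta_seasonal):
            raise ValueError("beta_seasonal must be finite")
        if self.collections_per_year < 1 or not self.years or not self.localities:
            raise ValueError("design must contain at least one collection")


def gen_seasonal_series(
    scenario: SeasonalScenario, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a seasonal allele-frequency series plus its environmental table.

    Returns ``(samples, env)``: samples have observed ``freq``, ``n_e``, the
    lagged summary ``env``, and the latent truth columns ``true_freq`` /
    ``true_z``; env is a daily (date, variable, value) table covering every
    lag window. Raises if the lag summaries are constant (degenerate design).
    """
    rng = subseed_rng(seed, 3)
    dates: list[pd.Timestamp] = []
    locs: list[str] = []
    for loc in scenario.localities:
        for year in scenario.years:
            season = pd.date_range(f"{year}-06-01", f"{year}-10-31", freq="D")
            picks = np.linspace(0, len(season) - 1, scenario.collections_per_year).astype(int)
            dates += [season[i] for i in picks]
            locs += [loc] * scenario.collections_per_year
    start = min(dates) - pd.Timedelta(days=max(LAGS_MAX, scenario.lag_days))
    days = pd.date_range(start, max(dates), freq="D")
    doy = days.dayofyear.to_numpy()
    seasonal = scenario.env_mean + scenario.env_amplitude * np.sin(
        2 * np.pi * (doy - 110) / 365.25
    )
    noise = np.empty(len(days))
    eps = rng.normal(0, scenario.ar_sd, size=len(days))
    noise[0] = eps[0]
    for t in range(1, len(days)):
        noise[t] = scenario.ar_phi * noise[t - 1] + eps[t]
    env_series = pd.Series(seasonal + noise, index=days)

    summary = np.array(
        [lag_summary(env_series, d, scenario.lag_days, scenario.statistic) for d in dates]
    )
    sd = summary.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate design: lagged environmental summary is constant")
    z = (summary - summary.mean()) / sd
    true_freq = expit(logit(scenario.baseline_freq) + scenario.beta_seasonal * z)

    n_chrom = 2 * scenario.pool_diploids
    depth = np.maximum(rng.poisson(scenario.mean_depth, size=len(dates)), 1)
    alt, total = poolseq_noise(true_freq, scenario.pool_diploids, depth, rng)
    samples = pd.DataFrame(
        {
            "sample_id": [f"{l}_{d.date()}" for l, d in zip(locs, dates)],
            "locality": locs,
            "latitude": [scenario.latitudes.get(l, np.nan) for l in locs],
            "date": dates,
            "freq": alt / total,
            "n_e": effective_coverage(float(n_chrom), total.astype(float)),
            "env": summary,
            "true_freq": true_freq,
            "true_z": z,
        }
    )
    env = pd.DataFrame(
        {"date": days.strftime("%Y-%m-%d"), "variable": "temperature", "value": env_series.values}
    )
    return samples, env


LAGS_MAX = 90


@dataclass
class PanelScenario:
    """Inbred line panel with a purely epistatic two-locus survival effect.

    Only the doubly-tropical class receives ``epistatic_effect`` (an additive
    logit shift); all other classes share ``base_survival``. Class
    frequencies default to the observed mix of homozygous combinations in
    reference panels (roughly 0.35/0.20/0.12/0.33).
    """

    n_lines: int = 64
    class_probs: tuple[float, float, float, float] = (0.12, 0.35, 0.20, 0.33)
    base_survival: float = 0.25
    epistatic_effect: float = 1.5
    embryos_per_line: int = 100

    def __post_init__(self) -> None:
        if self.n_lines < 8:
            raise ValueError("panel needs >= 8 lines so all classes can appear")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs <= 0) or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("class_probs must be 4 positive values summing to 1")
        if np.any(self.n_lines * probs < 1):
            raise ValueError("class_probs imply an expected class count < 1")
        if not (0.0 < self.base_survival < 1.0):
            raise ValueError("base_survival must lie in (0, 1)")
        shifted = expit(logit(self.base_survival) + self.epistatic_effect)
        if not (0.0 < shifted < 1.0):
            raise ValueError("epistatic class survival leaves (0, 1)")
        if self.embryos_per_line < 1:
            raise ValueError("embryos_per_line must be >= 1")


def gen_line_panel(scenario: PanelScenario, seed: int | None = None) -> pd.DataFrame:
    """Generate a two-locus line panel with binomial survival counts.

    Genotype classes are drawn multinomially (redrawing until all four
    classes are represented, per the design precondition); survival counts
    are Binomial(embryos_per_line, class survival), where only the
    tropical_tropical class carries the epistatic logit shift. Covariate
    columns (wolbachia, In2Lt, In2RNS) are generated without any effect.
    """
    rng = subseed_rng(seed, 4)
    probs = np.asarray(scenario.class_probs, dtype=float)
    while True:
        counts = rng.multinomial(scenario.n_lines, probs)
        if np.all(counts >= 1):
            break
    classes = np.repeat(GENOTYPE_CLASSES, counts)
    p_class = {
        c: expit(
            logit(scenario.base_survival)
            + (scenario.epistatic_effect if c == "tropical_tropical" else 0.0)
        )
        for c in GENOTYPE_CLASSES
    }
    p = np.array([p_class[c] for c in classes])
    survived = rng.binomial(scenario.embryos_per_line, p)
    return pd.DataFrame(
        {
            "line": [f"line_{i + 1}" for i in range(scenario.n_lines)],
            "allele_2R": [_CLASS_ALLELES[c][0] for c in classes],
            "allele_X": [_CLASS_ALLELES[c][1] for c in classes],
            "wolbachia": rng.integers(0, 2, scenario.n_lines),
            "In2Lt": rng.integers(0, 2, scenario.n_lines),
            "In2RNS": rng.integers(0, 2, scenario.n_lines),
            "survived": survived,
            "assayed": scenario.embryos_per_line,
            "genotype_class": classes,
            "true_p": p,
        }
    )


def gen_expression_counts(
    n_genes: int,
    backgrounds: list[str] | None = None,
    temperatures: list[str] | None = None,
    n_replicates: int = 3,
    interaction_effect: float = 0.0,
    carrier_fraction: float = 1.0,
    dispersion: float = 0.1,
    norm_factors: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Negative-binomial count matrix for a backgrounds x temperatures design.

    The log-scale mean is baseline + background effect + temperature effect +
    interaction + log(norm factor); ``interaction_effect`` is a log2 fold
    change applied, for carrier genes only, to every non-reference background
    in the heated condition. Returns (counts gene x sample, sample sheet,
    boolean carrier vector).
    """
    backgrounds = backgrounds or ["VT", "SK", "F16"]
    temperatures = temperatures or ["25C", "34C"]
    if len(backgrounds) < 2 or len(temperatures) != 2:
        raise ValueError("design needs >= 2 backgrounds and exactly 2 temperatures")
    if n_replicates < 2:
        raise ValueError("need replicates in every design cell")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = subseed_rng(seed, 5)
    sheet = pd.DataFrame(
        [
            {"sample_id": f"{b}_{t}_{r + 1}", "background": b, "temperature": t}
            for b in backgrounds
            for t in temperatures
            for r in range(n_replicates)
        ]
    )
    n_samples = len(sheet)
    if norm_factors is None:
        norm_factors = np.exp(rng.normal(0, 0.15, size=n_samples))
    norm_factors = np.asarray(norm_factors, dtype=float)
    if norm_factors.shape != (n_samples,) or np.any(norm_factors <= 0):
        raise ValueError("norm_factors must be positive, one per sample")
    sheet["norm_factor"] = norm_factors

    carriers = rng.random(n_genes) < carrier_fraction
    base = rng.uniform(np.log(50), np.log(800), size=n_genes)
    bg_eff = rng.normal(0, 0.3, size=(n_genes, len(backgrounds)))
    bg_eff[:, 0] = 0.0
    temp_eff = rng.normal(0, 0.3, size=n_genes)
    beta_int = interaction_effect * np.log(2.0)

    bg_idx = sheet["background"].map({b: i for i, b in enumerate(backgrounds)}).to_numpy()
    hot = (sheet["temperature"] == temperatures[1]).to_numpy()
    log_mu = (
        base[:, None]
        + bg_eff[:, bg_idx]
        + np.outer(temp_eff, hot)
        + beta_int * (carriers[:, None] & (bg_idx != 0) & hot)
        + np.log(norm_factors)[None, :]
    )
    mu = np.exp(log_mu)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(
        counts, index=[f"gene_{g + 1}" for g in range(n_genes)], columns=sheet["sample_id"]
    )
    return counts_df, sheet, carriers
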