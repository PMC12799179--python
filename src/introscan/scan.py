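"""Outlier scanning: top-quantile FST flags, window enrichment, envelope calls,
and the synthetic-pool Fisher's exact SNP scan with multiplicity control.

The scan logic depends only on the ranks of the differentiation statistic: a
fixed fraction of sites is flagged genome-wide, each window's flag count is
tested against the implied binomial null, and windows are called significant
only when every F16 replicate exceeds the window's neutral-simulation
envelope threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .poolstats import PoolSample

logger = logging.getLogger(__name__)

__all__ = [
    "WindowEnrichment",
    "FetResult",
    "flag_top_quantile",
    "window_enrichment",
    "call_significant_windows",
    "fet_scan",
    "adjust_pvalues",
]


@dataclass
class WindowEnrichment:
    window_id: str
    n_snps: int
    n_flagged: int
    p_value: float


def flag_top_quantile(values: np.ndarray, q: float = 0.01, min_values: int = 100) -> np.ndarray:
    """Flag the genome-wide top fraction ``q`` of a statistic by rank.

    Exactly ``ceil(q * n)`` of the ``n`` defined values are flagged; ties at
    the cutoff are broken by stable input order (earlier sites win). NaN
    entries are never flagged. Because only ranks are used, flags are
    invariant under any strictly increasing transform of the statistic.
    """
    values = np.asarray(values, dtype=float)
    defined = ~np.isnan(values)
    n = int(defined.sum())
    if n == 0:
        raise ValueError("all values undefined")
    if n < min_values:
        raise ValueError(f"need >= {min_values} defined values, got {n}")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    m = int(np.ceil(q * n))
    idx = np.nonzero(defined)[0]
    # stable sort descending by value, ascending by original index on ties
    order = idx[np.argsort(-values[idx], kind="stable")]
    flags = np.zeros(values.size, dtype=bool)
    flags[order[:m]] = True
    return flags


def window_enrichment(
    flags: np.ndarray, window_ids: np.ndarray, null_rate: float = 0.01
) -> pd.DataFrame:
    """Binomial enrichment of flagged sites per window.

    Null hypothesis: a fraction ``null_rate`` of the ``k`` SNPs in any window
    is flagged; the reported p is the exact upper tail
    ``P[Binomial(k, null_rate) >= x]``. Sites with window id ``None``/NaN are
    ignored; empty windows cannot arise (windows are keyed by their sites).
    """
    flags = np.asarray(flags, dtype=bool)
    window_ids = np.asarray(window_ids, dtype=object)
    if flags.shape != window_ids.shape:
        raise ValueError("flags and window assignment must align")
    rows = []
    df = pd.DataFrame({"window": window_ids, "flag": flags}).dropna(subset=["window"])
    for wid, grp in df.groupby("window", sort=False):
        k = len(grp)
        x = int(grp["flag"].sum())
        p = float(stats.binom.sf(x - 1, k, null_rate)) if x > 0 else 1.0
        rows.append(WindowEnrichment(str(wid), k, x, p))
    return pd.DataFrame(
        {
            "window": [r.window_id for r in rows],
            "n_snps": [r.n_snps for r in rows],
            "n_flagged": [r.n_flagged for r in rows],
            "p": [r.p_value for r in rows],
        }
    )


def call_significant_windows(
    replicate_stats: pd.DataFrame, envelope: dict[str, float]
) -> pd.DataFrame:
    """Call windows where every F16 replicate exceeds its neutral envelope.

    ``replicate_stats`` holds one row per (window, replicate) with a ``value``
    column computed with the same statistic as the envelope (the per-window
    count of genome-wide top-quantile SNPs). A window is significant iff the
    statistic strictly exceeds the envelope threshold in all replicates;
    per-replicate exceedance counts are reported alongside.
    """
    required = {"window", "replicate", "value"}
    if not required.issubset(replicate_stats.columns):
        raise ValueError(f"replicate_stats needs columns {sorted(required)}")
    rows = []
    for wid, grp in replicate_stats.groupby("window", sort=False):
        if wid not in envelope:
            raise KeyError(f"window {wid!r} missing from envelope")
        thr = envelope[wid]
        exceed = grp["value"].to_numpy() > thr
        rows.append(
            {
                "window": wid,
                "threshold": thr,
                "n_replicates": len(grp),
                "n_exceeding": int(exceed.sum()),
                "significant": bool(exceed.all()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FetResult:
    table: pd.DataFrame  # site-level results

    def __len__(self) -> int:
        return len(self.table)


def fet_scan(
    f16_pools: list[PoolSample],
    vt_pool: PoolSample,
    min_maf: float = 0.05,
    arms: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> FetResult:
    """Fisher's exact test of a synthetic F16 pool against the VT parent.

    The synthetic pool sums alt and total read counts element-wise over all
    F16 pools; at each site the 2x2 table is
    ``[[alt_syn, ref_syn], [alt_vt, ref_vt]]`` and a two-sided exact p is
    computed. Sites with pooled minor-allele frequency <= ``min_maf`` (over
    synthetic pool plus parent) are excluded, as are zero-coverage sites
    (skipped with a log entry). BH q-values and the Bonferroni flag at 0.01
    are left to :func:`adjust_pvalues`.
    """
    if not f16_pools:
        raise ValueError("need at least one F16 pool")
    n_sites = vt_pool.n_sites
    for p in f16_pools:
        if p.n_sites != n_sites:
            raise ValueError("pools must cover the same aligned sites")
    alt_syn = np.sum([p.alt for p in f16_pools], axis=0)
    tot_syn = np.sum([p.total for p in f16_pools], axis=0)
    alt_vt, tot_vt = vt_pool.alt, vt_pool.total

    zero = (tot_syn == 0) | (tot_vt == 0)
    if np.any(zero):
        logger.info("fet_scan: skipping %d zero-coverage sites", int(zero.sum()))
    pooled = (alt_syn + alt_vt) / np.maximum(tot_syn + tot_vt, 1)
    maf = np.minimum(pooled, 1 - pooled)
    keep = (~zero) & (maf > min_maf)

    if positions is None:
        positions = np.arange(1, n_sites + 1)
    if arms is None:
        arms = np.repeat("NA", n_sites)
    rows = []
    for i in np.nonzero(keep)[0]:
        tab = [
            [int(alt_syn[i]), int(tot_syn[i] - alt_syn[i])],
            [int(alt_vt[i]), int(tot_vt[i] - alt_vt[i])],
        ]
        _, p = stats.fisher_exact(tab, alternative="two-sided")
        rows.append(
            {
                "arm": arms[i],
                "pos": int(positions[i]),
                "alt_syn": tab[0][0],
                "ref_syn": tab[0][1],
                "alt_vt": tab[1][0],
                "ref_vt": tab[1][1],
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows, columns=["arm", "pos", "alt_syn", "ref_syn", "alt_vt", "ref_vt", "p"])
    if len(table):
        table["q"] = adjust_pvalues(table["p"].to_numpy(), method="bh")
        table["bonferroni_significant"] = table["p"].to_numpy() < adjust_pvalues(
            table["p"].to_numpy(), method="bonferroni", alpha=0.01
        )
    return FetResult(table=table)


def adjust_pvalues(
    pvals: np.ndarray, method: str = "bh", alpha: float = 0.05
) -> np.ndarray | float:
    """Multiple-testing adjustment.

    ``method="bh"`` returns Benjamini-Hochberg step-up q-values (monotone,
    capped at 1); ``method="bonferroni"`` returns the family-wise threshold
    ``alpha / m`` against which raw p-values are compared.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        return multipletests(pvals, method="fdr_bh")[1]
    if method == "bonferroni":
        return alpha / pvals.size
    raise ValueError(f"unknown method {method!r}")
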