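"""Pool-seq summary statistics: effective coverage, FST, PCA, distance ratios.

Pooled sequencing yields per-site read counts rather than genotypes, so every
estimator here corrects for the double sampling inherent to pools: first of
``n`` chromosomes into the pool, then of reads from those chromosomes. The
"effective coverage" ``n_e = n r / (n + r)`` summarizes the resulting
information content and the FST estimator removes the with-replacement read
sampling bias through identity probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "PoolSample",
    "PcaResult",
    "FstResult",
    "effective_coverage",
    "pairwise_fst",
    "pca_global",
    "pca_sliding",
    "parent_distance_ratio",
]


def effective_coverage(n: np.ndarray | float, r: np.ndarray | float) -> np.ndarray | float:
    """Effective number of independently sampled chromosomes in a pool.

    ``n_e = n * r / (n + r)`` for a pool of ``n`` chromosomes sequenced to
    read depth ``r``; monotone in both arguments and bounded by each.
    """
    n = np.asarray(n, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(n < 2):
        raise ValueError("pool chromosome count must be >= 2")
    if np.any(r < 1):
        raise ValueError("read depth must be >= 1")
    out = n * r / (n + r)
    return float(out) if out.ndim == 0 else out


@dataclass
class PoolSample:
    """Per-site allele counts for one pooled library."""

    sample_id: str
    role: str  # parent_VT | parent_SK | F16 | wild
    alt: np.ndarray
    total: np.ndarray
    n_chromosomes: int
    arms: np.ndarray | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alt = np.asarray(self.alt, dtype=int)
        self.total = np.asarray(self.total, dtype=int)
        if self.alt.shape != self.total.shape:
            raise ValueError("alt and total must align")
        if np.any(self.alt < 0) or np.any(self.alt > self.total):
            raise ValueError("require 0 <= alt <= total at every site")
        if self.n_chromosomes < 2:
            raise ValueError("pool must hold >= 2 chromosomes")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=int)
        if self.arms is not None:
            self.arms = np.asarray(self.arms, dtype=object)

    @property
    def n_sites(self) -> int:
        return self.alt.size

    @property
    def freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.alt / self.total, np.nan)

    @property
    def effective_coverage(self) -> np.ndarray:
        """Per-site n_e; NaN where depth is zero."""
        out = np.full(self.n_sites, np.nan)
        ok = self.total >= 1
        out[ok] = effective_coverage(float(self.n_chromosomes), self.total[ok].astype(float))
        return out


@dataclass
class PcaResult:
    coords: pd.DataFrame  # samples x PCs
    pve: np.ndarray  # percent variance explained per PC
    window_id: str = "global"


@dataclass
class FstResult:
    per_site: np.ndarray  # NaN where undefined
    window_value: float
    numerators: np.ndarray = field(repr=False, default=None)
    denominators: np.ndarray = field(repr=False, default=None)


def _identity_probs(sample: PoolSample) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased within-pool identity Q1 per site, plus a validity mask.

    Two reads drawn without replacement are copies of the same chromosome
    with probability ``1/n`` (reads sample chromosomes with replacement), so
    the read-pair identity ``(a(a-1) + r(r-1)) / (t(t-1))`` estimates
    ``1/n + (1 - 1/n) Q1`` and is inverted for Q1.
    """
    a = sample.alt.astype(float)
    t = sample.total.astype(float)
    r = t - a
    valid = t >= 2
    q1_reads = np.full(sample.n_sites, np.nan)
    tt = t[valid]
    q1_reads[valid] = (a[valid] * (a[valid] - 1) + r[valid] * (r[valid] - 1)) / (tt * (tt - 1))
    inv_n = 1.0 / sample.n_chromosomes
    q1 = (q1_reads - inv_n) / (1.0 - inv_n)
    return q1, valid


def pairwise_fst(sample_a: PoolSample, sample_b: PoolSample) -> FstResult:
    """Pool-seq FST between two pools via identity probabilities.

    Per site: ``FST = (Q1bar - Q2) / (1 - Q2)`` where ``Q1bar`` is the mean
    unbiased within-pool identity and ``Q2 = p_a p_b + q_a q_b`` the between-
    pool read identity (reads from different pools are never the same
    chromosome, so no correction is needed). The window value is the ratio of
    summed numerators to summed denominators over defined sites; sites with no
    variation in either pool (denominator 0) are undefined and excluded.
    """
    if sample_a.n_sites != sample_b.n_sites:
        raise ValueError("samples must cover the same aligned sites")
    if np.any(sample_a.total < 1) or np.any(sample_b.total < 1):
        raise ValueError("per-site total read count must be > 0 in both pools")
    q1a, va = _identity_probs(sample_a)
    q1b, vb = _identity_probs(sample_b)
    pa, pb = sample_a.freq, sample_b.freq
    q2 = pa * pb + (1 - pa) * (1 - pb)
    num = 0.5 * (q1a + q1b) - q2
    den = 1.0 - q2
    defined = va & vb & (den > 1e-12)
    per_site = np.full(sample_a.n_sites, np.nan)
    per_site[defined] = num[defined] / den[defined]
    if not np.any(defined):
        raise ValueError("FST undefined at every site in this window")
    window_value = float(num[defined].sum() / den[defined].sum())
    return FstResult(per_site=per_site, window_value=window_value,
                     numerators=num, denominators=den)


def _polymorphic_columns(freqs: np.ndarray) -> np.ndarray:
    return np.nanstd(freqs, axis=0) > 0


def pca_global(
    freqs: np.ndarray, sample_ids: list[str], n_components: int | None = None
) -> PcaResult:
    """Centered (not variance-scaled) PCA of a sample x site frequency matrix.

    Sites monomorphic across all samples are dropped; frequencies share a
    scale so no per-site standardization is applied.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    keep = _polymorphic_columns(freqs)
    x = freqs[:, keep]
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 polymorphic sites")
    k = n_components or min(freqs.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcaResult(
        coords=pd.DataFrame(coords, index=sample_ids, columns=cols),
        pve=pca.explained_variance_ratio_ * 100.0,
    )


def pca_sliding(
    freqs: np.ndarray,
    sample_ids: list[str],
    positions: np.ndarray,
    arms: np.ndarray | None = None,
    window_size: int = 100_000,
    step: int = 50_000,
    min_sites: int = 2,
) -> list[PcaResult]:
    """Sliding-window PCA (default 0.1 Mb windows stepped by 50 kb).

    Windows are half-open ``[start, start + window_size)`` on 1-based
    coordinates; windows with fewer than ``min_sites`` polymorphic sites are
    skipped with a log entry. Returns one :class:`PcaResult` per retained
    window, tagged ``arm:start-end``.
    """
    positions = np.asarray(positions)
    freqs = np.asarray(freqs, dtype=float)
    if arms is None:
        arms = np.repeat("NA", len(positions))
    results: list[PcaResult] = []
    for arm in pd.unique(arms):
        on_arm = arms == arm
        pos = positions[on_arm]
        sub = freqs[:, on_arm]
        if pos.size == 0:
            continue
        start = 1
        last = int(pos.max())
        while start <= last:
            in_win = (pos >= start) & (pos < start + window_size)
            wid = f"{arm}:{start}-{start + window_size - 1}"
            x = sub[:, in_win]
            n_poly = int(_polymorphic_columns(x).sum()) if x.size else 0
            if n_poly >= min_sites:
                res = pca_global(x, sample_ids)
                res.window_id = wid
                results.append(res)
            else:
                logger.info("skipping window %s: %d polymorphic sites", wid, n_poly)
            start += step
    return results


def parent_distance_ratio(
    coords: PcaResult, parent_vt: str, parent_sk: str, f16_ids: list[str]
) -> pd.Series:
    """Per-F16 log2 ratio of PC1-PC2 distances to the two parents.

    ``log2(d_SK / d_VT) > 0`` means the sample sits closer to the VT parent.
    A sample coincident with a parent yields a signed infinity sentinel (and a
    warning); callers must exclude sentinels from averages.
    """
    df = coords.coords[["PC1", "PC2"]]
    for sid in (parent_vt, parent_sk, *f16_ids):
        if sid not in df.index:
            raise ValueError(f"sample {sid!r} missing from PCA coordinates")
    vt = df.loc[parent_vt].to_numpy()
    sk = df.loc[parent_sk].to_numpy()
    out = {}
    for sid in f16_ids:
        x = df.loc[sid].to_numpy()
        d_vt = float(np.linalg.norm(x - vt))
        d_sk = float(np.linalg.norm(x - sk))
        if d_vt == 0.0 or d_sk == 0.0:
            warnings.warn(
                f"sample {sid!r} coincides with a parent; returning signed infinity",
                RuntimeWarning,
                stacklevel=2,
            )
            out[sid] = np.inf if d_vt == 0.0 else -np.inf
        else:
            out[sid] = float(np.log2(d_sk / d_vt))
    return pd.Series(out, name="log2_dSK_dVT")
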