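"""Recombination-window maps: the unit of simulation and window-level scanning.

The genome is partitioned per chromosome arm into contiguous windows of
roughly homogeneous recombination rate. Each window is later simulated as an
independent "virtual chromosome" with its own length and mean per-base
recombination rate (rho).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Number of recombination windows per D. melanogaster arm in the standard
#: design (totals 608 windows).
DEFAULT_ARM_WINDOW_COUNTS: dict[str, int] = {
    "2L": 110,
    "2R": 128,
    "3L": 110,
    "3R": 137,
    "X": 123,
}

#: Approximate dm6 euchromatic arm lengths (bases).
DMEL_ARM_LENGTHS: dict[str, int] = {
    "2L": 23_513_712,
    "2R": 25_286_936,
    "3L": 28_110_227,
    "3R": 32_079_331,
    "X": 23_542_271,
}


@dataclass(frozen=True)
class WindowSpec:
    """One recombination window simulated as a virtual chromosome.

    Coordinates are 1-based inclusive; ``rho`` is the mean per-base, per-meiosis
    recombination rate; ``sites`` are 1-based positions inside the window at
    which allele frequencies are tracked.
    """

    arm: str
    start: int
    end: int
    rho: float
    sites: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} > end {self.end}")
        if self.rho < 0:
            raise ValueError("recombination rate must be >= 0")
        for s in self.sites:
            if not (self.start <= s <= self.end):
                raise ValueError(f"site {s} outside window {self.arm}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def id(self) -> str:
        return f"{self.arm}:{self.start}-{self.end}"


class WindowMap:
    """Ordered collection of :class:`WindowSpec` covering the scanned genome."""

    def __init__(self, windows: list[WindowSpec]):
        if not windows:
            raise ValueError("empty window map")
        self.windows = list(windows)
        self._by_id = {w.id: w for w in self.windows}
        if len(self._by_id) != len(self.windows):
            raise ValueError("duplicate window ids")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self._by_id[key]
        return self.windows[key]

    def arm_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for w in self.windows:
            counts[w.arm] = counts.get(w.arm, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arm": [w.arm for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "rho": [w.rho for w in self.windows],
            }
        )

    def to_bed(self, path) -> None:
        """Write a BED-like TSV (arm, start, end, rho), 1-based inclusive."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_bed(cls, path) -> "WindowMap":
        df = pd.read_csv(path, sep="\t")
        required = {"arm", "start", "end", "rho"}
        if not required.issubset(df.columns):
            raise ValueError(f"window map must have columns {sorted(required)}")
        return cls(
            [
                WindowSpec(str(r.arm), int(r.start), int(r.end), float(r.rho))
                for r in df.itertuples()
            ]
        )

    def assign_sites(self, arms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Map each (arm, position) pair to a window index, or -1 if unassigned."""
        out = np.full(len(positions), -1, dtype=int)
        for i, w in enumerate(self.windows):
            mask = (arms == w.arm) & (positions >= w.start) & (positions <= w.end)
            out[mask] = i
        return out


def build_window_map(
    arm_window_counts: dict[str, int] | None = None,
    arm_lengths: dict[str, int] | None = None,
    mean_rho: float = 2.0e-8,
    rho_spread: float = 0.5,
    n_sites_per_window: int = 0,
    seed: int | None = None,
) -> WindowMap:
    """Partition each arm into its configured number of equal-length windows.

    Per-window rho is drawn log-uniformly within ``mean_rho * [1-rho_spread,
    1+rho_spread]`` to emulate local recombination-rate variation (a real map
    would be loaded with :meth:`WindowMap.from_bed`). With ``seed=None`` rho
    is constant at ``mean_rho``. Optionally places ``n_sites_per_window``
    evenly spaced sites in each window.
    """
    counts = dict(arm_window_counts or DEFAULT_ARM_WINDOW_COUNTS)
    lengths = dict(arm_lengths or DMEL_ARM_LENGTHS)
    rng = np.random.default_rng(seed) if seed is not None else None
    windows: list[WindowSpec] = []
    for arm, k in counts.items():
        if k < 1:
            raise ValueError(f"arm {arm}: window count must be >= 1")
        arm_len = lengths.get(arm)
        if arm_len is None:
            raise ValueError(f"no length known for arm {arm}")
        edges = np.linspace(1, arm_len + 1, k + 1).astype(int)
        for j in range(k):
            start, end = int(edges[j]), int(edges[j + 1] - 1)
            if rng is None:
                rho = mean_rho
            else:
                lo, hi = mean_rho * (1 - rho_spread), mean_rho * (1 + rho_spread)
                rho = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if n_sites_per_window > 0:
                sites = tuple(
                    int(p) for p in np.linspace(start, end, n_sites_per_window + 2)[1:-1]
                )
            else:
                sites = ()
            windows.append(WindowSpec(arm, start, end, rho, sites))
    return WindowMap(windows)
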