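"""Readers and writers for pool count tables and run metadata.

Two on-disk encodings of pooled allele counts are supported: popoolation2-
style sync TSV (chrom, pos, ref, then one ``A:T:C:G:N:del`` count string per
sample) and a minimal VCF dialect with per-sample ``AD`` (ref,alt depths) and
``DP`` fields. Coordinates are 1-based inclusive throughout. The reference
base defines the "ref" count; the "alt" allele is the most frequent
non-reference allele summed across all samples jointly, so polarization is
consistent site-wise across samples.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .poolstats import PoolSample

logger = logging.getLogger(__name__)

_NUCS = ("A", "T", "C", "G")
_SYNC_FIELDS = 6  # A:T:C:G:N:del


def write_sync(
    path,
    samples: list[PoolSample],
    ref_alleles: np.ndarray | None = None,
    alt_alleles: np.ndarray | None = None,
) -> None:
    """Write pools as sync TSV. Ref defaults to A and alt to T at every site."""
    n_sites = samples[0].n_sites
    arms = samples[0].arms if samples[0].arms is not None else np.repeat("NA", n_sites)
    pos = (
        samples[0].positions
        if samples[0].positions is not None
        else np.arange(1, n_sites + 1)
    )
    ref = np.asarray(ref_alleles) if ref_alleles is not None else np.repeat("A", n_sites)
    alt = np.asarray(alt_alleles) if alt_alleles is not None else np.repeat("T", n_sites)
    with open(path, "w") as fh:
        for i in range(n_sites):
            cols = [str(arms[i]), str(int(pos[i])), ref[i]]
            for s in samples:
                counts = dict.fromkeys(_NUCS, 0)
                counts[ref[i]] = int(s.total[i] - s.alt[i])
                counts[alt[i]] = int(s.alt[i])
                cols.append(":".join(str(counts[n]) for n in _NUCS) + ":0:0")
            fh.write("\t".join(cols) + "\n")


def read_sync(
    path,
    sample_ids: list[str],
    n_chromosomes: int | list[int] = 60,
    roles: list[str] | None = None,
) -> list[PoolSample]:
    """Read a sync TSV into one :class:`PoolSample` per column.

    Multi-allelic sites are reduced to reference plus the single most
    frequent non-reference allele across all samples jointly (logged);
    N and deletion counts are ignored in totals.
    """
    arms, positions, per_sample = [], [], None
    n_reduced = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3 + len(sample_ids):
                raise ValueError(
                    f"{path}: line {lineno}: expected {3 + len(sample_ids)} columns, "
                    f"got {len(parts)}"
                )
            arm, pos, ref = parts[0], parts[1], parts[2].upper()
            if ref not in _NUCS:
                raise ValueError(f"{path}: line {lineno}: bad reference allele {ref!r}")
            counts = []
            for j, cell in enumerate(parts[3:]):
                fields = cell.split(":")
                if len(fields) != _SYNC_FIELDS:
                    raise ValueError(
                        f"{path}: line {lineno}: sample {sample_ids[j]}: "
                        f"malformed count string {cell!r}"
                    )
                try:
                    counts.append([int(x) for x in fields[:4]])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            counts = np.array(counts)  # samples x ACGT
            joint = counts.sum(axis=0)
            nonref = [k for k in range(4) if _NUCS[k] != ref]
            if sum(joint[k] > 0 for k in nonref) > 1:
                n_reduced += 1
            alt_idx = max(nonref, key=lambda k: joint[k])
            ref_idx = _NUCS.index(ref)
            if per_sample is None:
                per_sample = [([], []) for _ in sample_ids]
            for j in range(len(sample_ids)):
                per_sample[j][0].append(int(counts[j, alt_idx]))
                per_sample[j][1].append(int(counts[j, ref_idx] + counts[j, alt_idx]))
            arms.append(arm)
            positions.append(int(pos))
    if per_sample is None:
        raise ValueError(f"{path}: no sites parsed")
    if n_reduced:
        logger.info("read_sync: reduced %d multi-allelic sites to biallelic", n_reduced)
    if isinstance(n_chromosomes, int):
        n_chromosomes = [n_chromosomes] * len(sample_ids)
    roles = roles or ["wild"] * len(sample_ids)
    return [
        PoolSample(
            sample_id=sid,
            role=roles[j],
            alt=np.array(per_sample[j][0]),
            total=np.array(per_sample[j][1]),
            n_chromosomes=n_chromosomes[j],
            arms=np.array(arms, dtype=object),
            positions=np.array(positions),
        )
        for j, sid in enumerate(sample_ids)
    ]


def write_vcf(
    path,
    samples: list[PoolSample],
    ref_alleles: np.ndarray | None = None,
    alt_alleles: np.ndarray | None = None,
) -> None:
    """Write pools as a minimal VCF with per-sample AD (ref,alt) and DP."""
    n_sites = samples[0].n_sites
    arms = samples[0].arms if samples[0].arms is not None else np.repeat("NA", n_sites)
    pos = (
        samples[0].positions
        if samples[0].positions is not None
        else np.arange(1, n_sites + 1)
    )
    ref = np.asarray(ref_alleles) if ref_alleles is not None else np.repeat("A", n_sites)
    alt = np.asarray(alt_alleles) if alt_alleles is not None else np.repeat("T", n_sites)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for arm in pd.unique(np.asarray(arms)):
            fh.write(f"##contig=<ID={arm}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(s.sample_id for s in samples)
            + "\n"
        )
        for i in range(n_sites):
            cols = [str(arms[i]), str(int(pos[i])), ".", ref[i], alt[i], ".", ".", ".", "GT:AD:DP"]
            for s in samples:
                ad = f"{int(s.total[i] - s.alt[i])},{int(s.alt[i])}"
                cols.append(f"./.:{ad}:{int(s.total[i])}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(
    path,
    n_chromosomes: int | list[int] = 60,
    roles: list[str] | None = None,
) -> list[PoolSample]:
    """Read a VCF with per-sample AD fields into :class:`PoolSample` tables.

    Only biallelic records are used directly; multi-allelic records are
    reduced to the two most frequent alleles with a log entry. Missing AD
    fields are an error naming the offending sample.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    arms, positions = [], []
    alts = [[] for _ in sample_ids]
    totals = [[] for _ in sample_ids]
    n_reduced = 0
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"{path}: {var.CHROM}:{var.POS}: missing AD for all samples")
        ad = np.asarray(ad)
        if np.any(ad < 0):
            bad = sample_ids[int(np.argwhere(ad < 0)[0][0])]
            raise ValueError(f"{path}: {var.CHROM}:{var.POS}: missing AD for sample {bad}")
        if ad.shape[1] > 2:
            n_reduced += 1
            alt_col = 1 + int(np.argmax(ad[:, 1:].sum(axis=0)))
            ad = ad[:, [0, alt_col]]
        arms.append(var.CHROM)
        positions.append(var.POS)
        for j in range(len(sample_ids)):
            alts[j].append(int(ad[j, 1]))
            totals[j].append(int(ad[j, 0] + ad[j, 1]))
    if not arms:
        raise ValueError(f"{path}: no records parsed")
    if n_reduced:
        logger.info("read_vcf: reduced %d multi-allelic sites to biallelic", n_reduced)
    if isinstance(n_chromosomes, int):
        n_chromosomes = [n_chromosomes] * len(sample_ids)
    roles = roles or ["wild"] * len(sample_ids)
    return [
        PoolSample(
            sample_id=sid,
            role=roles[j],
            alt=np.array(alts[j]),
            total=np.array(totals[j]),
            n_chromosomes=n_chromosomes[j],
            arms=np.array(arms, dtype=object),
            positions=np.array(positions),
        )
        for j, sid in enumerate(sample_ids)
    ]


def read_pool_counts(path, format: str | None = None, **kwargs) -> list[PoolSample]:
    """Dispatch to :func:`read_sync` or :func:`read_vcf` by format or suffix."""
    fmt = format or ("vcf" if str(path).endswith(".vcf") else "sync")
    if fmt == "sync":
        return read_sync(path, **kwargs)
    if fmt == "vcf":
        return read_vcf(path, **kwargs)
    raise ValueError(f"unknown format {fmt!r}")


def write_env_table(path, env: pd.DataFrame) -> None:
    env.to_csv(path, index=False)


def read_env_table(path) -> pd.Series:
    """Read a (date, variable, value) CSV into a date-indexed daily series."""
    df = pd.read_csv(path, parse_dates=["date"])
    if not {"date", "value"}.issubset(df.columns):
        raise ValueError("environment table needs 'date' and 'value' columns")
    return pd.Series(df["value"].to_numpy(), index=pd.DatetimeIndex(df["date"]))


def write_metadata(path, samples: list[PoolSample]) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "role": [s.role for s in samples],
            "n_chromosomes": [s.n_chromosomes for s in samples],
        }
    ).to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
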