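"""Quantitative comparison of multiplexed ChIP samples.

Because all RELACS samples share one ChIP reaction and each carries its own
input control, per-sample scaling factors estimated from the multiplexed
inputs put ChIP signals on a common quantitative scale.  This module bins
fragment midpoints over the genome, estimates scaling factors (median of
ratios over bins shared non-zero across samples, normalized to geometric mean
1 — total-count ratios as a fallback), computes FRiP (fraction of fragments
in peaks), converts FRiP to an RPKM-scale enrichment by dividing by the
genomic fraction covered by peaks and multiplying by 1e6, and forms per-bin
log2 ChIP/input ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from relacs.genome_digest import IntervalSet, _membership

Fragment = tuple[str, int, int]


@dataclass
class BinnedCounts:
    """Fragment counts per genomic bin per sample.

    ``bins`` tile each chromosome at ``bin_size`` (last bin truncated);
    ``counts`` has one column per sample on the shared bin axis; ``masked``
    flags bins fully inside blacklist regions.
    """

    bin_size: int
    bins: pd.DataFrame  # chrom, start, end
    counts: pd.DataFrame  # index aligned to bins; columns = samples
    masked: np.ndarray  # bool per bin
    blacklist_filtered: bool = False

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def make_bins(genome_lengths: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in genome_lengths.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def bin_counts(
    fragments: Mapping[str, Sequence[Fragment]],
    genome_lengths: Mapping[str, int],
    bin_size: int = 10_000,
    blacklist: Optional[IntervalSet] = None,
) -> BinnedCounts:
    """Bin fragment midpoints at ``bin_size`` per sample.

    Each fragment increments the bin containing its midpoint; fragments whose
    midpoint lies in a blacklist interval are excluded, and bins fully inside
    blacklist regions are masked.
    """
    bins = make_bins(genome_lengths, bin_size)
    # per-chromosome bin index offsets
    offsets: dict[str, int] = {}
    n_bins_by_chrom: dict[str, int] = {}
    off = 0
    for chrom, length in genome_lengths.items():
        offsets[chrom] = off
        n_bins_by_chrom[chrom] = int(np.ceil(length / bin_size)) if length else 0
        off += n_bins_by_chrom[chrom]

    bl_by_chrom: dict[str, np.ndarray] = {}
    if blacklist is not None and len(blacklist):
        merged = IntervalSet(
            [(c, s, e, "bl") for c, s, e, _ in blacklist.frame.itertuples(index=False)],
            merge=True,
        )
        bl_by_chrom = merged.by_class("bl")

    counts = {}
    for sample, frags in fragments.items():
        vec = np.zeros(len(bins), dtype=np.int64)
        by_chrom: dict[str, list[int]] = {}
        for chrom, start, end in frags:
            if chrom not in offsets:
                raise ValueError(f"fragment on unknown chromosome {chrom!r}")
            by_chrom.setdefault(chrom, []).append((int(start) + int(end)) // 2)
        for chrom, mids in by_chrom.items():
            arr = np.asarray(mids, dtype=np.int64)
            bl = bl_by_chrom.get(chrom)
            if bl is not None:
                arr = arr[~_membership(arr, bl)]
            idx = offsets[chrom] + arr // bin_size
            np.add.at(vec, idx, 1)
        counts[sample] = vec
    count_df = pd.DataFrame(counts)

    masked = np.zeros(len(bins), dtype=bool)
    for chrom, bl in bl_by_chrom.items():
        starts = bins["start"].to_numpy()[offsets[chrom] : offsets[chrom] + n_bins_by_chrom[chrom]]
        ends = bins["end"].to_numpy()[offsets[chrom] : offsets[chrom] + n_bins_by_chrom[chrom]]
        # a bin is masked when some blacklist interval covers it entirely
        bin_masked = np.zeros(starts.size, dtype=bool)
        for s, e in bl:
            bin_masked |= (starts >= s) & (ends <= e)
        masked[offsets[chrom] : offsets[chrom] + n_bins_by_chrom[chrom]] = bin_masked
    return BinnedCounts(
        bin_size=bin_size,
        bins=bins,
        counts=count_df,
        masked=masked,
        blacklist_filtered=blacklist is not None,
    )


@dataclass
class ScalingFactorSet:
    """Per-sample multiplicative scaling factors, geometric mean 1."""

    factors: dict[str, float]
    method: str

    def __post_init__(self) -> None:
        vals = np.array(list(self.factors.values()), dtype=float)
        if np.any(vals <= 0):
            raise ValueError("scaling factors must be positive")
        gm = float(np.exp(np.mean(np.log(vals))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"factors must have geometric mean 1, got {gm}")

    def __getitem__(self, sample: str) -> float:
        return self.factors[sample]


def _rescale_gm1(raw: dict[str, float], method: str) -> ScalingFactorSet:
    vals = np.array(list(raw.values()), dtype=float)
    gm = np.exp(np.mean(np.log(vals)))
    return ScalingFactorSet({k: float(v / gm) for k, v in raw.items()}, method=method)


def input_scaling_factors(
    inputs: BinnedCounts,
    method: str = "median_ratio",
    min_shared_bins: int = 50,
) -> ScalingFactorSet:
    """Estimate per-sample scaling factors from multiplexed input controls.

    ``median_ratio``: for each sample, the median over bins of
    count / (geometric mean of the bin across samples), restricted to
    unmasked bins non-zero in every sample (the DESeq-style size factor);
    fewer than ``min_shared_bins`` such bins triggers a fallback to
    ``total_count`` with a warning.  ``total_count``: library-size ratios.
    Either way the factors are rescaled to geometric mean 1, the convention
    under which identical replicates have factors of exactly 1.
    """
    if method not in ("median_ratio", "total_count"):
        raise ValueError(f"unknown method {method!r}")
    mat = inputs.counts.loc[~inputs.masked]
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    zero_samples = [s for s in mat.columns if mat[s].sum() == 0]
    if zero_samples:
        raise ValueError(f"sample(s) with all-zero counts: {zero_samples}")

    if method == "median_ratio":
        nonzero = (mat > 0).all(axis=1)
        if int(nonzero.sum()) < min_shared_bins:
            warnings.warn(
                f"only {int(nonzero.sum())} bins non-zero in all samples "
                f"(< {min_shared_bins}); falling back to total_count"
            )
            method = "total_count"
        else:
            sub = mat.loc[nonzero].to_numpy(dtype=float)
            log_gm = np.mean(np.log(sub), axis=1)  # per-bin geometric mean
            raw = {
                s: float(np.exp(np.median(np.log(sub[:, j]) - log_gm)))
                for j, s in enumerate(mat.columns)
            }
            return _rescale_gm1(raw, "median_ratio")
    totals = mat.sum(axis=0)
    raw = {s: float(totals[s]) for s in mat.columns}
    return _rescale_gm1(raw, "total_count")


@dataclass
class PeakSet:
    """Merged, non-overlapping peak intervals plus the genome fraction they cover."""

    intervals: dict[str, np.ndarray]  # chrom -> merged (n, 2)
    genome_length: int

    @classmethod
    def from_intervals(cls, intervals: Sequence[Fragment], genome_length: int) -> "PeakSet":
        iset = IntervalSet([(c, s, e, "peak") for c, s, e in intervals], merge=True)
        return cls(intervals=iset.by_class("peak"), genome_length=genome_length)

    @property
    def total_peak_bases(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self.intervals.values()))

    @property
    def genome_fraction(self) -> float:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        return self.total_peak_bases / self.genome_length


def frip(fragments: Sequence[Fragment], peaks: PeakSet) -> float:
    """Fraction of fragments overlapping any peak by at least 1 bp."""
    if len(fragments) == 0:
        raise ValueError("zero fragments")
    n_in = 0
    for chrom, start, end in fragments:
        ivs = peaks.intervals.get(chrom)
        if ivs is None or ivs.size == 0:
            continue
        starts, ends = ivs[:, 0], ivs[:, 1]
        i = int(np.searchsorted(starts, end, side="left"))
        if i > 0 and ends[i - 1] > start:
            n_in += 1
    return n_in / len(fragments)


def frip_rpkm(frip_value: float, peaks: PeakSet) -> float:
    """Convert FRiP to an RPKM-scale enrichment comparable across peak sets.

    FRiP divided by the fraction of the genome falling into peaks, times 1e6;
    a sample whose FRiP equals the peak genome fraction (pure background)
    scores exactly 1e6.
    """
    gf = peaks.genome_fraction
    if gf <= 0:
        raise ValueError("peak genome fraction is zero")
    return frip_value / gf * 1e6


def normalize_chip(
    chip: BinnedCounts,
    input_: BinnedCounts,
    chip_factors: Optional[ScalingFactorSet] = None,
    input_factors: Optional[ScalingFactorSet] = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-bin log2(ChIP / input) per sample, after factor scaling.

    Each ChIP sample is matched to the input sample of the same name; counts
    are divided by their respective scaling factor, offset by ``pseudocount``
    and log2-ratioed.  Masked bins are emitted as NaN.
    """
    if chip.bin_size != input_.bin_size or len(chip.bins) != len(input_.bins):
        raise ValueError("chip and input must share the same bin axis")
    unmatched = [s for s in chip.samples if s not in input_.samples]
    if unmatched:
        raise ValueError(f"chip sample(s) without matched input: {unmatched}")
    out = chip.bins.copy()
    mask = chip.masked | input_.masked
    for s in chip.samples:
        f = chip_factors[s] if chip_factors is not None else 1.0
        g = input_factors[s] if input_factors is not None else 1.0
        c = chip.counts[s].to_numpy(dtype=float) / f
        i = input_.counts[s].to_numpy(dtype=float) / g
        ratio = np.log2((c + pseudocount) / (i + pseudocount))
        ratio[mask] = np.nan
        out[s] = ratio
    return out
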