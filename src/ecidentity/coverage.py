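"""Binned coverage tracks and Poisson-background peak calling.

The model is deliberately simple, in the spirit of DANPOS-style dense-peak
calling: reads are extended to the expected fragment length from their 5'
end, fragment overlap is aggregated into fixed-width bins (10 bp default),
an optional matched input/control track is subtracted bin-wise (clipped at
zero), and a bin is called significant when its count is improbably high
under a single genome-wide Poisson background rate lambda (the mean bin
value). Runs of significant bins become peaks.

No smoothing is applied and the background is global, not local: a single
Poisson cutoff (1e-30 by default) against the genome-wide mean defines
enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import special

from .io import as_interval_frame
from .models import GenomicInterval, Peak


@dataclass
class PeakCallParams:
    """Tunable parameters of track construction and peak calling.

    p_cutoff
        Poisson upper-tail P-value below which a bin is significant.
    extension
        Read extension length in bp (5'-anchored); 0 leaves reads untouched.
    bin_size
        Bin width in bp for the coverage track.
    smooth_width
        Present for completeness; only 0 (no smoothing) is supported.
    normalization_target
        Library size the track is scaled to when depth normalization is
        requested (fragments; 25e6 default).
    merge_gap
        Maximum number of consecutive non-significant bins bridged when
        merging significant bins into peaks.
    """

    p_cutoff: float = 1e-30
    extension: int = 200
    bin_size: int = 10
    smooth_width: int = 0
    normalization_target: float = 25e6
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_cutoff < 1):
            raise ValueError("p_cutoff must lie in (0, 1)")
        if self.extension < 0:
            raise ValueError("extension must be >= 0")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.smooth_width != 0:
            raise ValueError("only smooth_width=0 is supported")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass
class CoverageTrack:
    """Binned fragment counts per chromosome.

    ``values[chrom][i]`` is the number of fragments overlapping bin i by at
    least 1 bp (a float after depth normalization). ``total_mass`` is the
    (normalized) fragment count of the library.
    """

    bin_size: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray]
    total_mass: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            expected = -(-self.chrom_lengths[chrom] // self.bin_size)
            if len(arr) != expected:
                raise ValueError(
                    f"{chrom}: {len(arr)} bins, expected {expected} for "
                    f"length {self.chrom_lengths[chrom]} at bin {self.bin_size}"
                )

    @property
    def n_bins(self) -> int:
        return sum(len(a) for a in self.values.values())

    def mean_bin_value(self) -> float:
        total = sum(float(a.sum()) for a in self.values.values())
        return total / self.n_bins


# ---------------------------------------------------------------------------
# read extension


def extend_reads(
    reads: Union[pd.DataFrame, Sequence[GenomicInterval]],
    extension: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Replace each stranded read by the ``extension``-bp interval starting at
    its 5' end and running 3'-ward, clipped to [0, chrom_length).

    extension=0 returns the reads unchanged. Accepts a list of
    GenomicInterval or an interval frame; returns an interval frame.
    """
    df = as_interval_frame(reads)
    if extension == 0 or df.empty:
        return df.copy()
    strand = df["strand"]
    if strand.isna().any() or not strand.isin(["+", "-"]).all():
        raise ValueError("read extension requires a strand on every read")
    start = df["start"].to_numpy(np.int64)
    end = df["end"].to_numpy(np.int64)
    plus = (strand == "+").to_numpy()
    new_start = np.where(plus, start, end - extension)
    new_end = np.where(plus, start + extension, end)
    new_start = np.maximum(new_start, 0)
    if chrom_lengths is not None:
        if df["chrom"].nunique() == 1:
            limit = chrom_lengths[df["chrom"].iloc[0]]
            new_end = np.minimum(new_end, limit)
        else:
            limits = df["chrom"].map(chrom_lengths).to_numpy(np.int64)
            new_end = np.minimum(new_end, limits)
    out = df.copy()
    out["start"], out["end"] = new_start, new_end
    return out


# ---------------------------------------------------------------------------
# track construction


def build_coverage(
    fragments: Union[pd.DataFrame, Sequence[GenomicInterval]],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 10,
) -> CoverageTrack:
    """Count, per bin, the fragments overlapping it by >=1 bp.

    total_mass is the number of fragments. Fragments on chromosomes absent
    from ``chrom_lengths`` or outside [0, length) are an error.
    """
    df = as_interval_frame(fragments)
    values: dict[str, np.ndarray] = {
        c: np.zeros(-(-length // bin_size), dtype=np.float64)
        for c, length in chrom_lengths.items()
    }
    unknown = set(df["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"fragments on unknown chromosomes: {sorted(unknown)[:5]}")
    for chrom, grp in df.groupby("chrom", sort=False, observed=True):
        if grp.empty:
            continue
        length = chrom_lengths[chrom]
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        if (starts < 0).any() or (ends > length).any():
            raise ValueError(f"fragment outside [0, {length}) on {chrom}")
        arr = values[chrom]
        first = starts // bin_size          # first overlapped bin
        last = (ends - 1) // bin_size       # last overlapped bin (inclusive)
        n = len(arr)
        diff = (
            np.bincount(first, minlength=n + 1).astype(np.float64)
            - np.bincount(last + 1, minlength=n + 2)[: n + 1]
        )
        arr += np.cumsum(diff[:-1])
    return CoverageTrack(
        bin_size=bin_size,
        chrom_lengths=dict(chrom_lengths),
        values=values,
        total_mass=float(len(df)),
        metadata={},
    )


def normalize_depth(track: CoverageTrack, target: float) -> CoverageTrack:
    """Scale every bin by target / total_mass; total_mass becomes target."""
    if track.total_mass <= 0:
        raise ValueError("cannot depth-normalize a track with zero total mass")
    scale = target / track.total_mass
    return CoverageTrack(
        bin_size=track.bin_size,
        chrom_lengths=dict(track.chrom_lengths),
        values={c: a * scale for c, a in track.values.items()},
        total_mass=float(target),
        metadata={**track.metadata, "normalization_target": float(target)},
    )


def subtract_control(treatment: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Bin-wise max(0, treatment - control); bin grids must match exactly."""
    if treatment.bin_size != control.bin_size:
        raise ValueError("bin_size mismatch between treatment and control")
    if set(treatment.values) != set(control.values) or any(
        treatment.chrom_lengths[c] != control.chrom_lengths.get(c)
        for c in treatment.chrom_lengths
    ):
        raise ValueError("chromosome grids differ between treatment and control")
    values = {
        c: np.maximum(treatment.values[c] - control.values[c], 0.0)
        for c in treatment.values
    }
    return CoverageTrack(
        bin_size=treatment.bin_size,
        chrom_lengths=dict(treatment.chrom_lengths),
        values=values,
        total_mass=float(sum(a.sum() for a in values.values())),
        metadata={**treatment.metadata, "control_subtracted": True},
    )


# ---------------------------------------------------------------------------
# Poisson tail


def poisson_upper_tail(k, lam: float):
    """P(X >= k) for X ~ Poisson(lam).

    Computed via the regularized lower incomplete gamma function
    (P(X >= k) = gammainc(k, lam)), which keeps relative accuracy for tail
    probabilities down to ~1e-300. k may be a scalar or array.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    out = np.where(k == 0, 1.0, special.gammainc(np.maximum(k, 1), lam))
    return float(out) if out.ndim == 0 else out


def log10_poisson_upper_tail(k: int, lam: float) -> float:
    """log10 P(X >= k), finite even where the tail underflows to 0.

    For the underflow regime (k >> lam) the tail is expanded as
    pmf(k) * (1 + lam/(k+1) + lam^2/((k+1)(k+2)) + ...), summed in linear
    space relative to the leading term.
    """
    p = poisson_upper_tail(k, lam)
    if p > 0:
        return math.log10(p)
    # leading log-pmf via Stirling-exact lgamma
    logpmf = -lam + k * math.log(lam) - math.lgamma(k + 1)
    rel, term, j = 1.0, 1.0, k + 1
    while True:
        term *= lam / j
        rel += term
        j += 1
        if term < 1e-16 * rel:
            break
    return (logpmf + math.log(rel)) / math.log(10)


# ---------------------------------------------------------------------------
# peak calling


def significance_threshold(lam: float, p_cutoff: float) -> int:
    """Smallest integer count k with P(X >= k) < p_cutoff under Poisson(lam)."""
    k = int(math.ceil(lam))
    while poisson_upper_tail(k, lam) >= p_cutoff:
        k += 1
    while k > 0 and poisson_upper_tail(k - 1, lam) < p_cutoff:
        k -= 1
    return k


def call_peaks(track: CoverageTrack, params: PeakCallParams) -> list[Peak]:
    """Call enriched peaks against a global Poisson background.

    lambda is the genome-wide mean bin value over all bins. A bin is
    significant iff P(X >= round(value)) < p_cutoff; runs of significant
    bins separated by <= merge_gap non-significant bins merge into one peak.
    Peak.score is -log10 of the minimum bin P inside the peak; the summit is
    the center of the bin attaining it (leftmost on ties). Peaks come back
    sorted by chromosome then start.
    """
    lam = track.mean_bin_value()
    if lam <= 0:
        raise ValueError("all-zero track: background rate undefined")
    kmin = significance_threshold(lam, params.p_cutoff)
    bin_size = track.bin_size
    peaks: list[Peak] = []
    for chrom in sorted(track.values):
        counts = np.rint(track.values[chrom]).astype(np.int64)
        sig = counts >= kmin
        idx = np.flatnonzero(sig)
        if idx.size == 0:
            continue
        # split runs where the gap between consecutive significant bins
        # exceeds merge_gap + 1
        breaks = np.flatnonzero(np.diff(idx) > params.merge_gap + 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [idx.size - 1]))
        chrom_len = track.chrom_lengths[chrom]
        for rs, re in zip(run_starts, run_ends):
            first_bin, last_bin = idx[rs], idx[re]
            run_counts = counts[first_bin:last_bin + 1]
            kmax = int(run_counts.max())
            summit_bin = first_bin + int(np.argmax(run_counts == kmax))
            score = -log10_poisson_upper_tail(kmax, lam)
            start = int(first_bin * bin_size)
            end = min(int((last_bin + 1) * bin_size), chrom_len)
            summit = min(int(summit_bin * bin_size + bin_size // 2), chrom_len - 1)
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), max(score, 0.0), summit)
            )
    return peaks


# ---------------------------------------------------------------------------
# bedGraph export


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write the track as bedGraph, merging adjacent equal-valued bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            chrom_len = track.chrom_lengths[chrom]
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(
                    f"{chrom}\t{s * track.bin_size}"
                    f"\t{min(e * track.bin_size, chrom_len)}\t{v:.6g}\n"
                )
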