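"""Binned genomic tracks and the sequence -> structural-profile transform.

A DNA sequence is converted to a raw structural vector by replacing each
k-mer with its scale value, then smoothed with a moving average (default:
100-bp window advanced in 10-bp steps), giving one structural value per
10 bp.  Non-ACGT positions are masked (NaN) rather than raising, and masked
entries are excluded from window means.

Coordinate convention: 0-based, half-open.  Bin ``j`` summarises raw
entries ``[j*step, j*step + window)``; its representative bp coordinate is
the window centre, ``origin_bp + j*step_bp + window_bp/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .scales import StructuralScale

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass
class BinnedTrack:
    """A per-chromosome vector of values at fixed bin spacing."""

    chrom: str
    values: np.ndarray
    origin_bp: int = 0
    step_bp: int = 10
    window_bp: int = 100

    def __post_init__(self) -> None:
        if self.step_bp < 1:
            raise ValueError("step_bp must be >= 1")
        if self.window_bp < self.step_bp:
            raise ValueError("window_bp must be >= step_bp")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def coords(self) -> np.ndarray:
        """Representative bp coordinate (window centre) of each bin."""
        return self.origin_bp + np.arange(len(self.values)) * self.step_bp + self.window_bp / 2

    def covered_span(self) -> tuple[int, int]:
        """bp interval [start, end) spanned by the underlying windows."""
        if len(self.values) == 0:
            return (self.origin_bp, self.origin_bp)
        end = self.origin_bp + (len(self.values) - 1) * self.step_bp + self.window_bp
        return (self.origin_bp, end)


@dataclass
class StructuralProfile(BinnedTrack):
    feature: str = ""


@dataclass
class OccupancyTrack(BinnedTrack):
    pass


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A,C,G,T -> 0..3; other -> -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[arr]


def raw_structural_vector(seq: str, scale: StructuralScale) -> np.ndarray:
    """Substitute every k-mer of ``seq`` with its scale value.

    Returns a float vector of length ``len(seq) - k + 1``; positions whose
    k-mer contains a non-ACGT symbol are NaN.
    """
    k = scale.k
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes = encode_sequence(seq)
    n = len(codes) - k + 1
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        idx = idx * 4 + np.where(c >= 0, c, 0)
        valid &= c >= 0
    # lookup table in lexicographic ACGT order
    lut = np.empty(4**k, dtype=float)
    digits = "ACGT"
    for i in range(4**k):
        kmer = ""
        v = i
        for _ in range(k):
            kmer = digits[v % 4] + kmer
            v //= 4
        lut[i] = scale.values[kmer]
    out = lut[idx]
    out[~valid] = np.nan
    return out


def smooth_profile(
    raw: np.ndarray,
    window_bp: int = 100,
    step_bp: int = 10,
    chrom: str = "",
    feature: str = "",
    origin_bp: int = 0,
) -> StructuralProfile:
    """Moving-average smoothing of a raw structural vector.

    Bin ``j`` is the mean of raw entries ``[j*step_bp, j*step_bp +
    window_bp)``, ignoring masked (NaN) entries; a fully masked window
    yields a masked bin.  Only full windows are emitted, so a raw vector
    shorter than ``window_bp`` gives an empty profile.
    """
    raw = np.asarray(raw, dtype=float)
    n_raw = len(raw)
    if n_raw < window_bp:
        values = np.empty(0, dtype=float)
    else:
        n_bins = (n_raw - window_bp) // step_bp + 1
        finite = np.isfinite(raw)
        filled = np.where(finite, raw, 0.0)
        csum = np.concatenate([[0.0], np.cumsum(filled)])
        ccnt = np.concatenate([[0], np.cumsum(finite)])
        starts = np.arange(n_bins) * step_bp
        sums = csum[starts + window_bp] - csum[starts]
        cnts = ccnt[starts + window_bp] - ccnt[starts]
        with np.errstate(invalid="ignore"):
            values = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return StructuralProfile(
        chrom=chrom,
        values=values,
        origin_bp=origin_bp,
        step_bp=step_bp,
        window_bp=window_bp,
        feature=feature,
    )


def structural_profile(
    seq: str,
    scale: StructuralScale,
    window_bp: int = 100,
    step_bp: int = 10,
    chrom: str = "",
    origin_bp: int = 0,
) -> StructuralProfile:
    """Convenience: raw substitution followed by moving-average smoothing."""
    raw = raw_structural_vector(seq, scale)
    return smooth_profile(
        raw,
        window_bp=window_bp,
        step_bp=step_bp,
        chrom=chrom,
        feature=scale.name,
        origin_bp=origin_bp,
    )


def oriented_profile(p: StructuralProfile, scale: StructuralScale) -> StructuralProfile:
    """Flip negatively correlated profiles so nucleosomes are always peaks.

    Identity for positive-class scales; values negated for negative-class
    scales, letting one peak detector serve both classes.
    """
    if scale.sign_class == "positive":
        return replace(p, values=p.values.copy())
    return replace(p, values=-p.values)


def aggregate_around_anchors(
    track: BinnedTrack,
    anchors,
    flank_bp: int,
) -> np.ndarray:
    """Average track values in ``[anchor - flank, anchor + flank]``.

    ``anchors`` is an iterable of ``(chrom, bp, strand)``; minus-strand
    anchors are reversed before averaging.  Anchors whose flank is
    truncated by the track boundary are dropped; if none remain, raises.
    Returns a vector of ``2*flank_bp/step_bp + 1`` per-offset means.
    """
    if flank_bp % track.step_bp != 0:
        raise ValueError("flank_bp must be a multiple of step_bp")
    f = flank_bp // track.step_bp
    n = len(track.values)
    half_w = track.window_bp / 2
    rows = []
    for chrom, bp, strand in anchors:
        if chrom != track.chrom:
            continue
        j = int(round((bp - track.origin_bp - half_w) / track.step_bp))
        if j - f < 0 or j + f >= n:
            continue
        row = track.values[j - f : j + f + 1]
        if strand == "-":
            row = row[::-1]
        rows.append(row)
    if not rows:
        raise ValueError("no usable anchors (all off-track or truncated)")
    return np.nanmean(np.vstack(rows), axis=0)
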