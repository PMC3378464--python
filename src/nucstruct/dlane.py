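"""DLaNe: locating nucleosomes by detecting peaks of structural profiles.

The procedure, applied per chromosome to an oriented (peaks-up) smoothed
structural profile:

1. median-filter the profile to suppress narrow noise spikes (window equal
   to the smoothing window, 100 bp by default), giving the vector ``SM``;
2. partition ``SM`` into non-overlapping scan windows (165 bp, i.e. one
   nucleosome plus a typical linker) and compute each window's peak
   intensity ``Pi = max - min``; the average ``APi`` over windows times the
   peak-significance parameter ``Ps`` gives the per-chromosome threshold;
3. slide a scan window along ``SM``; whenever its intensity reaches the
   threshold, the position of the maximal value becomes a peak centre
   ``Pc`` and implies the 147-bp nucleosome ``[Pc-73, Pc+74)``.  Scanning
   resumes just past the right endpoint ``Pr = Pc+73``, enforcing steric
   exclusion (non-overlapping calls).

Degenerate-input rules (not covered by the procedure itself): a window
qualifies only when ``Pi > 0``, so flat profiles yield no calls; the
leftmost position attaining the window maximum is taken as ``Pc``;
while the maximum sits on the window's trailing edge the profile is
still rising into the window, so acceptance is deferred until the apex
is interior; candidate calls extending beyond the covered span, or
overlapping the previously accepted call, are skipped and the window
advances one bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .calls import HALF_NUCLEOSOME_BP, NUCLEOSOME_BP, NucleosomeCall
from .profiles import StructuralProfile


@dataclass
class PeakCallerConfig:
    """Tuning knobs of the peak caller.

    ``ps`` is the peak-significance threshold in (0, 1]; values in
    [0.3, 0.6] work best, with 0.45 as the default.  The 165-bp scan
    window reflects the typical centre-to-centre spacing of adjacent
    yeast nucleosomes (147-bp core + ~18-bp linker).
    """

    ps: float = 0.45
    scan_window_bp: int = 165
    nucleosome_bp: int = NUCLEOSOME_BP
    median_window_bp: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.ps <= 1:
            raise ValueError("ps must lie in (0, 1]")
        if self.scan_window_bp < self.nucleosome_bp:
            raise ValueError("scan_window_bp must be >= nucleosome_bp")

    def scan_window_bins(self, step_bp: int) -> int:
        return int(math.floor(self.scan_window_bp / step_bp + 0.5))


@dataclass(frozen=True)
class Peak:
    """A detected peak and the nucleosome window it implies."""

    center_bp: int
    intensity: float
    width_bp: int

    @property
    def left_bp(self) -> int:
        return self.center_bp - HALF_NUCLEOSOME_BP

    @property
    def right_bp(self) -> int:
        return self.center_bp + HALF_NUCLEOSOME_BP


@dataclass
class ChromosomeThreshold:
    ap_i: float
    threshold: float
    n_windows: int


def median_filter(
    p: StructuralProfile, median_window_bp: int = 100
) -> StructuralProfile:
    """Replace each bin by the median of unmasked bins in a centred window.

    The window is the nearest odd bin count covering ``median_window_bp``;
    windows are truncated at the profile edges.
    """
    w = math.ceil(median_window_bp / p.step_bp)
    if w % 2 == 0:
        w += 1
    n = len(p.values)
    if n == 0 or w == 1:
        return replace(p, values=p.values.copy())
    half = w // 2
    padded = np.concatenate([np.full(half, np.nan), p.values, np.full(half, np.nan)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmedian(windows, axis=1)
    return replace(p, values=out)


def compute_threshold(
    sm: StructuralProfile, cfg: PeakCallerConfig | None = None
) -> ChromosomeThreshold:
    """Adaptive per-chromosome peak-intensity threshold ``Ps * APi``.

    ``APi`` is the mean of per-window (max - min) over the partition of
    ``SM`` into non-overlapping scan windows.
    """
    cfg = cfg or PeakCallerConfig()
    pw = cfg.scan_window_bins(sm.step_bp)
    n = len(sm.values)
    if n < pw:
        raise ValueError(
            f"profile has {n} bins, shorter than one {pw}-bin scan window"
        )
    n_win = n // pw
    blocks = sm.values[: n_win * pw].reshape(n_win, pw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ranges = np.nanmax(blocks, axis=1) - np.nanmin(blocks, axis=1)
    ranges = ranges[np.isfinite(ranges)]
    if len(ranges) == 0:
        raise ValueError("profile is fully masked; no scan window has data")
    ap_i = float(np.mean(ranges))
    return ChromosomeThreshold(ap_i=ap_i, threshold=cfg.ps * ap_i, n_windows=len(ranges))


def detect_peaks(
    sm: StructuralProfile,
    cfg: PeakCallerConfig | None = None,
    threshold: float | None = None,
) -> list[Peak]:
    """Scan ``SM`` left to right and return accepted peaks (S.3)."""
    cfg = cfg or PeakCallerConfig()
    if threshold is None:
        threshold = compute_threshold(sm, cfg).threshold
    pw = cfg.scan_window_bins(sm.step_bp)
    values = sm.values
    coords = sm.coords()
    n = len(values)
    span_start, span_end = sm.covered_span()
    peaks: list[Peak] = []
    prev_end = -1
    w = 0
    while w + pw <= n:
        window = values[w : w + pw]
        if not np.any(np.isfinite(window)):
            w += 1
            continue
        pi = float(np.nanmax(window) - np.nanmin(window))
        if pi < threshold or pi <= 0:
            w += 1
            continue
        j = w + int(np.nanargmax(window))  # leftmost maximum
        if j == w + pw - 1 and w + pw < n:
            w += 1  # still rising into the window; defer to centre the apex
            continue
        pc = int(round(coords[j]))
        start = pc - HALF_NUCLEOSOME_BP
        end = start + NUCLEOSOME_BP
        if start < span_start or end > span_end or start < prev_end:
            w += 1
            continue
        peaks.append(Peak(center_bp=pc, intensity=pi, width_bp=pw * sm.step_bp))
        prev_end = end
        # resume with the first bin lying past the right endpoint Pr
        resume_coord = pc + HALF_NUCLEOSOME_BP + 1
        w = max(
            w + 1,
            math.ceil((resume_coord - sm.origin_bp - sm.window_bp / 2) / sm.step_bp),
        )
    return peaks


def call_nucleosomes(
    sm: StructuralProfile,
    cfg: PeakCallerConfig | None = None,
    threshold: float | None = None,
    source: str | None = None,
) -> list[NucleosomeCall]:
    """Detect peaks on a median-filtered profile and emit 147-bp calls."""
    peaks = detect_peaks(sm, cfg=cfg, threshold=threshold)
    src = source if source is not None else sm.feature
    return [
        NucleosomeCall.from_center(sm.chrom, p.center_bp, score=p.intensity, source=src)
        for p in peaks
    ]


class DLaNePeakCaller:
    """Stateless detector object wrapping the median-filter/threshold/scan
    pipeline, with scikit-learn style parameter handling."""

    def __init__(
        self,
        ps: float = 0.45,
        scan_window_bp: int = 165,
        median_window_bp: int = 100,
    ):
        self.ps = ps
        self.scan_window_bp = scan_window_bp
        self.median_window_bp = median_window_bp

    def get_params(self, deep: bool = True) -> dict:
        return {
            "ps": self.ps,
            "scan_window_bp": self.scan_window_bp,
            "median_window_bp": self.median_window_bp,
        }

    def set_params(self, **params) -> "DLaNePeakCaller":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _config(self) -> PeakCallerConfig:
        return PeakCallerConfig(
            ps=self.ps,
            scan_window_bp=self.scan_window_bp,
            median_window_bp=self.median_window_bp,
        )

    def predict(self, profile: StructuralProfile, scale=None) -> list[NucleosomeCall]:
        """Call nucleosomes on one (optionally unoriented) profile.

        If ``scale`` is given, the profile is first oriented peaks-up
        according to the scale's sign class.
        """
        from .profiles import oriented_profile

        cfg = self._config()
        p = oriented_profile(profile, scale) if scale is not None else profile
        sm = median_filter(p, cfg.median_window_bp)
        return call_nucleosomes(sm, cfg)

    __call__ = predict
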