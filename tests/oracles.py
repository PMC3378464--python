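"""Independent reference implementations used only as test oracles.

Each routine re-derives a result by direct enumeration, staying
deliberately naive and separate from the package's code paths.
"""

import itertools
import math

import numpy as np


def smooth_bin_count(n_raw: int, window: int, step: int) -> int:
    """Count full smoothing windows by explicit enumeration."""
    count = 0
    start = 0
    while start + window <= n_raw:
        count += 1
        start += step
    return count


def dlane_literal(values, step_bp, window_bp, origin_bp, ps, scan_window_bp=165):
    """Literal transcription of the threshold + scan procedure.

    Works on an already median-filtered profile; returns peak centres in
    bp.  Kept loop-based and index-naive on purpose.
    """
    values = list(values)
    n = len(values)
    pw = int(math.floor(scan_window_bp / step_bp + 0.5))
    if n < pw:
        raise ValueError("profile shorter than one scan window")

    def coord(j):
        return origin_bp + j * step_bp + window_bp / 2

    # S.2: average peak intensity over the non-overlapping partition
    intensities = []
    for w0 in range(0, (n // pw) * pw, pw):
        win = [v for v in values[w0 : w0 + pw] if not math.isnan(v)]
        if win:
            intensities.append(max(win) - min(win))
    threshold = ps * (sum(intensities) / len(intensities))

    # S.3: left-to-right scan
    centers = []
    prev_end = -1
    w = 0
    span_end = origin_bp + (n - 1) * step_bp + window_bp
    while w + pw <= n:
        win = values[w : w + pw]
        finite = [v for v in win if not math.isnan(v)]
        if not finite:
            w += 1
            continue
        pi = max(finite) - min(finite)
        if pi < threshold or pi <= 0:
            w += 1
            continue
        best = None
        for j in range(w, w + pw):
            if not math.isnan(values[j]) and (best is None or values[j] > values[best]):
                best = j
        if best == w + pw - 1 and w + pw < n:
            w += 1  # apex not yet inside the window
            continue
        pc = int(round(coord(best)))
        start, end = pc - 73, pc + 74
        if start < origin_bp or end > span_end or start < prev_end:
            w += 1
            continue
        centers.append(pc)
        prev_end = end
        w_next = math.ceil((pc + 74 - origin_bp - window_bp / 2) / step_bp)
        w = max(w + 1, w_next)
    return centers


def valley_calls_literal(values, step_bp, window_bp, origin_bp, ps, scan_window_bp=165):
    """Valley-detection mirror of the literal scan (argmin, max-min range)."""
    flipped = [-v for v in values]
    return dlane_literal(flipped, step_bp, window_bp, origin_bp, ps, scan_window_bp)


def enumerate_legal_paths(n, allow_abutting=True):
    """All legal 16-state paths of length n (DFS over the transition set)."""
    succ = {0: [0, 1]}
    for k in range(1, 15):
        succ[k] = [k + 1]
    succ[15] = [0, 1] if allow_abutting else [0]
    paths = []

    def walk(prefix):
        if len(prefix) == n:
            paths.append(tuple(prefix))
            return
        for nxt in succ[prefix[-1]]:
            walk(prefix + [nxt])

    for start in range(16):
        walk([start])
    return paths


def viterbi_bruteforce(model, X):
    """Best path by exhaustive enumeration of all legal paths."""
    best_lp, best_path = -np.inf, None
    for path in enumerate_legal_paths(np.atleast_2d(X).shape[0] if np.asarray(X).ndim > 1 else len(X), model.allow_abutting):
        lp = model.path_log_prob(X, path)
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return best_lp, np.array(best_path)


def greedy_match_bruteforce(pred_centers, ref_centers, cutoff):
    """One-to-one greedy matching by full pair enumeration and sorting."""
    pairs = []
    for i, p in enumerate(pred_centers):
        for j, r in enumerate(ref_centers):
            d = abs(p - r)
            if d <= cutoff:
                pairs.append((d, r, p, i, j))
    pairs.sort()
    used_p, used_r, tp = set(), set(), 0
    for d, _, _, i, j in pairs:
        if i not in used_p and j not in used_r:
            used_p.add(i)
            used_r.add(j)
            tp += 1
    return tp


def support_counts_bruteforce(centers_by_feature, cutoff=73):
    """(chrom-free) support count per pooled call by pairwise distances."""
    pooled = [
        (c, f) for f, cs in centers_by_feature.items() for c in cs
    ]
    out = []
    for c, f in pooled:
        support = sum(
            1
            for g, gc in centers_by_feature.items()
            if any(abs(c - x) <= cutoff for x in gc)
        )
        out.append(((c, f), support))
    return dict(out)
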