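"""Nucleosome positioning with a 16-state hidden Markov model.

States: one linker state ``L0`` plus 15 ordered nucleosome states
``N1..N15`` -- at the 10-bp profile resolution a 147-bp nucleosome spans
~15 bins, so a complete left-to-right pass N1 -> ... -> N15 traces one
nucleosome.  Legal transitions are::

    L0 -> L0 | N1        (stay in linker, or enter a nucleosome)
    Nk -> Nk+1 (k < 15)  (march through the nucleosome)
    N15 -> L0 | N1       (exit to linker, or abut the next nucleosome)

Observations are the per-bin vectors of (by default six) structural
profiles; emissions are independent Gaussians per state and channel.
Training is supervised from a reference map (empirical transition counts
with add-one smoothing on the legal transitions; per-state sample
means/variances).  Decoding is exact Viterbi in the log domain with
leftmost tie-breaking; masked channels simply drop out of a bin's
emission term.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .calls import NucleosomeCall, ReferenceMap
from .profiles import BinnedTrack

LINKER = 0
N_NUC_STATES = 15
N_STATES = N_NUC_STATES + 1

_LOG_2PI = float(np.log(2 * np.pi))


def allowed_transitions(allow_abutting: bool = True) -> np.ndarray:
    """Boolean (16, 16) mask of legal transitions."""
    mask = np.zeros((N_STATES, N_STATES), dtype=bool)
    mask[LINKER, LINKER] = True
    mask[LINKER, 1] = True
    for k in range(1, N_NUC_STATES):
        mask[k, k + 1] = True
    mask[N_NUC_STATES, LINKER] = True
    if allow_abutting:
        mask[N_NUC_STATES, 1] = True
    return mask


def labels_to_state_path(reference: ReferenceMap, track: BinnedTrack) -> np.ndarray:
    """Map a reference nucleosome map onto a track's bins as a state path.

    Each reference centre claims the 15 bins whose representative
    coordinates fall in the 15-bin window centred on it; those bins get
    N1..N15 left to right and all other bins are linker.  Nucleosomes
    truncated by the track boundary are skipped; overlapping reference
    nucleosomes (in bin space) are an error.
    """
    coords = track.coords()
    n = len(coords)
    path = np.zeros(n, dtype=int)
    claimed = np.zeros(n, dtype=bool)
    half_span = N_NUC_STATES * track.step_bp / 2
    centers = reference.centers.get(track.chrom, np.empty(0, dtype=int))
    for c in centers:
        lo = np.searchsorted(coords, c - half_span, side="left")
        hi = np.searchsorted(coords, c + half_span, side="left")
        if hi - lo < N_NUC_STATES:
            continue  # truncated at the track edge
        if hi - lo > N_NUC_STATES:
            hi = lo + N_NUC_STATES
        if claimed[lo:hi].any():
            raise ValueError(
                f"reference nucleosomes overlap in bin space on {track.chrom} "
                f"near {int(c)}"
            )
        path[lo:hi] = np.arange(1, N_NUC_STATES + 1)
        claimed[lo:hi] = True
    return path


class NucleosomeHMM(BaseEstimator):
    """Supervised 16-state chromatin HMM over structural-profile channels."""

    def __init__(self, allow_abutting: bool = True, var_floor: float = 1e-6):
        self.allow_abutting = allow_abutting
        self.var_floor = var_floor

    def fit(self, X, path):
        """Supervised training from observations and a known state path.

        ``X`` is (n_bins, n_channels) with NaN for masked entries; ``path``
        is the aligned state sequence (0 = linker).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and len(path) != 1:
            X = X.T
        path = np.asarray(path, dtype=int)
        if len(path) != X.shape[0]:
            raise ValueError("path length must match number of observation rows")

        mask = allowed_transitions(self.allow_abutting)
        counts = np.zeros((N_STATES, N_STATES))
        for a, b in zip(path[:-1], path[1:]):
            if not mask[a, b]:
                raise ValueError(f"training path uses illegal transition {a} -> {b}")
            counts[a, b] += 1
        trans = np.zeros((N_STATES, N_STATES))
        for s in range(N_STATES):
            allowed = np.flatnonzero(mask[s])
            smoothed = counts[s, allowed] + 1.0
            trans[s, allowed] = smoothed / smoothed.sum()

        n_channels = X.shape[1]
        means = np.zeros((N_STATES, n_channels))
        variances = np.ones((N_STATES, n_channels))
        for s in range(N_STATES):
            rows = X[path == s]
            if rows.shape[0] < 2:
                raise ValueError(
                    f"state {s} has {rows.shape[0]} assigned bin(s); need >= 2 "
                    "for emission estimates"
                )
            means[s] = np.nanmean(rows, axis=0)
            variances[s] = np.maximum(np.nanvar(rows, axis=0), self.var_floor)

        start = np.bincount(path, minlength=N_STATES) + 1.0
        self.start_probs_ = start / start.sum()
        self.transitions_ = trans
        self.means_ = means
        self.variances_ = variances
        self.n_channels_ = n_channels
        self.transition_mask_ = mask
        return self

    def emission_log_probs(self, X) -> np.ndarray:
        """(n_bins, 16) per-state log density; masked channels omitted."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_channels_:
            X = X.T
        n = X.shape[0]
        out = np.zeros((n, N_STATES))
        finite = np.isfinite(X)
        Xf = np.nan_to_num(X)
        for s in range(N_STATES):
            mu = self.means_[s]
            var = self.variances_[s]
            ll = -0.5 * (_LOG_2PI + np.log(var) + (Xf - mu) ** 2 / var)
            out[:, s] = np.where(finite, ll, 0.0).sum(axis=1)
        return out

    def predict(self, X) -> np.ndarray:
        """Most probable legal state path (Viterbi)."""
        return self.decode(X)[1]

    def decode(self, X):
        """Log-domain Viterbi; returns ``(log_prob, path)``.

        Ties are broken toward the lowest state index, deterministically.
        """
        emit = self.emission_log_probs(X)
        n = emit.shape[0]
        with np.errstate(divide="ignore"):
            log_trans = np.where(
                self.transition_mask_, np.log(np.maximum(self.transitions_, 1e-300)), -np.inf
            )
            log_start = np.log(self.start_probs_)
        delta = log_start + emit[0]
        back = np.zeros((n, N_STATES), dtype=int)
        for t in range(1, n):
            cand = delta[:, None] + log_trans  # (from, to)
            back[t] = np.argmax(cand, axis=0)  # argmax takes first (lowest) index
            delta = cand[back[t], np.arange(N_STATES)] + emit[t]
        last = int(np.argmax(delta))
        path = np.empty(n, dtype=int)
        path[-1] = last
        for t in range(n - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        return float(np.max(delta)), path

    def path_log_prob(self, X, path) -> float:
        """Joint log probability of a given state path and observations."""
        emit = self.emission_log_probs(X)
        path = np.asarray(path, dtype=int)
        with np.errstate(divide="ignore"):
            lp = float(np.log(self.start_probs_[path[0]])) + float(emit[0, path[0]])
            for t in range(1, len(path)):
                lp += float(np.log(self.transitions_[path[t - 1], path[t]]))
                lp += float(emit[t, path[t]])
        return lp


def path_to_calls(path, track: BinnedTrack, source: str = "hmm") -> list[NucleosomeCall]:
    """Convert maximal complete N1..N15 runs into 147-bp calls.

    The call centre is the bp midpoint of the run; runs truncated at the
    sequence ends (incomplete passes) are discarded.
    """
    path = np.asarray(path, dtype=int)
    coords = track.coords()
    calls = []
    i = 0
    n = len(path)
    while i < n:
        if path[i] == 1 and i + N_NUC_STATES <= n and np.array_equal(
            path[i : i + N_NUC_STATES], np.arange(1, N_NUC_STATES + 1)
        ):
            mid = (coords[i] + coords[i + N_NUC_STATES - 1]) / 2
            calls.append(
                NucleosomeCall.from_center(track.chrom, int(round(mid)), source=source)
            )
            i += N_NUC_STATES
        else:
            i += 1
    return calls
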