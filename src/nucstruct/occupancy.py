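"""Linear prediction of continuous nucleosome occupancy from structural
profiles via least angle regression (LARS).

The twelve smoothed structural profiles, aligned on shared bins with an
occupancy track, form the design matrix.  LARS computes the equiangular
forward-selection coefficient path; the final model is the path point
minimising Mallows' Cp (configurable to the full-path OLS endpoint).
Features are centred and scaled internally; reported coefficients are on
the original profile scale.  Training and test chromosomes are kept
disjoint by fitting and predicting on separately aligned matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import lars_path

from .profiles import BinnedTrack, OccupancyTrack, StructuralProfile


def align_tracks(
    profiles: list[StructuralProfile],
    occupancy: OccupancyTrack | None = None,
    feature_order: list[str] | None = None,
):
    """Intersect profiles (and optionally an occupancy track) on shared,
    unmasked bins of one chromosome.

    Returns ``(X, y, coords)`` where rows are bins present and finite in
    every input and columns follow ``feature_order`` (default: feature
    names sorted alphabetically, so shuffled inputs give an identical
    matrix).  ``y`` is None when no occupancy track is given.
    """
    if not profiles:
        raise ValueError("no profiles given")
    chroms = {p.chrom for p in profiles}
    steps = {p.step_bp for p in profiles}
    if occupancy is not None:
        chroms.add(occupancy.chrom)
        steps.add(occupancy.step_bp)
    if len(chroms) != 1:
        raise ValueError(f"tracks span multiple chromosomes: {sorted(chroms)}")
    if len(steps) != 1:
        raise ValueError("tracks have differing bin steps")

    by_feature = {p.feature: p for p in profiles}
    if feature_order is None:
        feature_order = sorted(by_feature)
    missing = [f for f in feature_order if f not in by_feature]
    if missing:
        raise ValueError(f"profiles missing for features {missing}")

    tracks: list[BinnedTrack] = [by_feature[f] for f in feature_order]
    if occupancy is not None:
        tracks.append(occupancy)

    common = tracks[0].coords()
    for t in tracks[1:]:
        common = np.intersect1d(common, t.coords())
    if len(common) == 0:
        raise ValueError("tracks share no bins")

    cols = []
    for t in tracks:
        idx = np.searchsorted(t.coords(), common)
        cols.append(t.values[idx])
    mat = np.column_stack(cols)
    keep = np.all(np.isfinite(mat), axis=1)
    mat = mat[keep]
    coords = common[keep]
    if mat.shape[0] == 0:
        raise ValueError("no shared unmasked bins")
    if occupancy is not None:
        return mat[:, :-1], mat[:, -1], coords
    return mat, None, coords


class LarsOccupancyRegressor(BaseEstimator, RegressorMixin):
    """LARS linear model for nucleosome occupancy.

    Parameters
    ----------
    stop : {"cp", "full"}
        Model-selection rule along the LARS path: the Mallows'
        Cp-minimising point (default) or the full-path OLS endpoint.

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : model on the original feature scale.
    entry_order_ : feature indices in order of entry onto the path.
    stop_index_ : selected point on the path.
    cp_path_ : Cp value at every path point.
    """

    def __init__(self, stop: str = "cp"):
        self.stop = stop

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        if n < p + 1:
            raise ValueError(f"need at least {p + 1} rows for {p} features, got {n}")
        if self.stop not in ("cp", "full"):
            raise ValueError("stop must be 'cp' or 'full'")

        x_mean = X.mean(axis=0)
        x_std = X.std(axis=0)
        keep = x_std > 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} constant feature column(s)",
                RuntimeWarning,
                stacklevel=2,
            )
        Xs = (X[:, keep] - x_mean[keep]) / x_std[keep]
        rank = int(np.linalg.matrix_rank(Xs))
        if rank < Xs.shape[1]:
            # Collinear feature sets are expected (strand-symmetric
            # dinucleotide scales are linearly dependent by construction);
            # the LARS path simply stops once the column space is exhausted.
            warnings.warn(
                f"design matrix has rank {rank} < {Xs.shape[1]} columns; "
                "the LARS path will not activate every feature",
                RuntimeWarning,
                stacklevel=2,
            )
        y_mean = y.mean()
        yc = y - y_mean

        alphas, active, coef_path = lars_path(Xs, yc, method="lar")
        n_steps = coef_path.shape[1]

        resid = yc[:, None] - Xs @ coef_path
        rss = np.sum(resid**2, axis=0)
        # noise scale from the least-squares fit (stable under collinearity,
        # unlike the last path point)
        ols_resid = yc - Xs @ np.linalg.lstsq(Xs, yc, rcond=None)[0]
        sigma2 = float(ols_resid @ ols_resid) / max(n - rank - 1, 1)
        df = np.count_nonzero(coef_path, axis=0) + 1
        cp = rss / sigma2 - n + 2 * df

        self.cp_path_ = cp
        self.alphas_ = alphas
        self.entry_order_ = list(active)
        self.stop_index_ = int(np.argmin(cp)) if self.stop == "cp" else n_steps - 1

        coef_std = coef_path[:, self.stop_index_]
        coef = np.zeros(p)
        coef[keep] = coef_std / x_std[keep]
        self.coef_ = coef
        self.intercept_ = float(y_mean - coef @ x_mean)
        self.n_features_in_ = p
        self.kept_features_ = keep
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def predict_occupancy(
    model: LarsOccupancyRegressor,
    profiles: list[StructuralProfile],
    feature_order: list[str] | None = None,
) -> OccupancyTrack:
    """Apply a fitted model to aligned profiles of one chromosome.

    Output bins are masked wherever any input profile is masked.
    """
    if feature_order is None:
        feature_order = sorted({p.feature for p in profiles})
    by_feature = {p.feature: p for p in profiles}
    tracks = [by_feature[f] for f in feature_order]
    common = tracks[0].coords()
    for t in tracks[1:]:
        common = np.intersect1d(common, t.coords())
    if len(common) == 0:
        raise ValueError("profiles share no bins")
    cols = []
    for t in tracks:
        idx = np.searchsorted(t.coords(), common)
        cols.append(t.values[idx])
    X = np.column_stack(cols)
    pred = np.where(
        np.all(np.isfinite(X), axis=1),
        np.nan_to_num(X) @ model.coef_ + model.intercept_,
        np.nan,
    )
    ref = tracks[0]
    origin = common[0] - ref.window_bp / 2
    return OccupancyTrack(
        chrom=ref.chrom,
        values=pred,
        origin_bp=int(origin),
        step_bp=ref.step_bp,
        window_bp=ref.window_bp,
    )
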