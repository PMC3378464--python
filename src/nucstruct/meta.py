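"""Meta-prediction: integrating per-feature nucleosome call sets.

Every call made by any single structural feature becomes a candidate.  A
candidate is described by (i) how many distinct features predict a
nucleosome within 73 bp of it, (ii) the distance to its closest other
candidate, and (iii) one indicator per feature.  A Random-Forest
classifier, trained against a reference map on one chromosome, accepts or
rejects candidates; accepted candidates within 73 bp of each other are
clustered and each cluster's middle candidate becomes a meta call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .calls import HALF_NUCLEOSOME_BP, NucleosomeCall, ReferenceMap

CLUSTER_BP = HALF_NUCLEOSOME_BP  # 73 bp both for support counting and clustering


@dataclass(frozen=True)
class Candidate:
    chrom: str
    center_bp: int
    source: str
    support_count: int
    nearest_neighbor_bp: float
    per_feature_flags: tuple[bool, ...]

    def feature_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                [self.support_count, self.nearest_neighbor_bp],
                np.asarray(self.per_feature_flags, dtype=float),
            ]
        )


def build_candidates(
    call_sets: dict[str, list[NucleosomeCall]],
) -> list[Candidate]:
    """Pool per-feature call sets into annotated candidates.

    ``support_count`` counts features (including the candidate's own
    source) with a call centre within 73 bp; ``nearest_neighbor_bp`` is the
    distance to the closest other candidate in the pooled set.
    """
    if len(call_sets) < 2:
        raise ValueError("need call sets from at least two features")
    features = list(call_sets)
    pooled: list[tuple[str, int, str]] = []  # (chrom, center, feature)
    for feat in features:
        for c in call_sets[feat]:
            pooled.append((c.chrom, c.center_bp, feat))
    if not pooled:
        return []

    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, center, feat in pooled:
        by_chrom.setdefault(chrom, []).append((center, feat))

    candidates: list[Candidate] = []
    for chrom, items in by_chrom.items():
        items.sort()
        centers = np.array([c for c, _ in items])
        feats = [f for _, f in items]
        per_feature_centers = {
            feat: np.array(sorted(c for c, f in items if f == feat))
            for feat in features
        }
        for i, (center, feat) in enumerate(items):
            flags = []
            for other in features:
                fc = per_feature_centers[other]
                if len(fc) == 0:
                    flags.append(False)
                    continue
                j = np.searchsorted(fc, center)
                dmin = min(
                    abs(int(fc[j - 1]) - center) if j > 0 else np.inf,
                    abs(int(fc[j]) - center) if j < len(fc) else np.inf,
                )
                flags.append(dmin <= CLUSTER_BP)
            # closest other candidate (pooled, any feature)
            left = center - int(centers[i - 1]) if i > 0 else np.inf
            right = int(centers[i + 1]) - center if i + 1 < len(centers) else np.inf
            nn = float(min(left, right))
            candidates.append(
                Candidate(
                    chrom=chrom,
                    center_bp=center,
                    source=feat,
                    support_count=int(sum(flags)),
                    nearest_neighbor_bp=nn,
                    per_feature_flags=tuple(flags),
                )
            )
    return candidates


def label_candidates(
    candidates: list[Candidate],
    reference: ReferenceMap,
    label_cutoff_bp: int = 35,
) -> np.ndarray:
    """1 where a candidate centre lies within the cutoff of any reference
    centre, else 0."""
    labels = np.zeros(len(candidates), dtype=int)
    for i, cand in enumerate(candidates):
        centers = reference.centers.get(cand.chrom)
        if centers is None or len(centers) == 0:
            continue
        j = np.searchsorted(centers, cand.center_bp)
        dmin = min(
            abs(int(centers[j - 1]) - cand.center_bp) if j > 0 else np.inf,
            abs(int(centers[j]) - cand.center_bp) if j < len(centers) else np.inf,
        )
        labels[i] = int(dmin <= label_cutoff_bp)
    return labels


class MetaPredictor(BaseEstimator, ClassifierMixin):
    """Random-Forest accept/reject classifier over pooled candidates.

    Parameters
    ----------
    n_estimators : number of trees (default 100).
    label_cutoff_bp : candidate-to-reference distance defining a positive
        training label (default 35 bp).
    cluster_bp : single-linkage clustering distance for accepted
        candidates (default 73 bp).
    random_state : seed recorded with the fitted model.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        label_cutoff_bp: int = 35,
        cluster_bp: int = CLUSTER_BP,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.label_cutoff_bp = label_cutoff_bp
        self.cluster_bp = cluster_bp
        self.random_state = random_state

    def fit(self, candidates: list[Candidate], reference: ReferenceMap):
        """Train on candidates from one (training) chromosome set."""
        if not candidates:
            raise ValueError("no candidates to train on")
        y = label_candidates(candidates, reference, self.label_cutoff_bp)
        if len(np.unique(y)) < 2:
            raise ValueError(
                "training labels are single-class; widen the label cutoff or "
                "use data with both matched and unmatched candidates"
            )
        X = np.vstack([c.feature_vector() for c in candidates])
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        )
        self.forest_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = self.forest_.classes_
        self.training_chroms_ = sorted({c.chrom for c in candidates})
        return self

    def accept(self, candidates: list[Candidate]) -> np.ndarray:
        """Boolean accept/reject decision per candidate."""
        if not hasattr(self, "forest_"):
            raise ValueError("MetaPredictor is not fitted")
        if not candidates:
            return np.zeros(0, dtype=bool)
        X = np.vstack([c.feature_vector() for c in candidates])
        return self.forest_.predict(X).astype(bool)

    def predict(self, candidates: list[Candidate]) -> list[NucleosomeCall]:
        """Accepted candidates -> clustered, non-overlapping meta calls."""
        accepted = [c for c, a in zip(candidates, self.accept(candidates)) if a]
        return cluster_candidates(accepted, cluster_bp=self.cluster_bp)


def cluster_candidates(
    accepted: list[Candidate], cluster_bp: int = CLUSTER_BP
) -> list[NucleosomeCall]:
    """Single-linkage clustering of accepted candidates at ``cluster_bp``.

    Per cluster the median-centre candidate is emitted (lower median for
    even cluster sizes).  Overlapping survivors are resolved greedily by
    descending support count.
    """
    by_chrom: dict[str, list[Candidate]] = {}
    for c in accepted:
        by_chrom.setdefault(c.chrom, []).append(c)

    picked: list[Candidate] = []
    for chrom in sorted(by_chrom):
        cands = sorted(by_chrom[chrom], key=lambda c: c.center_bp)
        cluster: list[Candidate] = []
        for cand in cands:
            if cluster and cand.center_bp - cluster[-1].center_bp > cluster_bp:
                picked.append(cluster[(len(cluster) - 1) // 2])
                cluster = []
            cluster.append(cand)
        if cluster:
            picked.append(cluster[(len(cluster) - 1) // 2])

    # resolve residual overlaps by descending support, then position
    picked.sort(key=lambda c: (-c.support_count, c.chrom, c.center_bp))
    kept: list[Candidate] = []
    for cand in picked:
        lo, hi = cand.center_bp - HALF_NUCLEOSOME_BP, cand.center_bp + HALF_NUCLEOSOME_BP + 1
        if all(
            k.chrom != cand.chrom
            or hi <= k.center_bp - HALF_NUCLEOSOME_BP
            or lo >= k.center_bp + HALF_NUCLEOSOME_BP + 1
            for k in kept
        ):
            kept.append(cand)
    kept.sort(key=lambda c: (c.chrom, c.center_bp))
    return [
        NucleosomeCall.from_center(
            c.chrom, c.center_bp, score=float(c.support_count), source="meta"
        )
        for c in kept
    ]
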