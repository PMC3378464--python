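"""Scoring predicted nucleosome positions against a reference map.

A prediction is correct when its centre lies within ``L`` bp of a
reference centre; matching is one-to-one (greedy in increasing distance),
so redundant predictions of the same reference nucleosome are penalised.
Sensitivity ``Se = TP / n_reference``, specificity ``Sp = TP /
n_predicted`` and the harmonic F-measure ``2*Se*Sp/(Se+Sp)`` summarise a
call set; a uniformly random set of non-overlapping calls with the
reference's per-chromosome counts serves as the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calls import NUCLEOSOME_BP, NucleosomeCall, ReferenceMap
from .profiles import BinnedTrack


@dataclass(frozen=True)
class EvalResult:
    cutoff_bp: int
    true_positive: int
    n_reference: int
    n_predicted: int

    @property
    def sensitivity(self) -> float:
        return self.true_positive / self.n_reference if self.n_reference else 0.0

    @property
    def specificity(self) -> float:
        return self.true_positive / self.n_predicted if self.n_predicted else 0.0

    @property
    def f_measure(self) -> float:
        return f_measure(self.sensitivity, self.specificity)


def f_measure(se: float, sp: float) -> float:
    """Harmonic mean 2*Se*Sp/(Se+Sp); 0 when both rates are 0."""
    if se + sp == 0:
        return 0.0
    return 2.0 * se * sp / (se + sp)


def match_calls(
    predicted: list[NucleosomeCall],
    reference: ReferenceMap,
    cutoff_bp: int,
) -> list[tuple[int, int, int]]:
    """One-to-one greedy matching of predictions to reference centres.

    Candidate pairs within the cutoff are taken in increasing distance
    order (ties broken by reference then prediction position); each
    prediction and each reference centre matches at most once.  Returns
    ``(pred_index, ref_chrom_index, distance)`` triples.
    """
    if cutoff_bp <= 0:
        raise ValueError("cutoff must be positive")
    matches: list[tuple[int, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, call in enumerate(predicted):
        by_chrom.setdefault(call.chrom, []).append((call.center_bp, i))
    for chrom, preds in by_chrom.items():
        refs = reference.centers.get(chrom)
        if refs is None or len(refs) == 0:
            continue
        pairs = []
        for center, i in preds:
            lo = np.searchsorted(refs, center - cutoff_bp, side="left")
            hi = np.searchsorted(refs, center + cutoff_bp, side="right")
            for j in range(lo, hi):
                d = abs(int(refs[j]) - center)
                if d <= cutoff_bp:
                    pairs.append((d, int(refs[j]), center, i, j))
        pairs.sort()
        used_pred: set[int] = set()
        used_ref: set[int] = set()
        for d, _, _, i, j in pairs:
            if i in used_pred or j in used_ref:
                continue
            used_pred.add(i)
            used_ref.add(j)
            matches.append((i, j, d))
    return matches


def score(
    predicted: list[NucleosomeCall],
    reference: ReferenceMap,
    cutoff_bp: int,
) -> EvalResult:
    """Match and summarise one call set at one distance cutoff."""
    matches = match_calls(predicted, reference, cutoff_bp)
    return EvalResult(
        cutoff_bp=cutoff_bp,
        true_positive=len(matches),
        n_reference=reference.n(),
        n_predicted=len(predicted),
    )


def sweep_cutoffs(
    predicted: list[NucleosomeCall],
    reference: ReferenceMap,
    cutoffs=(10, 20, 30, 40, 50, 60),
) -> list[EvalResult]:
    return [score(predicted, reference, L) for L in cutoffs]


def random_baseline(
    reference: ReferenceMap,
    chrom_lengths: dict[str, int],
    seed: int = 0,
) -> list[NucleosomeCall]:
    """Random non-overlapping calls, matched per chromosome in number.

    Placements are drawn uniformly among all legal non-overlapping
    configurations: n sorted draws from the gap-collapsed coordinate space
    ``[0, length - n*147]`` are expanded by one nucleosome width each.
    This stays exact at the high packing densities of real reference maps
    (where naive rejection sampling stalls) and is deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    calls: list[NucleosomeCall] = []
    for chrom in sorted(reference.centers):
        n = reference.n(chrom)
        length = chrom_lengths.get(chrom)
        if length is None:
            raise ValueError(f"no length known for chromosome {chrom!r}")
        free = length - n * NUCLEOSOME_BP
        if free < 0:
            raise ValueError(
                f"{chrom}: cannot place {n} non-overlapping nucleosomes in "
                f"{length} bp"
            )
        collapsed = np.sort(rng.integers(0, free + 1, size=n))
        starts = collapsed + np.arange(n) * NUCLEOSOME_BP
        for s in starts:
            calls.append(
                NucleosomeCall(chrom, int(s), int(s) + NUCLEOSOME_BP, source="random")
            )
    return calls


def pearson_correlation(a: BinnedTrack, b: BinnedTrack) -> float:
    """Pearson r between two tracks over their shared unmasked bins."""
    if a.chrom != b.chrom:
        raise ValueError("tracks are on different chromosomes")
    if a.step_bp != b.step_bp:
        raise ValueError("tracks have differing bin steps")
    common, ia, ib = np.intersect1d(a.coords(), b.coords(), return_indices=True)
    if len(common) == 0:
        raise ValueError("tracks share no bins")
    x = a.values[ia]
    y = b.values[ib]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared unmasked bins")
    return float(stats.pearsonr(x[ok], y[ok]).statistic)
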