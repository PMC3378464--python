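"""End-to-end synthetic benchmark used by the test suite and the
acceptance script.

One run simulates a two-chromosome genome (training + held-out test),
computes all twelve structural profiles, and measures on the test
chromosome: per-feature DLaNe accuracy, the Random-Forest meta-predictor,
the 16-state HMM, the random baseline, and the held-out Pearson
correlation of the LARS occupancy model.
"""

from __future__ import annotations

import warnings

import numpy as np

from .calls import NucleosomeCall, ReferenceMap
from .dlane import DLaNePeakCaller
from .evaluation import pearson_correlation, random_baseline, score
from .hmm import NucleosomeHMM, labels_to_state_path, path_to_calls
from .meta import MetaPredictor, build_candidates
from .occupancy import LarsOccupancyRegressor, align_tracks, predict_occupancy
from .profiles import structural_profile
from .scales import FEATURE_NAMES, TOP_FEATURES, load_scales
from .simulate import SimulationConfig, simulate_genome, simulate_occupancy

TRAIN_CHROM = "chrTrain"
TEST_CHROM = "chrTest"


def compute_all_profiles(sequences, scales, window_bp=100, step_bp=10):
    """{chrom: {feature: StructuralProfile}} for every scale."""
    return {
        chrom: {
            name: structural_profile(
                seq, scale, window_bp=window_bp, step_bp=step_bp, chrom=chrom
            )
            for name, scale in scales.items()
        }
        for chrom, seq in sequences.items()
    }


def synthetic_benchmark(
    seed: int,
    chrom_bp: int = 50_000,
    cutoff_bp: int = 35,
    ps: float = 0.45,
    contrast: float = 1.0,
    noise_sd: float = 0.5,
    meta_features=TOP_FEATURES,
) -> dict:
    """Simulate, predict with every method, and score on the held-out
    chromosome.  Returns a flat dict of metrics."""
    cfg = SimulationConfig(
        chrom_lengths={TRAIN_CHROM: chrom_bp, TEST_CHROM: chrom_bp},
        seed=seed,
        contrast=contrast,
        occupancy_noise_sd=noise_sd,
    )
    genome = simulate_genome(cfg)
    scales = load_scales()
    profiles = compute_all_profiles(genome.sequences, scales)
    truth_test = genome.truth.subset([TEST_CHROM])
    truth_train = genome.truth.subset([TRAIN_CHROM])

    caller = DLaNePeakCaller(ps=ps)
    calls: dict[str, dict[str, list[NucleosomeCall]]] = {}
    for chrom in (TRAIN_CHROM, TEST_CHROM):
        calls[chrom] = {
            name: caller.predict(profiles[chrom][name], scales[name])
            for name in FEATURE_NAMES
        }

    results: dict[str, float] = {}
    per_feature = {}
    for name in FEATURE_NAMES:
        r = score(calls[TEST_CHROM][name], truth_test, cutoff_bp)
        per_feature[name] = r
        results[f"dlane_{name}_f"] = r.f_measure
    best = max(per_feature, key=lambda n: per_feature[n].f_measure)
    results["dlane_best_feature"] = best
    results["dlane_best_se"] = per_feature[best].sensitivity
    results["dlane_best_sp"] = per_feature[best].specificity
    results["dlane_best_f"] = per_feature[best].f_measure
    results["dlane_median_f"] = float(
        np.median([r.f_measure for r in per_feature.values()])
    )

    # meta-predictor: train on the training chromosome, apply to the test one
    meta = MetaPredictor(label_cutoff_bp=cutoff_bp, random_state=seed % (2**31))
    cand_train = build_candidates(
        {f: calls[TRAIN_CHROM][f] for f in meta_features}
    )
    cand_test = build_candidates({f: calls[TEST_CHROM][f] for f in meta_features})
    meta.fit(cand_train, truth_train)
    meta_calls = meta.predict(cand_test)
    r_meta = score(meta_calls, truth_test, cutoff_bp)
    results["meta_se"] = r_meta.sensitivity
    results["meta_sp"] = r_meta.specificity
    results["meta_f"] = r_meta.f_measure

    # HMM over the six top-feature channels
    feats = list(meta_features)
    track0 = profiles[TRAIN_CHROM][feats[0]]
    X_train = np.column_stack([profiles[TRAIN_CHROM][f].values for f in feats])
    X_test = np.column_stack([profiles[TEST_CHROM][f].values for f in feats])
    hmm = NucleosomeHMM()
    hmm.fit(X_train, labels_to_state_path(truth_train, track0))
    hmm_path = hmm.predict(X_test)
    hmm_calls = path_to_calls(hmm_path, profiles[TEST_CHROM][feats[0]])
    r_hmm = score(hmm_calls, truth_test, cutoff_bp)
    results["hmm_se"] = r_hmm.sensitivity
    results["hmm_sp"] = r_hmm.specificity
    results["hmm_f"] = r_hmm.f_measure

    # random baseline, matched in per-chromosome call count
    rand_calls = random_baseline(
        truth_test, {TEST_CHROM: chrom_bp}, seed=seed % (2**31)
    )
    r_rand = score(rand_calls, truth_test, cutoff_bp)
    results["random_se"] = r_rand.sensitivity
    results["random_f"] = r_rand.f_measure

    # LARS occupancy model: fit on train, correlate on test
    order = list(FEATURE_NAMES)
    occ_train = simulate_occupancy(genome, TRAIN_CHROM)
    occ_test = simulate_occupancy(genome, TEST_CHROM)
    X, y, _ = align_tracks(
        list(profiles[TRAIN_CHROM].values()), occ_train, feature_order=order
    )
    with warnings.catch_warnings():
        # the 12 strand-symmetric scales are collinear by construction;
        # the truncated LARS path is the intended behaviour here
        warnings.simplefilter("ignore", RuntimeWarning)
        lars = LarsOccupancyRegressor().fit(X, y)
    pred = predict_occupancy(
        lars, list(profiles[TEST_CHROM].values()), feature_order=order
    )
    results["lars_heldout_r"] = pearson_correlation(pred, occ_test)

    return results
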