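"""Synthetic genomes with planted nucleosomes.

Chromosomes are built as alternating 147-bp cores and short linkers
(10-20 bp, the yeast regime), with occasional longer nucleosome-free
regions.  Cores and linkers are drawn from different base compositions --
GC-rich cores versus AT-rich linkers -- so that every positively
correlated structural scale has a higher expected raw value inside cores
than in linkers, mirroring the structural contrast between
nucleosome-enriched and nucleosome-depleted sequence that the prediction
methods exploit.  The ``contrast`` knob scales the compositional
divergence; at 0 cores and linkers are indistinguishable.

The companion occupancy track is the boxcar-smoothed core indicator,
binned like the structural profiles, plus Gaussian noise -- a stand-in
for an MNase log-ratio signal (nucleosomes as ~150-bp peaks between
depleted valleys).

All randomness flows from one seed through a counter-based stream per
chromosome, so outputs are byte-identical for a given configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calls import NUCLEOSOME_BP, ReferenceMap
from .profiles import OccupancyTrack, smooth_profile

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 50_000, "chrS2": 50_000}
    )
    nucleosome_bp: int = NUCLEOSOME_BP
    linker_min: int = 10
    linker_max: int = 20
    contrast: float = 1.0
    free_fraction: float = 0.1
    free_len_range: tuple[int, int] = (300, 800)
    occupancy_noise_sd: float = 0.5
    occupancy_smooth_bp: int = 100
    window_bp: int = 100
    step_bp: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.linker_min > self.linker_max or self.linker_min < 0:
            raise ValueError("invalid linker length range")
        if not 0 <= self.free_fraction < 1:
            raise ValueError("free_fraction must lie in [0, 1)")
        for length in self.chrom_lengths.values():
            if length <= 0:
                raise ValueError("chromosome lengths must be positive")

    @property
    def core_gc(self) -> float:
        """GC fraction of core sequence; 0.85 at the default contrast,
        emulating strongly positioned, GC-rich cores."""
        return float(np.clip(0.5 + 0.35 * self.contrast, 0.02, 0.98))

    @property
    def linker_gc(self) -> float:
        """GC fraction of linker/free sequence; 0.02 at the default
        contrast, emulating poly(dA:dT)-like depleted regions."""
        return float(np.clip(0.5 - 0.48 * self.contrast, 0.02, 0.98))


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    truth: ReferenceMap
    free_regions: dict[str, list[tuple[int, int]]]
    config: SimulationConfig


def _draw_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]
    return _BASES[rng.choice(4, size=n, p=probs)]


def _chrom_rng(cfg: SimulationConfig, chrom: str, stream: int) -> np.random.Generator:
    idx = list(cfg.chrom_lengths).index(chrom)
    return np.random.default_rng([cfg.seed, idx, stream])


def simulate_genome(cfg: SimulationConfig) -> SimulatedGenome:
    """Generate FASTA-ready sequences plus the truth nucleosome map."""
    sequences: dict[str, str] = {}
    centers: dict[str, list[int]] = {}
    free_regions: dict[str, list[tuple[int, int]]] = {}

    # probability that a cycle emits a free region instead of core+linker,
    # chosen so the expected free fraction matches the configuration
    mean_cycle = cfg.nucleosome_bp + (cfg.linker_min + cfg.linker_max) / 2
    mean_free = sum(cfg.free_len_range) / 2
    f = cfg.free_fraction
    p_free = f * mean_cycle / (mean_free * (1 - f) + mean_cycle * f) if f > 0 else 0.0

    for chrom, length in cfg.chrom_lengths.items():
        if length < cfg.nucleosome_bp + cfg.linker_max:
            raise ValueError(
                f"{chrom}: length {length} cannot fit a nucleosome plus linker"
            )
        rng = _chrom_rng(cfg, chrom, 0)
        parts: list[np.ndarray] = []
        centers[chrom] = []
        free_regions[chrom] = []
        pos = 0
        while pos + cfg.nucleosome_bp <= length:
            if p_free > 0 and rng.random() < p_free:
                flen = int(rng.integers(cfg.free_len_range[0], cfg.free_len_range[1] + 1))
                flen = min(flen, length - pos)
                parts.append(_draw_seq(rng, flen, cfg.linker_gc))
                free_regions[chrom].append((pos, pos + flen))
                pos += flen
                continue
            parts.append(_draw_seq(rng, cfg.nucleosome_bp, cfg.core_gc))
            centers[chrom].append(pos + cfg.nucleosome_bp // 2)
            pos += cfg.nucleosome_bp
            llen = int(rng.integers(cfg.linker_min, cfg.linker_max + 1))
            llen = min(llen, length - pos)
            parts.append(_draw_seq(rng, llen, cfg.linker_gc))
            pos += llen
        if pos < length:
            parts.append(_draw_seq(rng, length - pos, cfg.linker_gc))
        seq = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        sequences[chrom] = seq.tobytes().decode("ascii")

    truth = ReferenceMap({c: np.array(v, dtype=int) for c, v in centers.items()})
    return SimulatedGenome(
        sequences=sequences, truth=truth, free_regions=free_regions, config=cfg
    )


def core_indicator(truth: ReferenceMap, chrom: str, length: int) -> np.ndarray:
    """Per-bp 0/1 vector marking planted 147-bp cores."""
    ind = np.zeros(length, dtype=float)
    for c in truth.centers.get(chrom, ()):
        lo = max(0, int(c) - NUCLEOSOME_BP // 2)
        hi = min(length, int(c) + NUCLEOSOME_BP // 2 + 1)
        ind[lo:hi] = 1.0
    return ind


def simulate_occupancy(
    genome: SimulatedGenome, chrom: str, noise_sd: float | None = None
) -> OccupancyTrack:
    """Noisy occupancy track over the planted cores of one chromosome.

    The core indicator is boxcar-smoothed and binned exactly like the
    structural profiles (so tracks align bin-for-bin), then per-bin
    Gaussian noise of the configured standard deviation is added.
    """
    cfg = genome.config
    sd = cfg.occupancy_noise_sd if noise_sd is None else noise_sd
    length = cfg.chrom_lengths[chrom]
    # match the raw-vector length of a dinucleotide profile so bins align
    ind = core_indicator(genome.truth, chrom, length)[: length - 1]
    if cfg.occupancy_smooth_bp != cfg.window_bp:
        w = max(1, cfg.occupancy_smooth_bp)
        kernel = np.ones(w) / w
        ind = np.convolve(ind, kernel, mode="same")
    prof = smooth_profile(
        ind, window_bp=cfg.window_bp, step_bp=cfg.step_bp, chrom=chrom
    )
    values = prof.values
    if sd > 0:
        rng = _chrom_rng(cfg, chrom, 1)
        values = values + rng.normal(0.0, sd, size=len(values))
    return OccupancyTrack(
        chrom=chrom,
        values=values,
        origin_bp=prof.origin_bp,
        step_bp=prof.step_bp,
        window_bp=prof.window_bp,
    )


def simulate_expression_anchors(
    genome: SimulatedGenome, max_per_class: int | None = None
):
    """Two anchor classes for metaprofile tests.

    Class ``"depleted"`` anchors sit at the centres of nucleosome-free
    regions; class ``"enriched"`` anchors at planted core centres.  Raises
    when either class is empty.
    """
    depleted = []
    enriched = []
    for chrom in genome.config.chrom_lengths:
        for start, end in genome.free_regions.get(chrom, ()):
            depleted.append((chrom, (start + end) // 2, "+"))
        for c in genome.truth.centers.get(chrom, ()):
            enriched.append((chrom, int(c), "+"))
    if max_per_class is not None:
        depleted = depleted[:max_per_class]
        enriched = enriched[:max_per_class]
    if not depleted or not enriched:
        raise ValueError(
            "empty anchor class; simulate with free_fraction > 0 and at "
            "least one planted nucleosome"
        )
    return {"depleted": depleted, "enriched": enriched}
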