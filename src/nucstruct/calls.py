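"""Nucleosome call and reference-map containers.

A call is a legal 147-bp nucleosome: ``end - start == 147`` and calls from
one run never overlap (steric exclusion).  A reference map holds the
experimentally determined (or planted) nucleosome centres per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NUCLEOSOME_BP = 147
HALF_NUCLEOSOME_BP = 73


@dataclass(frozen=True)
class NucleosomeCall:
    chrom: str
    start_bp: int
    end_bp: int
    score: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.end_bp - self.start_bp != NUCLEOSOME_BP:
            raise ValueError(
                f"a nucleosome call must span {NUCLEOSOME_BP} bp, got "
                f"[{self.start_bp}, {self.end_bp})"
            )
        if self.start_bp < 0:
            raise ValueError("call start must be >= 0")

    @property
    def center_bp(self) -> int:
        return self.start_bp + HALF_NUCLEOSOME_BP

    @classmethod
    def from_center(
        cls, chrom: str, center_bp: int, score: float = 0.0, source: str = ""
    ) -> "NucleosomeCall":
        start = int(center_bp) - HALF_NUCLEOSOME_BP
        return cls(chrom, start, start + NUCLEOSOME_BP, score=score, source=source)


def check_non_overlapping(calls) -> None:
    """Raise if any two same-chromosome calls overlap."""
    by_chrom: dict[str, list[NucleosomeCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, cs in by_chrom.items():
        cs = sorted(cs, key=lambda c: c.start_bp)
        for a, b in zip(cs, cs[1:]):
            if b.start_bp < a.end_bp:
                raise ValueError(
                    f"overlapping calls on {chrom}: [{a.start_bp},{a.end_bp}) "
                    f"and [{b.start_bp},{b.end_bp})"
                )


@dataclass
class ReferenceMap:
    """Per-chromosome sorted nucleosome centre positions (bp)."""

    centers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = {
            chrom: np.sort(np.asarray(pos, dtype=int))
            for chrom, pos in self.centers.items()
        }

    @classmethod
    def from_calls(cls, calls) -> "ReferenceMap":
        centers: dict[str, list[int]] = {}
        for c in calls:
            centers.setdefault(c.chrom, []).append(c.center_bp)
        return cls({k: np.array(v) for k, v in centers.items()})

    @classmethod
    def from_intervals(cls, intervals) -> "ReferenceMap":
        """Build from (chrom, start, end) triples; centre = midpoint."""
        centers: dict[str, list[int]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"interval end <= start on {chrom}: {start},{end}")
            centers.setdefault(chrom, []).append((int(start) + int(end)) // 2)
        return cls({k: np.array(v) for k, v in centers.items()})

    def chroms(self):
        return list(self.centers)

    def n(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.centers.get(chrom, ()))
        return sum(len(v) for v in self.centers.values())

    def subset(self, chroms) -> "ReferenceMap":
        chroms = set(chroms)
        return ReferenceMap(
            {c: v.copy() for c, v in self.centers.items() if c in chroms}
        )
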