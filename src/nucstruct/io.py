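"""Readers and writers for FASTA, BED6, bedGraph and TSV tables.

Coordinates are 0-based, half-open throughout (BED convention).  Writers
prepend a provenance comment line; readers skip ``#`` comments and
``track`` lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .calls import NUCLEOSOME_BP, NucleosomeCall, ReferenceMap
from .profiles import BinnedTrack, OccupancyTrack, StructuralProfile


def _provenance(extra: str = "") -> str:
    tag = f"# nucstruct v{__version__}"
    return f"{tag} {extra}".rstrip()


@dataclass
class GenomeIndex:
    """Ordered chromosome names and lengths."""

    names: list[str]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name in self.names:
            if self.lengths.get(name, 0) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "GenomeIndex":
        return cls(list(sequences), {k: len(v) for k, v in sequences.items()})

    @classmethod
    def read_tsv(cls, path) -> "GenomeIndex":
        names, lengths = [], {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
                names.append(fields[0])
                lengths[fields[0]] = int(fields[1])
        return cls(names, lengths)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f"{name}\t{self.lengths[name]}\n")


def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA -> {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


def read_bed(path, one_based: bool = False) -> list[NucleosomeCall]:
    """BED of 147-bp nucleosome calls.  ``one_based`` shifts starts by -1."""
    calls = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if one_based:
            start -= 1
        if end <= start:
            raise ValueError(f"{path}:{lineno}: end <= start")
        name = fields[3] if len(fields) > 3 else ""
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        calls.append(NucleosomeCall(chrom, start, end, score=score, source=name))
    return calls


def read_bed_reference(path, one_based: bool = False) -> ReferenceMap:
    """BED of reference nucleosome intervals -> centre map (any widths)."""
    intervals = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        start, end = int(fields[1]), int(fields[2])
        if one_based:
            start -= 1
        intervals.append((fields[0], start, end))
    return ReferenceMap.from_intervals(intervals)


def write_bed(calls: list[NucleosomeCall], path, provenance: str = "") -> None:
    """BED6; score is the call score scaled into [0, 1000]."""
    scores = [c.score for c in calls]
    smax = max(scores) if scores else 0.0
    with open(path, "w") as fh:
        fh.write(_provenance(provenance) + "\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.start_bp)):
            scaled = int(round(1000 * c.score / smax)) if smax > 0 else 0
            fh.write(
                f"{c.chrom}\t{c.start_bp}\t{c.end_bp}\t{c.source or '.'}\t"
                f"{scaled}\t.\n"
            )


def write_reference_bed(reference: ReferenceMap, path, provenance: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(provenance) + "\n")
        for chrom in reference.centers:
            for c in reference.centers[chrom]:
                start = int(c) - NUCLEOSOME_BP // 2
                fh.write(f"{chrom}\t{start}\t{start + NUCLEOSOME_BP}\tref\t0\t.\n")


def write_bedgraph(track: BinnedTrack, path, provenance: str = "") -> None:
    """bedGraph with intervals of width ``step_bp`` centred on each bin;
    masked bins are omitted."""
    half = (track.window_bp - track.step_bp) / 2
    with open(path, "w") as fh:
        fh.write(_provenance(provenance) + "\n")
        for j, v in enumerate(track.values):
            if not np.isfinite(v):
                continue
            start = int(track.origin_bp + j * track.step_bp + half)
            fh.write(f"{track.chrom}\t{start}\t{start + track.step_bp}\t{v:.6g}\n")


def read_bedgraph(
    path, window_bp: int = 100, feature: str = "", kind: str = "profile"
) -> dict[str, BinnedTrack]:
    """bedGraph -> per-chromosome tracks.

    Interval widths define the bin step; gaps become masked bins.
    Overlapping intervals are rejected.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if end <= start:
            raise ValueError(f"{path}:{lineno}: end <= start")
        per_chrom.setdefault(chrom, []).append((start, end, value))

    out: dict[str, BinnedTrack] = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
            if s2 < e1:
                raise ValueError(f"{path}: overlapping bedGraph intervals on {chrom}")
        step = rows[0][1] - rows[0][0]
        first = rows[0][0]
        last = rows[-1][0]
        n = (last - first) // step + 1
        values = np.full(n, np.nan)
        for s, e, v in rows:
            if e - s != step or (s - first) % step != 0:
                raise ValueError(
                    f"{path}: interval [{s},{e}) on {chrom} is not on the "
                    f"{step}-bp grid"
                )
            values[(s - first) // step] = v
        origin = int(first - (window_bp - step) / 2)
        if kind == "occupancy":
            out[chrom] = OccupancyTrack(
                chrom=chrom, values=values, origin_bp=origin, step_bp=step,
                window_bp=window_bp,
            )
        else:
            out[chrom] = StructuralProfile(
                chrom=chrom, values=values, origin_bp=origin, step_bp=step,
                window_bp=window_bp, feature=feature,
            )
    return out


def write_anchors_tsv(anchors: dict[str, list], path, provenance: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(provenance) + "\n")
        fh.write("class\tchrom\tposition\tstrand\n")
        for cls, items in anchors.items():
            for chrom, bp, strand in items:
                fh.write(f"{cls}\t{chrom}\t{bp}\t{strand}\n")
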