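"""DNA structural scales: k-mer -> physicochemical value lookup tables.

Each scale is an experimentally derived model assigning a structural value
(e.g. a propeller-twist angle, a base-stacking energy, a B-to-Z transition
energy) to every dinucleotide or trinucleotide.  Scales fall into two sign
classes according to whether their smoothed genomic profile correlates
positively or negatively with nucleosome occupancy; the sign class decides
whether nucleosomes appear as peaks or as valleys of the profile.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

#: Canonical feature order.  Positively correlated scales first.
FEATURE_NAMES = (
    "propeller_twist",
    "dna_denaturation",
    "bending_stiffness",
    "bendability",
    "duplex_disrupt_energy",
    "stacking_energy",
    "z_dna",
    "duplex_free_energy",
    "a_philicity",
    "protein_dna_twist",
    "b_dna_twist",
    "protein_deformation",
)

POSITIVE_FEATURES = frozenset(
    {
        "propeller_twist",
        "dna_denaturation",
        "bending_stiffness",
        "bendability",
        "duplex_disrupt_energy",
    }
)

#: The six scales most informative for nucleosome positioning; default
#: channel set for the meta-predictor and the HMM.
TOP_FEATURES = (
    "dna_denaturation",
    "propeller_twist",
    "bending_stiffness",
    "z_dna",
    "stacking_energy",
    "duplex_free_energy",
)

ALPHABET = "ACGT"


@dataclass(frozen=True)
class StructuralScale:
    """One named k-mer -> value table with its occupancy sign class."""

    name: str
    k: int
    values: dict[str, float]
    sign_class: str  # "positive" | "negative"
    units: str = ""

    def __post_init__(self) -> None:
        expected = 4**self.k
        if self.sign_class not in ("positive", "negative"):
            raise ValueError(
                f"scale {self.name!r}: sign_class must be 'positive' or "
                f"'negative', got {self.sign_class!r}"
            )
        kmers = ["".join(p) for p in itertools.product(ALPHABET, repeat=self.k)]
        for kmer in kmers:
            if kmer not in self.values:
                raise ValueError(
                    f"scale {self.name!r} is missing an entry for k-mer {kmer!r}"
                )
        if len(self.values) != expected:
            extra = set(self.values) - set(kmers)
            raise ValueError(
                f"scale {self.name!r}: expected {expected} k-mers, got "
                f"{len(self.values)} (unexpected: {sorted(extra)})"
            )


def _infer_k(kmers, feature: str) -> int:
    lengths = {len(kmer) for kmer in kmers}
    if len(lengths) != 1:
        raise ValueError(
            f"scale {feature!r} mixes k-mer lengths {sorted(lengths)}"
        )
    (k,) = lengths
    if k not in (2, 3):
        raise ValueError(
            f"scale {feature!r} has k-mers of length {k}; expected "
            "dinucleotides or trinucleotides"
        )
    return k


def _bundled(fname: str):
    return resources.files("nucstruct.data").joinpath(fname)


def load_scales(
    path=None,
    meta_path=None,
    features=None,
) -> dict[str, StructuralScale]:
    """Load structural scales from a TSV table.

    Parameters
    ----------
    path : path-like, optional
        TSV with columns ``feature``, ``kmer``, ``value``.  Defaults to the
        bundled 12-scale table.
    meta_path : path-like, optional
        Companion TSV with columns ``feature``, ``k``, ``sign_class``,
        ``units``.  Defaults to the bundled metadata.
    features : iterable of str, optional
        Subset of feature names to return (default: all in the table).

    Returns
    -------
    dict mapping feature name to :class:`StructuralScale`, in canonical
    order where applicable.
    """
    with resources.as_file(_bundled("scales.tsv")) as default_path:
        table = pd.read_csv(path if path is not None else default_path, sep="\t")
    with resources.as_file(_bundled("scales_meta.tsv")) as default_meta:
        meta = pd.read_csv(
            meta_path if meta_path is not None else default_meta, sep="\t"
        ).set_index("feature")

    for col in ("feature", "kmer", "value"):
        if col not in table.columns:
            raise ValueError(f"scale table is missing required column {col!r}")

    available = list(dict.fromkeys(table["feature"]))
    if features is None:
        features = available
    else:
        features = list(features)
        unknown = [f for f in features if f not in available]
        if unknown:
            raise ValueError(
                f"unknown feature name(s) {unknown}; valid names are "
                f"{sorted(available)}"
            )

    scales: dict[str, StructuralScale] = {}
    for name in features:
        sub = table[table["feature"] == name]
        values = dict(zip(sub["kmer"].str.upper(), sub["value"].astype(float)))
        k = _infer_k(values.keys(), name)
        if name in meta.index:
            row = meta.loc[name]
            sign = str(row["sign_class"])
            units = str(row.get("units", ""))
            if int(row["k"]) != k:
                raise ValueError(
                    f"scale {name!r}: metadata declares k={int(row['k'])} but "
                    f"table has {len(values)} entries (k={k})"
                )
        else:
            raise ValueError(f"scale {name!r} has no metadata row (sign class unknown)")
        scales[name] = StructuralScale(
            name=name, k=k, values=values, sign_class=sign, units=units
        )
    return scales
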