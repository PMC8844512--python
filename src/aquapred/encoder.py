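"""The 188-dimensional global protein sequence descriptor (GPSD).

A sequence is mapped to 188 numbers: 20 amino-acid composition (AAC)
frequencies followed by, for each of 8 physicochemical properties, a
21-feature composition/transition/distribution (CTD) block.  Each property
partitions the 20 amino acids into three disjoint groups; the block is

* C (3): fraction of residues falling in each group;
* T (3): fraction of adjacent residue pairs crossing each unordered group
  pair, in the cyclic order (g1,g2), (g2,g3), (g3,g1);
* D (15): for each group, the relative sequence position (1-based index / L)
  of the first, 25%, 50%, 75% and last residue of that group.

Feature indexing contract (1-based): features 1-20 are AAC in alphabetical
one-letter-code order; 21-41 is the hydrophobicity block, whose groups are
ordered (hydrophobic, polar, neutral) so that feature 21 is the hydrophobic
composition and feature 26 — the third transition feature — is the
neutral<->hydrophobic pair.  These two indices are the ones that dominate
the aquaporin/non-aquaporin contrast, reflecting the transmembrane-helix
architecture of the positive class.

All 188 values lie in [0, 1]; the D quantile index is m = ceil(q * n_k)
(floored at 1), with m = n_k for "last", and an empty group yields five
zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CANONICAL_ALPHABET, ProteinRecord

__all__ = [
    "PropertyPartition",
    "EncoderSchema",
    "FeatureMatrix",
    "DEFAULT_PARTITIONS",
    "default_schema",
    "load_partitions",
    "aac",
    "ctd_composition",
    "ctd_transition",
    "ctd_distribution",
    "encode_188",
    "encode_matrix",
]

N_FEATURES = 188
DISTRIBUTION_QUANTILES = ("first", "q25", "q50", "q75", "last")


@dataclass(frozen=True)
class PropertyPartition:
    """One physicochemical property's 3-group partition of the 20 amino acids.

    ``groups`` is an ordered tuple of (label, residue-set) pairs; the order
    fixes the C, T and D feature ordering inside the property's 21-feature
    block.
    """

    name: str
    groups: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        if len(self.groups) != 3:
            raise ValueError(f"{self.name}: expected exactly 3 groups, got {len(self.groups)}")
        labels = [lab for lab, _ in self.groups]
        if len(set(labels)) != 3:
            raise ValueError(f"{self.name}: group labels must be distinct: {labels}")
        union: set[str] = set()
        total = 0
        for _, residues in self.groups:
            union |= residues
            total += len(residues)
        if total != 20 or union != set(CANONICAL_ALPHABET):
            raise ValueError(
                f"{self.name}: groups must disjointly cover the 20 canonical amino acids"
            )

    def group_index(self) -> dict[str, int]:
        """Residue letter -> group position (0, 1 or 2)."""
        idx: dict[str, int] = {}
        for k, (_, residues) in enumerate(self.groups):
            for aa in residues:
                idx[aa] = k
        return idx


def _p(name: str, g1: tuple[str, str], g2: tuple[str, str], g3: tuple[str, str]) -> PropertyPartition:
    return PropertyPartition(
        name,
        tuple((lab, frozenset(res)) for lab, res in (g1, g2, g3)),
    )


# The classical 3-group partitions used with the 188D descriptor (Dubchak-style
# CTD tables).  Group order within each property is the block's feature order;
# for hydrophobicity it is fixed by the index-21/26 contract documented above,
# the remaining properties follow their conventional tabulated order.
DEFAULT_PARTITIONS: tuple[PropertyPartition, ...] = (
    _p(
        "hydrophobicity",
        ("hydrophobic", "CLVIMFW"),
        ("polar", "RKEDQN"),
        ("neutral", "GASTPHY"),
    ),
    _p(
        "vdw_volume",
        ("small", "GASTPDC"),
        ("medium", "NVEQIL"),
        ("large", "MHKFRYW"),
    ),
    _p(
        "polarity",
        ("low", "LIFWCMVY"),
        ("medium", "PATGS"),
        ("high", "HQRKNED"),
    ),
    _p(
        "polarizability",
        ("low", "GASDT"),
        ("medium", "CPNVEQIL"),
        ("high", "KMHFRYW"),
    ),
    _p(
        "charge",
        ("positive", "KR"),
        ("neutral", "ANCQGHILMFPSTWYV"),
        ("negative", "DE"),
    ),
    _p(
        "surface_tension",
        ("low", "GQDNAHR"),
        ("medium", "KTSEC"),
        ("high", "ILMFPWYV"),
    ),
    _p(
        "secondary_structure",
        ("helix", "EALMQKRH"),
        ("strand", "VIYCWFT"),
        ("coil", "GNPSD"),
    ),
    _p(
        "solvent_accessibility",
        ("buried", "ALFCGIVW"),
        ("exposed", "RKQEND"),
        ("intermediate", "MSPTHY"),
    ),
)


def load_partitions(path: str | Path) -> tuple[PropertyPartition, ...]:
    """Load partition tables from a plain-text TSV.

    Format: one line per property, four tab-separated fields::

        property<TAB>label1:RESIDUES<TAB>label2:RESIDUES<TAB>label3:RESIDUES

    Lines starting with '#' are ignored.
    """
    partitions: list[PropertyPartition] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"malformed partition line (need 4 fields): {line!r}")
        name = fields[0]
        groups = []
        for fld in fields[1:]:
            label, _, residues = fld.partition(":")
            groups.append((label, residues))
        partitions.append(_p(name, *groups))
    if not partitions:
        raise ValueError(f"no partitions found in {path}")
    return tuple(partitions)


def _transition_pairs(partition: PropertyPartition) -> tuple[tuple[int, int, str], ...]:
    """The three unordered group pairs in cyclic order with display labels."""
    labs = [lab for lab, _ in partition.groups]
    return (
        (0, 1, f"{labs[0]}~{labs[1]}"),
        (1, 2, f"{labs[1]}~{labs[2]}"),
        (2, 0, f"{labs[2]}~{labs[0]}"),
    )


@dataclass(frozen=True)
class EncoderSchema:
    """The canonical ordering of the 188 features."""

    partitions: tuple[PropertyPartition, ...] = DEFAULT_PARTITIONS
    feature_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.partitions) != 8:
            raise ValueError(f"expected 8 property partitions, got {len(self.partitions)}")
        names: list[str] = [f"AAC.{aa}" for aa in CANONICAL_ALPHABET]
        for part in self.partitions:
            for lab, _ in part.groups:
                names.append(f"{part.name}.C.{lab}")
            for _, _, pair_lab in _transition_pairs(part):
                names.append(f"{part.name}.T.{pair_lab}")
            for lab, _ in part.groups:
                for q in DISTRIBUTION_QUANTILES:
                    names.append(f"{part.name}.D.{lab}.{q}")
        if len(names) != N_FEATURES or len(set(names)) != N_FEATURES:
            raise ValueError("schema must define 188 unique feature names")
        object.__setattr__(self, "feature_names", tuple(names))

    def feature_name(self, index: int) -> str:
        """Canonical name of a feature by its 1-based index."""
        if not 1 <= index <= N_FEATURES:
            raise IndexError(f"feature index must be in 1..{N_FEATURES}, got {index}")
        return self.feature_names[index - 1]

    def block_of(self, index: int) -> str:
        """Which block ('AAC' or a property name) a 1-based feature index lies in."""
        return self.feature_names[index - 1].split(".")[0]


_DEFAULT_SCHEMA = EncoderSchema()


def default_schema() -> EncoderSchema:
    return _DEFAULT_SCHEMA


def aac(seq: str) -> np.ndarray:
    """Amino-acid composition: 20 frequencies in alphabetical code order."""
    L = len(seq)
    if L < 2:
        raise ValueError("sequence length must be >= 2")
    counts = np.array([seq.count(a) for a in CANONICAL_ALPHABET], dtype=float)
    if counts.sum() != L:
        bad = sorted(set(seq) - set(CANONICAL_ALPHABET))
        raise ValueError(f"non-canonical residues in sequence: {bad}")
    return counts / L


def _group_codes(seq: str, partition: PropertyPartition) -> np.ndarray:
    idx = partition.group_index()
    try:
        return np.array([idx[a] for a in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc} in sequence") from exc


def ctd_composition(seq: str, partition: PropertyPartition) -> np.ndarray:
    """Fraction of residues in each of the partition's three groups."""
    codes = _group_codes(seq, partition)
    return np.bincount(codes, minlength=3).astype(float) / len(seq)


def ctd_transition(seq: str, partition: PropertyPartition) -> np.ndarray:
    """Cross-group adjacent-pair frequencies, direction-insensitive.

    Entry order is the cyclic pair order (g1,g2), (g2,g3), (g3,g1);
    denominator L-1.
    """
    codes = _group_codes(seq, partition)
    a, b = codes[:-1], codes[1:]
    out = np.zeros(3)
    for slot, (j, k, _) in enumerate(_transition_pairs(partition)):
        out[slot] = np.count_nonzero(((a == j) & (b == k)) | ((a == k) & (b == j)))
    return out / (len(seq) - 1)


def ctd_distribution(seq: str, partition: PropertyPartition) -> np.ndarray:
    """Relative positions of quantile occurrences per group (15 values).

    For group k with n_k member residues, the five descriptors are the
    1-based positions of the m-th occurrence divided by L, with m = 1
    (first), ceil(0.25 n_k), ceil(0.5 n_k), ceil(0.75 n_k) — each floored
    at 1 — and n_k (last).  An empty group contributes five zeros.
    """
    codes = _group_codes(seq, partition)
    L = len(seq)
    out = np.zeros(15)
    for k in range(3):
        positions = np.flatnonzero(codes == k) + 1  # 1-based
        n = len(positions)
        if n == 0:
            continue
        ms = [1, max(1, math.ceil(0.25 * n)), max(1, math.ceil(0.5 * n)),
              max(1, math.ceil(0.75 * n)), n]
        out[5 * k : 5 * k + 5] = positions[np.array(ms) - 1] / L
    return out


def encode_188(seq: str, schema: EncoderSchema | None = None) -> np.ndarray:
    """Encode one validated sequence as the 188-dimensional feature vector."""
    schema = schema or _DEFAULT_SCHEMA
    parts = [aac(seq)]
    for partition in schema.partitions:
        parts.append(ctd_composition(seq, partition))
        parts.append(ctd_transition(seq, partition))
        parts.append(ctd_distribution(seq, partition))
    vec = np.concatenate(parts)
    assert vec.shape == (N_FEATURES,)
    return vec


@dataclass
class FeatureMatrix:
    """n_samples x n_features numeric table with names, labels and ids."""

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = self.X.shape
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} names for {p} columns")
        if len(self.labels) != n or len(self.ids) != n:
            raise ValueError("labels/ids length must match number of rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names, index=pd.Index(self.ids, name="id"))
        df["label"] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        if "label" not in df.columns:
            raise ValueError("feature table must carry a 'label' column")
        labels = df["label"].to_numpy()
        X = df.drop(columns="label")
        return cls(
            X.to_numpy(dtype=float),
            list(X.columns),
            labels,
            [str(i) for i in df.index],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))


def encode_matrix(
    records: Sequence[ProteinRecord], schema: EncoderSchema | None = None
) -> FeatureMatrix:
    """Encode labelled records row-by-row, preserving input order."""
    schema = schema or _DEFAULT_SCHEMA
    records = list(records)
    if not records:
        raise ValueError("cannot encode an empty record list")
    if any(rec.label is None for rec in records):
        raise ValueError("all records must carry a 0/1 label; use label=None pathways for prediction")
    X = np.vstack([encode_188(rec.seq, schema) for rec in records])
    labels = np.array([rec.label for rec in records], dtype=int)
    return FeatureMatrix(X, list(schema.feature_names), labels, [rec.id for rec in records])


def encode_unlabelled(
    records: Sequence[ProteinRecord], schema: EncoderSchema | None = None
) -> FeatureMatrix:
    """Encode records for prediction; labels are set to -1 placeholders."""
    schema = schema or _DEFAULT_SCHEMA
    records = list(records)
    if not records:
        raise ValueError("cannot encode an empty record list")
    X = np.vstack([encode_188(rec.seq, schema) for rec in records])
    return FeatureMatrix(
        X, list(schema.feature_names), np.full(len(records), -1), [r.id for r in records]
    )


def feature_name(index: int, schema: EncoderSchema | None = None) -> str:
    """Canonical feature name for a 1-based index (stable across runs)."""
    return (schema or _DEFAULT_SCHEMA).feature_name(index)
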