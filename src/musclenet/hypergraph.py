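"""Bipartite muscle--bone hypergraph: parsing, validation, projections.

A muscle is a hyperedge joining every bone it attaches to.  The whole
system is stored as an N x M 0/1 incidence matrix (bones x muscles);
the hyperedge degree of a muscle is its column sum.  One-mode projections
count shared counterparts: the bone-centric matrix counts muscles shared
by a bone pair and the muscle-centric matrix counts bones shared by a
muscle pair; diagonals are zeroed by convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "Hypergraph", "Projection", "DegreeProfile", "ParseError",
    "ValidationError", "parse_incidence", "hyperedge_degree", "project",
    "degree_profile", "normalize_label",
]


class ParseError(ValueError):
    """Raised when incidence input cannot be interpreted."""


class ValidationError(ValueError):
    """Raised when parsed data violates hypergraph invariants."""


def normalize_label(label: str) -> str:
    """Collapse internal whitespace and lowercase, so spreadsheet exports
    and synthetic fixtures with cosmetic differences are interchangeable."""
    return " ".join(str(label).split()).lower()


@dataclass
class Hypergraph:
    """Bones (nodes) x muscles (hyperedges) incidence structure.

    Parameters
    ----------
    bone_labels : unique bone identifiers, length N.
    muscle_labels : unique muscle identifiers, length M.
    incidence : (N, M) array with entry (i, j) = 1 iff bone i is an
        attachment point of muscle j.
    """

    bone_labels: list[str]
    muscle_labels: list[str]
    incidence: np.ndarray
    validate: bool = True

    def __post_init__(self) -> None:
        self.bone_labels = [str(b) for b in self.bone_labels]
        self.muscle_labels = [str(m) for m in self.muscle_labels]
        self.incidence = np.asarray(self.incidence)
        if self.incidence.shape != (len(self.bone_labels), len(self.muscle_labels)):
            raise ValidationError(
                f"incidence shape {self.incidence.shape} does not match "
                f"{len(self.bone_labels)} bones x {len(self.muscle_labels)} muscles"
            )
        bad = ~np.isin(self.incidence, (0, 1))
        if bad.any():
            cells = list(zip(*np.nonzero(bad)))[:20]
            raise ValidationError(f"non-binary incidence entries at cells {cells}")
        self.incidence = self.incidence.astype(np.int8)
        if len(set(self.bone_labels)) != len(self.bone_labels):
            raise ValidationError("duplicate bone labels")
        if len(set(self.muscle_labels)) != len(self.muscle_labels):
            raise ValidationError("duplicate muscle labels")
        if self.validate:
            iso_m = [m for j, m in enumerate(self.muscle_labels)
                     if self.incidence[:, j].sum() == 0]
            iso_b = [b for i, b in enumerate(self.bone_labels)
                     if self.incidence[i, :].sum() == 0]
            if iso_m or iso_b:
                raise ValidationError(
                    f"isolated entities: muscles with no bones {iso_m}; "
                    f"bones with no muscles {iso_b}"
                )
        self._bone_index = {b: i for i, b in enumerate(self.bone_labels)}
        self._muscle_index = {m: j for j, m in enumerate(self.muscle_labels)}

    # -- basic queries -------------------------------------------------
    @property
    def n_bones(self) -> int:
        return len(self.bone_labels)

    @property
    def n_muscles(self) -> int:
        return len(self.muscle_labels)

    def bone_index(self, bone: str) -> int:
        try:
            return self._bone_index[bone]
        except KeyError:
            raise KeyError(f"unknown bone label: {bone!r}") from None

    def muscle_index(self, muscle: str) -> int:
        try:
            return self._muscle_index[muscle]
        except KeyError:
            raise KeyError(f"unknown muscle label: {muscle!r}") from None

    def members(self, muscle: str) -> list[str]:
        """Bones attached by *muscle*."""
        j = self.muscle_index(muscle)
        return [self.bone_labels[i] for i in np.nonzero(self.incidence[:, j])[0]]

    def member_indices(self, muscle: str) -> np.ndarray:
        return np.nonzero(self.incidence[:, self.muscle_index(muscle)])[0]

    def degrees(self) -> np.ndarray:
        """Hyperedge degree per muscle (column sums)."""
        return self.incidence.sum(axis=0).astype(int)

    def edges(self) -> pd.DataFrame:
        """Canonical (muscle, bone) edge list, sorted."""
        rows = [
            (m, self.bone_labels[i])
            for j, m in enumerate(self.muscle_labels)
            for i in np.nonzero(self.incidence[:, j])[0]
        ]
        return (pd.DataFrame(rows, columns=["muscle", "bone"])
                .sort_values(["muscle", "bone"], kind="stable")
                .reset_index(drop=True))

    def write_edges(self, path: str | Path) -> None:
        self.edges().to_csv(path, index=False)

    def replace_incidence(self, incidence: np.ndarray,
                          validate: bool = False) -> "Hypergraph":
        """Same labels, new incidence (used by null-model rewiring)."""
        return Hypergraph(list(self.bone_labels), list(self.muscle_labels),
                          incidence, validate=validate)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypergraph):
            return NotImplemented
        return (self.bone_labels == other.bone_labels
                and self.muscle_labels == other.muscle_labels
                and np.array_equal(self.incidence, other.incidence))


@dataclass
class Projection:
    """One-mode projection of the hypergraph.

    ``kind='muscle_centric'``: weights[p, q] = number of bones shared by
    muscles p and q.  ``kind='bone_centric'``: weights[i, j] = number of
    muscles attaching both bones i and j.  Diagonal is identically zero.
    """

    labels: list[str]
    weights: np.ndarray
    kind: Literal["bone_centric", "muscle_centric"]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValidationError("projection weights must be square")
        if not np.array_equal(self.weights, self.weights.T):
            raise ValidationError("projection weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValidationError("projection diagonal must be zero")
        if np.any(self.weights < 0):
            raise ValidationError("projection weights must be non-negative")


@dataclass
class DegreeProfile:
    """Per-muscle hyperedge degrees and their empirical distribution."""

    muscle_labels: list[str]
    degrees: np.ndarray
    histogram: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.degrees = np.asarray(self.degrees, dtype=int)
        if not self.histogram:
            vals, counts = np.unique(self.degrees, return_counts=True)
            total = counts.sum()
            self.histogram = {int(v): c / total for v, c in zip(vals, counts)}

    @property
    def modal_degree(self) -> int:
        return max(self.histogram, key=self.histogram.get)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"muscle": self.muscle_labels, "degree": self.degrees})


# ----------------------------------------------------------------------
def _read_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    if isinstance(source, (str, Path)):
        path = Path(source)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        return pd.read_csv(path, sep=sep)
    if isinstance(source, io.IOBase):
        return pd.read_csv(source)
    if isinstance(source, Iterable):  # bare (muscle, bone) pair iterable
        rows = list(source)
        if not rows:
            raise ParseError("empty edge list")
        return pd.DataFrame(rows, columns=["muscle", "bone"][: len(rows[0])])
    raise ParseError(f"unsupported incidence source type: {type(source)!r}")


def parse_incidence(source, side: str | None = None) -> Hypergraph:
    """Parse a muscle--bone incidence table into a :class:`Hypergraph`.

    Accepts either a two-column edge list with header ``muscle,bone`` (an
    optional ``side`` column restricts to one body half when *side* is
    given), or a labelled 0/1 matrix whose first column holds bone labels
    and whose remaining column names are muscle labels.  Duplicate
    (muscle, bone) rows collapse to a single attachment.  Labels are
    whitespace-collapsed and lowercased.
    """
    df = _read_table(source)
    if df.empty:
        raise ParseError("empty incidence source")

    cols = [str(c).strip().lower() for c in df.columns]
    df.columns = cols
    if "muscle" in cols and "bone" in cols:
        if side is not None and "side" in cols:
            df = df[df["side"].astype(str).str.strip().str.lower()
                    == str(side).strip().lower()]
            if df.empty:
                raise ParseError(f"no rows remain after filtering side={side!r}")
        edges = df[["muscle", "bone"]].map(normalize_label)
        n_dup = int(edges.duplicated().sum())
        edges = edges.drop_duplicates()
        bones = sorted(edges["bone"].unique())
        muscles = sorted(edges["muscle"].unique())
        b_idx = {b: i for i, b in enumerate(bones)}
        m_idx = {m: j for j, m in enumerate(muscles)}
        inc = np.zeros((len(bones), len(muscles)), dtype=np.int8)
        inc[edges["bone"].map(b_idx), edges["muscle"].map(m_idx)] = 1
        h = Hypergraph(bones, muscles, inc)
        h.parse_report = {"n_bones": h.n_bones, "n_muscles": h.n_muscles,
                          "n_duplicates": n_dup}
        return h

    # labelled 0/1 matrix: first column = bone labels, header = muscles
    bone_col = df.columns[0]
    bones = [normalize_label(b) for b in df[bone_col]]
    muscles = [normalize_label(m) for m in df.columns[1:]]
    mat = df.iloc[:, 1:].to_numpy()
    try:
        mat = mat.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"matrix entries must be numeric 0/1: {exc}") from None
    if not np.isin(mat, (0.0, 1.0)).all():
        bad = np.argwhere(~np.isin(mat, (0.0, 1.0)))[:20]
        cells = [(bones[i], muscles[j]) for i, j in bad]
        raise ValidationError(f"non-binary matrix entries at {cells}")
    h = Hypergraph(bones, muscles, mat.astype(np.int8))
    h.parse_report = {"n_bones": h.n_bones, "n_muscles": h.n_muscles,
                      "n_duplicates": 0}
    return h


def hyperedge_degree(h: Hypergraph, muscle: str) -> int:
    """Number of bones attached by *muscle* (its hyperedge degree k)."""
    return int(h.incidence[:, h.muscle_index(muscle)].sum())


def project(h: Hypergraph,
            kind: Literal["bone_centric", "muscle_centric"]) -> Projection:
    """One-mode projection with zeroed diagonal.

    bone_centric[i, j] counts muscles attaching both bones i and j
    (C C^T in the bones-x-muscles orientation of the incidence matrix);
    muscle_centric[p, q] counts bones shared by muscles p and q (C^T C).
    """
    C = h.incidence.astype(np.int64)
    if kind == "bone_centric":
        W = C @ C.T
        labels = list(h.bone_labels)
    elif kind == "muscle_centric":
        W = C.T @ C
        labels = list(h.muscle_labels)
    else:
        raise ValueError(f"unknown projection kind: {kind!r}")
    np.fill_diagonal(W, 0)
    return Projection(labels, W, kind)


def degree_profile(h: Hypergraph) -> DegreeProfile:
    """Hyperedge degree of every muscle plus the normalized histogram."""
    return DegreeProfile(list(h.muscle_labels), h.degrees())
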