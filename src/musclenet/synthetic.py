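"""Synthetic bodies with the statistical structure the analysis assumes.

The generator emulates the gross features of the real musculoskeletal
hypergraph without any anatomical realism: bones lie along a single
body axis with 3D jitter; hyperedge degrees have a point mass at 2
(most muscles span one joint) with a zeta-like heavy tail; each muscle
attaches to spatially proximal bones, which plants community structure;
contiguous categories along the axis stand in for the motor-homunculus
ordering; and boundary bones are flagged fixed.  Clinical-style tables
are drawn as linear functions of the impact deviation plus noise, so
parameter-recovery behaviour of the regression layer can be tested.

A single seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .hypergraph import Hypergraph
from .springs import PhysicalEmbedding

__all__ = ["BodySpec", "generate_body", "generate_clinical_tables",
           "fixture_library"]


@dataclass
class BodySpec:
    """Parameters of a synthetic body.

    n_bones, n_muscles : entity counts.
    modal_fraction : fraction of muscles with degree exactly 2.
    tail_exponent : zeta-like exponent for degrees >= 3 (p(k) ~ k^-s).
    max_degree : cap on sampled degrees.
    localization_scale : axis-distance scale of attachment affinity;
        bone spacing along the axis is 1 unit.
    jitter_sd : transverse 3D jitter of bone positions (length units).
    n_categories : contiguous body-axis categories (homunculus stand-in).
    fixed_fraction : fraction of bones (split between the two axis ends)
        flagged as fixed boundary nodes.
    seed : deterministic generator seed.
    """

    n_bones: int = 30
    n_muscles: int = 40
    modal_fraction: float = 0.6
    tail_exponent: float = 3.0
    max_degree: int = 10
    localization_scale: float = 2.0
    jitter_sd: float = 0.3
    n_categories: int = 8
    fixed_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_bones, self.n_muscles, self.n_categories) <= 0:
            raise ValueError("counts must be positive")
        if self.max_degree > self.n_bones:
            raise ValueError(
                f"max_degree {self.max_degree} exceeds bone count "
                f"{self.n_bones}: infeasible attachment")


def _sample_degree(rng: np.random.Generator, spec: BodySpec) -> int:
    if rng.random() < spec.modal_fraction:
        return 2
    ks = np.arange(3, spec.max_degree + 1)
    p = ks.astype(float) ** -spec.tail_exponent
    return int(rng.choice(ks, p=p / p.sum()))


def generate_body(spec: BodySpec
                  ) -> tuple[Hypergraph, PhysicalEmbedding, pd.DataFrame]:
    """Generate (hypergraph, embedding, category table) from *spec*.

    Bones sit at unit spacing along the x axis with Gaussian jitter;
    muscle j samples a degree, picks an anchor bone and attaches to
    spatially proximal bones with affinity exp(-axis distance / scale).
    Categories are contiguous axis intervals; boundary bones are fixed.
    """
    rng = np.random.default_rng(spec.seed)
    nb, nm = spec.n_bones, spec.n_muscles
    bone_labels = [f"b{i:03d}" for i in range(nb)]
    muscle_labels = [f"m{j:03d}" for j in range(nm)]

    axis = np.arange(nb, dtype=float)
    coords = np.column_stack([
        axis + rng.normal(0, spec.jitter_sd * 0.5, nb),
        rng.normal(0, spec.jitter_sd, nb),
        rng.normal(0, spec.jitter_sd, nb),
    ])

    n_fixed = max(2, int(round(spec.fixed_fraction * nb)))
    fixed_idx = set(range(n_fixed // 2)) | set(range(nb - (n_fixed + 1) // 2, nb))

    inc = np.zeros((nb, nm), dtype=np.int8)
    for j in range(nm):
        k = _sample_degree(rng, spec)
        anchor = int(rng.integers(nb))
        members = {anchor}
        while len(members) < k:
            remaining = np.array([i for i in range(nb) if i not in members])
            aff = np.exp(-np.abs(axis[remaining] - axis[anchor])
                         / spec.localization_scale)
            members.add(int(rng.choice(remaining, p=aff / aff.sum())))
        inc[sorted(members), j] = 1

    # every bone must attach at least one muscle: attach strays to the
    # muscle whose anchor region is nearest along the axis
    centroids = np.array([axis[inc[:, j].astype(bool)].mean()
                          for j in range(nm)])
    for i in np.nonzero(inc.sum(axis=1) == 0)[0]:
        inc[i, int(np.argmin(np.abs(centroids - axis[i])))] = 1

    h = Hypergraph(bone_labels, muscle_labels, inc)
    emb = PhysicalEmbedding(
        {b: coords[i] for i, b in enumerate(bone_labels)},
        {b: (i in fixed_idx) for i, b in enumerate(bone_labels)},
    )

    edges = np.linspace(0, nb - 1, spec.n_categories + 1)
    muscle_centroid = np.array([axis[inc[:, j].astype(bool)].mean()
                                for j in range(nm)])
    cat = np.clip(np.searchsorted(edges[1:-1], muscle_centroid,
                                  side="right") + 1, 1, spec.n_categories)
    categories = pd.DataFrame({"muscle": muscle_labels,
                               "category_id": cat.astype(int)})
    return h, emb, categories


def generate_clinical_tables(h: Hypergraph,
                             deviations: Mapping[str, float] | None,
                             effect_size: float = 2.0,
                             noise_sd: float = 0.5,
                             seed: int = 0,
                             n_groups: int = 14,
                             n_volume_groups: int = 7,
                             ) -> tuple[pd.DataFrame, pd.DataFrame,
                                        dict[str, list[str]]]:
    """Draw recovery and activation-volume tables from a planted linear
    model on the impact deviation.

    Muscles are partitioned into *n_groups* groups; each group's
    recovery time is ``effect_size * mean deviation + noise``, shifted
    to be non-negative, and the first *n_volume_groups* groups
    additionally get an activation volume on the same linear model
    (scaled to mm^3, strictly positive).  When *deviations* is None the
    standardized hyperedge degree serves as a proxy signal.

    Returns (recovery table, volume table, group -> member muscles).
    """
    rng = np.random.default_rng(seed)
    muscles = list(h.muscle_labels)
    if deviations is None:
        deg = h.degrees().astype(float)
        sd = deg.std() or 1.0
        deviations = {m: (d - deg.mean()) / sd for m, d in zip(muscles, deg)}
    order = sorted(muscles, key=lambda m: deviations.get(m, 0.0))
    chunks = np.array_split(np.array(order), n_groups)
    groups = {f"group{g:02d}": list(c) for g, c in enumerate(chunks) if len(c)}

    names, signal = [], []
    for name, members in groups.items():
        names.append(name)
        signal.append(np.mean([deviations[m] for m in members]))
    signal = np.asarray(signal)
    recovery_raw = (effect_size * signal
                    + rng.normal(0, noise_sd, len(signal)))
    recovery = pd.DataFrame({
        "group": names,
        "weeks_recovery": recovery_raw - min(0.0, recovery_raw.min()),
    })
    vnames = names[:n_volume_groups]
    vol_raw = (effect_size * signal[:n_volume_groups]
               + rng.normal(0, noise_sd, len(vnames)))
    volumes = pd.DataFrame({
        "group": vnames,
        "volume_mm3": 1000.0 * (vol_raw - vol_raw.min() + 1.0),
    })
    return recovery, volumes, groups


def fixture_library() -> dict[str, dict]:
    """Canonical toy systems used across the test suite.

    dumbbell : 2 bones (one fixed), one degree-2 muscle -> 1 spring of
        strength 1; closed-form relaxation.
    star : one central fixed bone with 4 symmetric leaves joined by a
        single degree-5 muscle.
    chain : 5 collinear bones, 3 muscles (degrees 2, 3, 2), ends fixed.
    planted_triads : 9 muscles in 3 disjoint shared-bone cliques.
    path_body : 10 bones in a line, 9 degree-2 muscles whose
        muscle-centric projection is a path graph.
    two_cliques : 8-node adjacency matrix, two 4-cliques + one bridge.
    """
    lib: dict[str, dict] = {}

    def emb(coords, fixed):
        return PhysicalEmbedding(
            {b: np.asarray(r, dtype=float) for b, r in coords.items()},
            fixed)

    lib["dumbbell"] = {
        "hypergraph": Hypergraph(["b1", "b2"], ["m1"], [[1], [1]]),
        "embedding": emb({"b1": (0, 0, 0), "b2": (1, 0, 0)},
                         {"b1": True, "b2": False}),
    }
    star_inc = np.ones((5, 1), dtype=int)
    lib["star"] = {
        "hypergraph": Hypergraph([f"b{i}" for i in range(5)], ["hub"],
                                 star_inc),
        "embedding": emb({"b0": (0, 0, 0), "b1": (1, 0, 0), "b2": (-1, 0, 0),
                          "b3": (0, 1, 0), "b4": (0, -1, 0)},
                         {"b0": True, "b1": False, "b2": False,
                          "b3": False, "b4": False}),
    }
    chain_inc = np.zeros((5, 3), dtype=int)
    chain_inc[[0, 1, 2], 0] = 1       # ma = {b1, b2, b3} (degree 3)
    chain_inc[[2, 3], 1] = 1          # mb = {b3, b4}
    chain_inc[[3, 4], 2] = 1          # mc = {b4, b5}
    lib["chain"] = {
        "hypergraph": Hypergraph([f"b{i+1}" for i in range(5)],
                                 ["ma", "mb", "mc"], chain_inc),
        "embedding": emb({f"b{i+1}": (float(i), 0, 0) for i in range(5)},
                         {"b1": True, "b2": False, "b3": False,
                          "b4": False, "b5": True}),
    }
    # 3 groups x 3 muscles on group-private bone triples
    bones, muscles = [], []
    inc = np.zeros((9, 9), dtype=int)
    for g in range(3):
        gb = [f"g{g}b{t}" for t in range(3)]
        bones.extend(gb)
        for t, (a, b) in enumerate([(0, 1), (1, 2), (0, 2)]):
            muscles.append(f"g{g}m{t}")
            inc[3 * g + a, 3 * g + t] = 1
            inc[3 * g + b, 3 * g + t] = 1
    lib["planted_triads"] = {
        "hypergraph": Hypergraph(bones, muscles, inc),
        "planted": np.repeat(np.arange(3), 3),
    }
    nb = 10
    inc = np.zeros((nb, nb - 1), dtype=int)
    for j in range(nb - 1):
        inc[j, j] = inc[j + 1, j] = 1
    lib["path_body"] = {
        "hypergraph": Hypergraph([f"b{i}" for i in range(nb)],
                                 [f"m{j}" for j in range(nb - 1)], inc),
        "embedding": emb({f"b{i}": (float(i), 0, 0) for i in range(nb)},
                         {f"b{i}": i in (0, nb - 1) for i in range(nb)}),
        "order": [f"m{j}" for j in range(nb - 1)],
    }
    A = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    A[i, j] = 1
    A[3, 4] = A[4, 3] = 1
    lib["two_cliques"] = {"adjacency": A,
                          "planted": np.repeat([0, 1], 4)}
    return lib
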