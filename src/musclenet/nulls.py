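"""Null hypergraph ensembles and impact-score deviations.

A muscle's raw impact score is dominated by its hyperedge degree.  To
isolate the contribution of local wiring, each muscle is referenced
against degree-matched muscles in an ensemble of rewired null
hypergraphs.  Four null variants are supported:

``triad_rewire``
    Muscles are first partitioned into small groups of roughly three
    topologically related muscles (penalized greedy modularity) and bone
    attachments are shuffled only within a group.  This perturbs the
    topology locally while preserving each muscle's degree exactly.
``category_rewire``
    Same shuffling, but within homunculus categories.
``free_rewire``
    Shuffling among all muscles (degree-preserving, global).
``random``
    Attachments placed uniformly at random, preserving only the total
    attachment count.

The *impact deviation* of a muscle is the z-score-like quantity
(impact - null mean) / null std, where the null statistics are pooled
per hyperedge degree across the ensemble; |z| > 1.96 marks a muscle
outside the normal-theory 95% band.  The *deviation ratio* of a
homunculus category is the fraction of its muscles with positive
deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .community import adjusted_matrix
from .hypergraph import Hypergraph, Projection, project

__all__ = [
    "TriadPartition", "NullEnsemble", "triad_partition",
    "rewire_within_groups", "random_hypergraph", "impact_deviation",
    "deviation_ratio",
]

Variant = Literal["triad_rewire", "category_rewire", "free_rewire", "random"]


@dataclass
class TriadPartition:
    """Assignment of muscles to small, roughly equal groups."""

    muscle_labels: list[str]
    groups: np.ndarray          # group id per muscle
    K: int

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=int)
        if len(self.groups) != len(self.muscle_labels):
            raise ValueError("group assignment length mismatch")

    def as_mapping(self) -> dict[str, int]:
        return {m: int(g) for m, g in zip(self.muscle_labels, self.groups)}

    def sizes(self) -> np.ndarray:
        return np.bincount(self.groups)


def triad_partition(B_muscle: Projection, gamma_local: float = 1.0,
                    K: int | None = None, penalty_weight: float = 1.0,
                    rng_seed: int = 0, max_sweeps: int = 100) -> TriadPartition:
    """Partition muscles into groups of roughly size 3.

    Greedy node moves maximize the modularity gain on the
    resolution-adjusted muscle-centric matrix, minus an equal-size
    penalty (sum over groups of (size - N/K)^2) that keeps groups small
    and balanced.  Because the size penalty makes single moves between
    balanced groups costly, converged sweeps alternate with pairwise
    exchange moves (size-neutral, so judged on affinity alone).  Group
    sizes are forced into [2, 5] post hoc.
    """
    N = len(B_muscle.labels)
    if K is None:
        K = max(1, round(N / 3))
    if K > N:
        raise ValueError(f"K={K} exceeds the number of muscles {N}")
    Bp = adjusted_matrix(B_muscle, gamma_local).adjusted
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(N)
    groups = np.empty(N, dtype=int)
    groups[order] = np.arange(N) % K
    target = N / K

    def H(n: int, c: int) -> float:
        mask = groups == c
        mask_n = mask.copy()
        mask_n[n] = False
        return float(Bp[n, mask_n].sum())

    def best_move(n: int, allowed_sizes: tuple[int, int] | None = None
                  ) -> tuple[int, float]:
        c0 = groups[n]
        sizes = np.bincount(groups, minlength=K)
        h0 = H(n, c0)
        best_c, best_gain = c0, 0.0
        for c in range(K):
            if c == c0:
                continue
            if allowed_sizes is not None and not (
                    allowed_sizes[0] <= sizes[c] + 1 <= allowed_sizes[1]):
                continue
            dpen = ((sizes[c] + 1 - target) ** 2 - (sizes[c] - target) ** 2
                    + (sizes[c0] - 1 - target) ** 2 - (sizes[c0] - target) ** 2)
            gain = H(n, c) - h0 - penalty_weight * dpen
            if gain > best_gain + 1e-12:
                best_c, best_gain = c, gain
        return best_c, best_gain

    def swap_sweep() -> bool:
        """Exchange node pairs between groups when total affinity rises."""
        swapped = False
        for n in rng.permutation(N):
            c1 = groups[n]
            aff_n = np.zeros(K)
            np.add.at(aff_n, groups, Bp[n])
            aff_n[c1] -= Bp[n, n]
            for m in np.nonzero(groups != c1)[0]:
                c2 = groups[m]
                aff_m = np.zeros(K)
                np.add.at(aff_m, groups, Bp[m])
                aff_m[c2] -= Bp[m, m]
                gain = ((aff_n[c2] - Bp[n, m]) + (aff_m[c1] - Bp[n, m])
                        - (aff_n[c1]) - (aff_m[c2]))
                if gain > 1e-12:
                    groups[n], groups[m] = c2, c1
                    swapped = True
                    break
            if swapped:
                break
        return swapped

    for _ in range(max_sweeps):
        moved = False
        for n in rng.permutation(N):
            c, gain = best_move(n)
            if c != groups[n]:
                groups[n] = c
                moved = True
        if not moved and not swap_sweep():
            break

    # post hoc size enforcement: every group in [2, 5]
    for _ in range(10 * N):
        sizes = np.bincount(groups, minlength=K)
        present = np.nonzero(sizes)[0]
        big = [c for c in present if sizes[c] > 5]
        small = [c for c in present if sizes[c] < 2]
        if not big and not small:
            break
        if big:
            c = big[0]
            members = np.nonzero(groups == c)[0]
            # evict the member least attached to its group
            n = min(members, key=lambda i: H(i, c))
        else:
            c = small[0]
            n = np.nonzero(groups == c)[0][0]
        sizes_now = np.bincount(groups, minlength=K)
        candidates = [cc for cc in range(K)
                      if cc != c and sizes_now[cc] + 1 <= 5
                      and (sizes_now[cc] >= 2 or sizes_now[cc] == 0 or big)]
        if not candidates:
            candidates = [cc for cc in range(K)
                          if cc != c and sizes_now[cc] + 1 <= 5]
        if not candidates:
            break
        groups[n] = max(candidates, key=lambda cc: H(n, cc))

    # relabel contiguously
    _, groups = np.unique(groups, return_inverse=True)
    return TriadPartition(list(B_muscle.labels), groups,
                          int(groups.max()) + 1)


def rewire_within_groups(h: Hypergraph, grouping: Mapping[str, int],
                         rng_seed: int = 0,
                         swaps_per_attachment: int = 10) -> Hypergraph:
    """Shuffle bone attachments among muscles of the same group.

    Repeated double endpoint swaps: two attachments (m1, b1), (m2, b2)
    of distinct same-group muscles exchange bones unless a duplicate
    attachment would result.  Per-muscle degrees (and hence the whole
    degree sequence and each bone's degree) are preserved exactly.
    Single-muscle groups are left untouched.
    """
    missing = [m for m in h.muscle_labels if m not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover muscles: {missing[:10]}")
    rng = np.random.default_rng(rng_seed)
    inc = h.incidence.copy()
    by_group: dict[int, list[int]] = {}
    for j, m in enumerate(h.muscle_labels):
        by_group.setdefault(grouping[m], []).append(j)

    for g, muscles in sorted(by_group.items()):
        if len(muscles) < 2:
            continue
        attachments = [(j, i) for j in muscles
                       for i in np.nonzero(inc[:, j])[0]]
        n_att = len(attachments)
        for _ in range(swaps_per_attachment * n_att):
            a, b = rng.integers(0, n_att, size=2)
            (m1, b1), (m2, b2) = attachments[a], attachments[b]
            if m1 == m2 or b1 == b2:
                continue
            if inc[b2, m1] or inc[b1, m2]:
                continue
            inc[b1, m1] = inc[b2, m2] = 0
            inc[b2, m1] = inc[b1, m2] = 1
            attachments[a] = (m1, b2)
            attachments[b] = (m2, b1)
    return h.replace_incidence(inc)


def random_hypergraph(h: Hypergraph, rng_seed: int = 0) -> Hypergraph:
    """Uniformly random attachments, preserving only N, M and the total
    attachment count (not individual muscle degrees)."""
    rng = np.random.default_rng(rng_seed)
    n, m = h.incidence.shape
    total = int(h.incidence.sum())
    cells = rng.choice(n * m, size=total, replace=False)
    inc = np.zeros(n * m, dtype=np.int8)
    inc[cells] = 1
    return h.replace_incidence(inc.reshape(n, m))


@dataclass
class NullEnsemble:
    """A seeded collection of null hypergraphs plus their impact tables."""

    variant: Variant
    replicates: list[Hypergraph]
    seeds: list[int]
    impact_tables: list[pd.DataFrame] = field(default_factory=list)
    grouping: dict[str, int] | None = None

    @classmethod
    def generate(cls, h: Hypergraph, variant: Variant, n_replicates: int = 100,
                 seed: int = 0, grouping: Mapping[str, int] | None = None,
                 gamma_local: float = 1.0) -> "NullEnsemble":
        """Draw *n_replicates* null hypergraphs of the given variant.

        ``triad_rewire`` derives its grouping from a penalized greedy
        triad partition of the muscle-centric projection unless one is
        supplied; ``category_rewire`` requires *grouping* (the
        homunculus categories); ``free_rewire`` uses a single group.
        """
        if variant == "triad_rewire" and grouping is None:
            B = project(h, "muscle_centric")
            grouping = triad_partition(B, gamma_local=gamma_local,
                                       rng_seed=seed).as_mapping()
        elif variant == "category_rewire":
            if grouping is None:
                raise ValueError("category_rewire requires a grouping")
        elif variant == "free_rewire":
            grouping = {m: 0 for m in h.muscle_labels}
        seeds = [int(np.random.SeedSequence([seed, r]).generate_state(1)[0]
                     % (2 ** 31)) for r in range(n_replicates)]
        reps = []
        for s in seeds:
            if variant == "random":
                reps.append(random_hypergraph(h, rng_seed=s))
            else:
                reps.append(rewire_within_groups(h, grouping, rng_seed=s))
        return cls(variant, reps, seeds,
                   grouping=dict(grouping) if grouping else None)

    def compute_impacts(self, emb, mode="steady_state_4d",
                        settings=None) -> "NullEnsemble":
        """Score every replicate with the same solver settings."""
        from .springs import impact_all
        self.impact_tables = [impact_all(rep, emb, mode, settings)
                              for rep in self.replicates]
        return self


def _pooled_null(ensemble: NullEnsemble) -> dict[int, np.ndarray]:
    pools: dict[int, list[float]] = {}
    for table in ensemble.impact_tables:
        for deg, imp in zip(table["degree"], table["impact"]):
            pools.setdefault(int(deg), []).append(float(imp))
    return {k: np.asarray(v) for k, v in pools.items()}


def impact_deviation(real: pd.DataFrame, ensemble: NullEnsemble,
                     reference: Literal["mean", "ci"] = "mean",
                     min_null_obs: int = 2) -> pd.DataFrame:
    """Per-muscle deviation of impact from its degree-matched null.

    Null statistics are pooled per exact hyperedge degree across the
    ensemble.  A degree with fewer than *min_null_obs* null observations
    is widened symmetrically to neighbouring degrees until enough
    observations exist (logged in the ``binning`` column).  The primary
    deviation is the plain z-score (impact - mean)/std; with
    ``reference='ci'`` it is the distance to the nearest bound of the
    normal-theory 95% interval divided by std (0 inside the interval),
    keeping the sign of (impact - mean).
    """
    if not ensemble.impact_tables:
        raise ValueError("ensemble has no impact tables; "
                         "call compute_impacts first")
    pools = _pooled_null(ensemble)
    all_degrees = sorted(pools)
    rows = []
    for _, r in real.iterrows():
        deg, imp = int(r["degree"]), float(r["impact"])
        width = 0
        obs = pools.get(deg, np.empty(0))
        while len(obs) < min_null_obs and width < max(all_degrees, default=0):
            width += 1
            obs = np.concatenate([pools.get(d, np.empty(0))
                                  for d in range(deg - width, deg + width + 1)])
        binning = f"degree {deg}" if width == 0 else \
            f"degrees {deg - width}..{deg + width} (pooled)"
        if len(obs) < min_null_obs or obs.std(ddof=1) == 0:
            warnings.warn(f"degree category {deg}: insufficient null "
                          f"observations; deviation set to NA")
            rows.append({"muscle": r["muscle"], "degree": deg, "impact": imp,
                         "null_mean": np.nan, "null_std": np.nan,
                         "deviation": np.nan, "significant": False,
                         "binning": binning})
            continue
        mean, std = obs.mean(), obs.std(ddof=1)
        lo, hi = mean - 1.96 * std, mean + 1.96 * std
        z = (imp - mean) / std
        if reference == "ci":
            dist = max(0.0, lo - imp, imp - hi)
            dev = np.sign(imp - mean) * dist / std
        else:
            dev = z
        rows.append({"muscle": r["muscle"], "degree": deg, "impact": imp,
                     "null_mean": mean, "null_std": std, "deviation": dev,
                     "significant": bool(abs(z) > 1.96), "binning": binning})
    out = pd.DataFrame(rows)
    out.attrs["variant"] = ensemble.variant
    out.attrs["reference"] = reference
    return out


def deviation_ratio(dev: pd.DataFrame,
                    categories: Mapping[str, int] | pd.DataFrame
                    ) -> pd.DataFrame:
    """Fraction of each category's muscles with positive deviation.

    *categories* maps muscle -> homunculus category id (or is a frame
    with ``muscle`` and ``category_id`` columns).  Muscles with NA
    deviation and empty categories are excluded with a warning.
    """
    if isinstance(categories, pd.DataFrame):
        categories = dict(zip(categories["muscle"], categories["category_id"]))
    uncat = [m for m in dev["muscle"] if m not in categories]
    if uncat:
        raise ValueError(f"muscles without category: {uncat[:10]}")
    dev = dev.copy()
    dev["category_id"] = [int(categories[m]) for m in dev["muscle"]]
    ok = dev[np.isfinite(dev["deviation"])]
    dropped = set(dev["category_id"]) - set(ok["category_id"])
    if dropped:
        warnings.warn(f"categories with no finite deviations excluded: "
                      f"{sorted(dropped)}")
    rows = []
    for cat, grp in ok.groupby("category_id"):
        rows.append({"category_id": int(cat),
                     "ratio": float((grp["deviation"] > 0).mean()),
                     "n_muscles": int(len(grp))})
    return pd.DataFrame(rows).sort_values("category_id").reset_index(drop=True)
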