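"""Physically embedded spring--mass model and perturbation impact scores.

Bones are unit point masses at their anatomical centre-of-mass
coordinates; a muscle of hyperedge degree k is realised as the complete
set of k(k-1)/2 damped springs among its member bones, each of strength
1/(k-1) (times an optional per-muscle strength multiplier), so that the
total restoring force a muscle exerts is normalized across degrees.
Spring strengths on a bone pair accumulate over all muscles containing
both bones.  Rest lengths equal the initial distances, so the
unperturbed system sits at equilibrium.

A muscle is perturbed by displacing all of its member bones by a
constant amount ``d`` into a fourth spatial dimension and clamping them
there; the response ripples through the spring network.  The *impact
score* of the perturbation is the total distance moved by all nodes —
summed over time for the dynamic mode (dt-weighted quadrature), or at
equilibrium for the steady-state mode.

The equation of motion for free node i is

    m_i r_i'' = sum_j S_ij * u_ij * (x_ij - |l_ij|) - beta * r_i'

with l_ij = r_i - r_j, u_ij = l_ij/|l_ij|, rest length x_ij, damping
beta = 1 and unit masses by default.  The sign is fixed so stretched
springs attract (restoring force).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .hypergraph import Hypergraph

__all__ = [
    "PhysicalEmbedding", "SpringSystem", "PerturbationState", "Trajectory",
    "ImpactSettings", "BuildError", "ConstraintError", "InstabilityError",
    "ConvergenceError", "build_spring_system", "perturb_muscle",
    "integrate_dynamics", "steady_state_solve", "impact_score", "impact_all",
    "most_impacted", "load_embedding",
]

Mode = Literal["dynamic_4d", "steady_state_4d", "orthogonal_3d_sum"]


class BuildError(ValueError):
    """Embedding does not cover the hypergraph."""


class ConstraintError(ValueError):
    """No fixed bone: the system would drift freely."""


class InstabilityError(RuntimeError):
    """Dynamic integration diverged; try a smaller dt."""


class ConvergenceError(RuntimeError):
    """Steady-state solver failed to reach the force tolerance."""


@dataclass
class PhysicalEmbedding:
    """3D coordinates, fixed flags and optional masses per bone.

    ``coordinates`` maps bone label -> length-3 position in body
    coordinate units.  At least one bone must be fixed, otherwise a
    perturbed system drifts without restoring reference.
    """

    coordinates: dict[str, np.ndarray]
    fixed: dict[str, bool]
    mass: dict[str, float] | None = None
    muscle_strength: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.coordinates = {b: np.asarray(r, dtype=float)
                            for b, r in self.coordinates.items()}
        for b, r in self.coordinates.items():
            if r.shape != (3,):
                raise BuildError(f"coordinate for bone {b!r} is not a 3-vector")
        if not any(self.fixed.get(b, False) for b in self.coordinates):
            raise ConstraintError("no fixed bone in embedding: unconstrained drift")

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   strengths: pd.DataFrame | None = None) -> "PhysicalEmbedding":
        """Build from a table with columns bone,x,y,z,fixed[,mass]."""
        df = df.copy()
        df.columns = [str(c).strip().lower() for c in df.columns]
        coords = {str(r.bone): np.array([r.x, r.y, r.z]) for r in df.itertuples()}
        fixed = {str(r.bone): bool(int(r.fixed)) for r in df.itertuples()}
        mass = None
        if "mass" in df.columns:
            mass = {str(r.bone): float(r.mass) for r in df.itertuples()}
        strength = None
        if strengths is not None:
            strengths = strengths.copy()
            strengths.columns = [str(c).strip().lower() for c in strengths.columns]
            strength = {str(r.muscle): float(r.strength)
                        for r in strengths.itertuples()}
        return cls(coords, fixed, mass, strength)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, r in self.coordinates.items():
            row = {"bone": b, "x": r[0], "y": r[1], "z": r[2],
                   "fixed": int(self.fixed.get(b, False))}
            if self.mass is not None:
                row["mass"] = self.mass.get(b, 1.0)
            rows.append(row)
        return pd.DataFrame(rows)


def load_embedding(path: str | Path,
                   strengths_path: str | Path | None = None) -> PhysicalEmbedding:
    """Read a ``bone,x,y,z,fixed[,mass]`` CSV (plus optional
    ``muscle,strength`` CSV)."""
    strengths = pd.read_csv(strengths_path) if strengths_path else None
    return PhysicalEmbedding.from_frame(pd.read_csv(path), strengths)


@dataclass
class SpringSystem:
    """Assembled spring network over the embedded bones.

    Positions live in 4D: the anatomical (x, y, z) plus the perturbation
    dimension w, initialized to 0.
    """

    bone_labels: list[str]
    positions0: np.ndarray          # (N, 4)
    fixed: np.ndarray               # (N,) bool
    mass: np.ndarray                # (N,)
    spring_i: np.ndarray            # (P,) int
    spring_j: np.ndarray            # (P,) int
    rest_length: np.ndarray         # (P,)
    strength: np.ndarray            # (P,)
    membership: dict[str, np.ndarray]
    beta: float = 1.0

    @property
    def n_nodes(self) -> int:
        return len(self.bone_labels)

    @property
    def n_springs(self) -> int:
        return len(self.spring_i)

    def forces(self, pos: np.ndarray) -> np.ndarray:
        """Net spring force on every node at configuration *pos* (N, 4)."""
        F = np.zeros_like(pos)
        if self.n_springs == 0:
            return F
        l = pos[self.spring_i] - pos[self.spring_j]
        dist = np.linalg.norm(l, axis=1)
        safe = np.where(dist > 0, dist, 1.0)
        coef = np.where(dist > 0,
                        self.strength * (self.rest_length - dist) / safe, 0.0)
        f = coef[:, None] * l
        n = self.n_nodes
        for k in range(pos.shape[1]):
            F[:, k] = (np.bincount(self.spring_i, weights=f[:, k], minlength=n)
                       - np.bincount(self.spring_j, weights=f[:, k], minlength=n))
        return F

    def energy_and_grad(self, pos: np.ndarray) -> tuple[float, np.ndarray]:
        """Elastic energy and its gradient (= minus the spring forces)."""
        if self.n_springs == 0:
            return 0.0, np.zeros_like(pos)
        l = pos[self.spring_i] - pos[self.spring_j]
        dist = np.linalg.norm(l, axis=1)
        energy = float(0.5 * np.sum(self.strength * (dist - self.rest_length) ** 2))
        return energy, -self.forces(pos)

    def stiffness(self, pos: np.ndarray, free: np.ndarray) -> np.ndarray:
        """Tangent stiffness (Hessian of the elastic energy) restricted
        to the free nodes, as a dense (4F, 4F) matrix."""
        free_nodes = np.nonzero(free)[0]
        F = len(free_nodes)
        dim = pos.shape[1]
        if self.n_springs == 0 or F == 0:
            return np.zeros((dim * F, dim * F))
        node_to_free = -np.ones(self.n_nodes, dtype=int)
        node_to_free[free_nodes] = np.arange(F)
        l = pos[self.spring_i] - pos[self.spring_j]
        dist = np.linalg.norm(l, axis=1)
        keep = dist > 0
        u = l[keep] / dist[keep, None]
        S = self.strength[keep]
        ratio = 1 - self.rest_length[keep] / dist[keep]
        outer = u[:, :, None] * u[:, None, :]
        eye = np.eye(dim)
        blocks = S[:, None, None] * (outer + ratio[:, None, None]
                                     * (eye - outer))
        ai = node_to_free[self.spring_i[keep]]
        aj = node_to_free[self.spring_j[keep]]
        H4 = np.zeros((F, F, dim, dim))
        fi, fj = ai >= 0, aj >= 0
        np.add.at(H4, (ai[fi], ai[fi]), blocks[fi])
        np.add.at(H4, (aj[fj], aj[fj]), blocks[fj])
        both = fi & fj
        np.add.at(H4, (ai[both], aj[both]), -blocks[both])
        np.add.at(H4, (aj[both], ai[both]), -blocks[both])
        return H4.transpose(0, 2, 1, 3).reshape(dim * F, dim * F)


def build_spring_system(h: Hypergraph, emb: PhysicalEmbedding,
                        beta: float = 1.0) -> SpringSystem:
    """Assemble the spring network for hypergraph *h* embedded by *emb*.

    Muscles of degree 1 contribute no springs (a lone attachment has
    nothing to pull against); their perturbation still moves the one
    clamped bone.
    """
    missing = [b for b in h.bone_labels if b not in emb.coordinates]
    if missing:
        raise BuildError(f"embedding lacks coordinates for bones: {missing}")
    n = h.n_bones
    pos0 = np.zeros((n, 4))
    for i, b in enumerate(h.bone_labels):
        pos0[i, :3] = emb.coordinates[b]
    fixed = np.array([bool(emb.fixed.get(b, False)) for b in h.bone_labels])
    if not fixed.any():
        raise ConstraintError("no fixed bone among hypergraph nodes")
    mass = np.ones(n)
    if emb.mass is not None:
        mass = np.array([float(emb.mass.get(b, 1.0)) for b in h.bone_labels])

    pair_strength: dict[tuple[int, int], float] = {}
    membership: dict[str, np.ndarray] = {}
    for m in h.muscle_labels:
        idx = h.member_indices(m)
        membership[m] = idx
        k = len(idx)
        if k < 2:
            continue
        mult = 1.0
        if emb.muscle_strength is not None:
            mult = float(emb.muscle_strength.get(m, 1.0))
        s = mult / (k - 1)
        for a in range(k):
            for b in range(a + 1, k):
                key = (int(idx[a]), int(idx[b]))
                pair_strength[key] = pair_strength.get(key, 0.0) + s

    if pair_strength:
        keys = sorted(pair_strength)
        si = np.array([k[0] for k in keys])
        sj = np.array([k[1] for k in keys])
        strength = np.array([pair_strength[k] for k in keys])
        rest = np.linalg.norm(pos0[si] - pos0[sj], axis=1)
    else:
        si = sj = np.zeros(0, dtype=int)
        strength = rest = np.zeros(0)
    return SpringSystem(list(h.bone_labels), pos0, fixed, mass,
                        si, sj, rest, strength, membership, beta=beta)


@dataclass
class PerturbationState:
    """A spring system with one muscle's bones displaced and clamped."""

    system: SpringSystem
    positions: np.ndarray           # (N, 4) perturbed configuration
    clamped: np.ndarray             # (N,) bool — held for the whole run
    muscle: str
    d: float
    axis: int = 3
    log: list[str] = field(default_factory=list)


def perturb_muscle(sys: SpringSystem, muscle: str, d: float,
                   axis: int = 3) -> PerturbationState:
    """Displace all member bones of *muscle* by *d* along *axis*
    (default: the fourth dimension) and clamp them there.

    Globally fixed bones stay clamped at their rest position unless they
    are members of the perturbed muscle, in which case the membership
    clamp wins (they are held at the displaced position; logged).
    """
    if muscle not in sys.membership:
        raise KeyError(f"unknown muscle label: {muscle!r}")
    if d < 0:
        raise ValueError("perturbation magnitude d must be >= 0")
    idx = sys.membership[muscle]
    pos = sys.positions0.copy()
    pos[idx, axis] += d
    clamped = sys.fixed.copy()
    clamped[idx] = True
    log = []
    overridden = [sys.bone_labels[i] for i in idx if sys.fixed[i]]
    if overridden:
        log.append(f"membership clamp overrides fixed flag for {overridden}")
    return PerturbationState(sys, pos, clamped, muscle, d, axis, log)


@dataclass
class Trajectory:
    """Dynamic relaxation record.

    ``free_displacement_integral`` is the dt-weighted time-quadrature of
    the summed displacement norms of non-clamped nodes;
    ``clamped_displacement_integral`` is the same for clamped nodes
    (constant per step).  ``positions`` is only kept when recording.
    """

    times: np.ndarray
    free_displacement_integral: float
    clamped_displacement_integral: float
    final_positions: np.ndarray
    termination: str
    positions: np.ndarray | None = None


def integrate_dynamics(state: PerturbationState, dt: float = 0.01,
                       speed_tol: float = 1e-6, t_max: float = 500.0,
                       dwell: int = 10, record: bool = False,
                       divergence_bound: float = 1e9) -> Trajectory:
    """Relax the perturbed system with semi-implicit Euler integration.

    Terminates when the fastest free node has speed below *speed_tol*
    for *dwell* consecutive steps, or at *t_max*, whichever comes first.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    sys_, pos = state.system, state.positions.copy()
    free = ~state.clamped
    vel = np.zeros_like(pos)
    ref = sys_.positions0
    clamped_step = float(np.linalg.norm(
        (pos - ref)[state.clamped], axis=1).sum())
    n_steps = int(np.ceil(t_max / dt))
    free_int = 0.0
    quiet = 0
    times = []
    history = [] if record else None
    termination = "t_max"
    mass = sys_.mass[:, None]
    for step in range(n_steps):
        F = sys_.forces(pos)
        acc = (F - sys_.beta * vel) / mass
        vel[free] += dt * acc[free]
        pos[free] += dt * vel[free]
        disp = np.linalg.norm((pos - ref)[free], axis=1).sum()
        free_int += dt * disp
        t = (step + 1) * dt
        times.append(t)
        if record:
            history.append(pos.copy())
        if not np.isfinite(pos).all() or np.abs(pos).max() > divergence_bound:
            raise InstabilityError(
                f"integration diverged at t={t:.3f}; reduce dt (dt={dt})")
        speed = np.linalg.norm(vel[free], axis=1).max() if free.any() else 0.0
        quiet = quiet + 1 if speed < speed_tol else 0
        if quiet >= dwell:
            termination = "converged"
            break
    times = np.asarray(times)
    clamped_int = clamped_step * dt * len(times)
    return Trajectory(times, free_int, clamped_int, pos, termination,
                      np.asarray(history) if record else None)


@dataclass
class EquilibriumDisplacements:
    """Steady-state result: final positions and per-node displacements."""

    final_positions: np.ndarray
    displacements: np.ndarray      # (N,) norms from rest
    residual: float
    n_iterations: int


def steady_state_solve(state: PerturbationState, force_tol: float = 1e-4,
                       max_iter: int = 300,
                       newton_iter: int = 40) -> EquilibriumDisplacements:
    """Solve the nonlinear force balance of the clamped system directly.

    Two phases: quasi-Newton energy minimization over the free-node
    coordinates (L-BFGS with analytic gradient, *max_iter* iterations)
    to get near the equilibrium, then Levenberg-damped Newton steps
    using the analytic tangent stiffness until the force residual
    converges.  Fails with :class:`ConvergenceError` if the residual
    force (max node force norm) still exceeds *force_tol*.

    The default tolerance reflects that unstressed spring chains act as
    mechanisms whose restoring forces are cubic in the displacement:
    both dynamic relaxation and statics resolve them only to finite
    precision.
    """
    sys_ = state.system
    free = ~state.clamped
    pos = state.positions.copy()
    n_free = int(free.sum())
    if n_free == 0:
        disp = np.linalg.norm(pos - sys_.positions0, axis=1)
        return EquilibriumDisplacements(pos, disp, 0.0, 0)

    def energy(x):
        p = pos.copy()
        p[free] = x.reshape(n_free, 4)
        e, g = sys_.energy_and_grad(p)
        return e, g[free].ravel()

    def force_vec(x):
        p = pos.copy()
        p[free] = x.reshape(n_free, 4)
        return sys_.forces(p)[free].ravel()

    x0 = pos[free].ravel()
    res = minimize(energy, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": 1e-10,
                            "ftol": 1e-16})
    n_iter = int(res.nit)
    x = res.x
    F = force_vec(x)
    lam = 1e-6
    eye = np.eye(4 * n_free)
    for _ in range(newton_iter):
        if np.linalg.norm(F.reshape(n_free, 4), axis=1).max() < force_tol / 100:
            break
        p = pos.copy()
        p[free] = x.reshape(n_free, 4)
        H = sys_.stiffness(p, free)
        scale = max(np.trace(H) / H.shape[0], np.finfo(float).tiny)
        improved = False
        for _damp in range(25):
            try:
                dx = np.linalg.solve(H + lam * scale * eye, F)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            Fn = force_vec(x + dx)
            if np.linalg.norm(Fn) < np.linalg.norm(F):
                x, F = x + dx, Fn
                lam = max(lam / 10, 1e-12)
                improved = True
                break
            lam *= 10
        n_iter += 1
        if not improved:
            break
    pos[free] = x.reshape(n_free, 4)
    residual = float(np.linalg.norm(F.reshape(n_free, 4), axis=1).max())
    if residual > force_tol:
        raise ConvergenceError(
            f"steady-state residual force {residual:.3e} exceeds "
            f"tolerance {force_tol:.1e} after {n_iter} iterations")
    disp = np.linalg.norm(pos - sys_.positions0, axis=1)
    return EquilibriumDisplacements(pos, disp, residual, n_iter)


@dataclass
class ImpactSettings:
    """Solver settings shared by every row of an impact table.

    d : perturbation magnitude in body-coordinate length units.
    include_clamped : count the held (displaced) bones in the impact sum.
    normalize : divide by the node count (mean instead of total).
    """

    d: float = 1.0
    dt: float = 0.01
    speed_tol: float = 1e-6
    t_max: float = 500.0
    dwell: int = 10
    force_tol: float = 1e-4
    include_clamped: bool = True
    normalize: bool = False
    beta: float = 1.0


def _impact_from_state(sys_: SpringSystem, state: PerturbationState,
                       mode: Mode, settings: ImpactSettings) -> float:
    if mode == "dynamic_4d" or mode == "dynamic":
        traj = integrate_dynamics(state, dt=settings.dt,
                                  speed_tol=settings.speed_tol,
                                  t_max=settings.t_max, dwell=settings.dwell)
        total = traj.free_displacement_integral
        if settings.include_clamped:
            total += traj.clamped_displacement_integral
    else:
        eq = steady_state_solve(state, force_tol=settings.force_tol)
        disp = eq.displacements
        if not settings.include_clamped:
            disp = disp[~state.clamped]
        total = float(disp.sum())
    if settings.normalize:
        total /= sys_.n_nodes
    return total


def impact_score(h: Hypergraph, emb: PhysicalEmbedding, muscle: str,
                 mode: Mode = "dynamic_4d",
                 settings: ImpactSettings | None = None,
                 system: SpringSystem | None = None) -> float:
    """Impact score of perturbing one muscle.

    dynamic_4d : dt-weighted time-integral of the summed node
        displacement norms (length x time units).
    steady_state_4d : summed equilibrium displacement norms (length).
    orthogonal_3d_sum : vector-sum magnitude of three single-axis
        steady-state runs along x, y and z.
    """
    settings = settings or ImpactSettings()
    sys_ = system or build_spring_system(h, emb, beta=settings.beta)
    if mode == "orthogonal_3d_sum":
        comps = []
        for axis in range(3):
            state = perturb_muscle(sys_, muscle, settings.d, axis=axis)
            comps.append(_impact_from_state(sys_, state, "steady_state_4d",
                                            settings))
        return float(np.linalg.norm(comps))
    state = perturb_muscle(sys_, muscle, settings.d)
    return _impact_from_state(sys_, state, mode, settings)


def impact_all(h: Hypergraph, emb: PhysicalEmbedding,
               mode: Mode = "dynamic_4d",
               settings: ImpactSettings | None = None) -> pd.DataFrame:
    """Impact score for every muscle; deterministic given the settings.

    Returns a table with columns muscle, degree, impact, mode.  Failures
    of individual muscles are collected into the ``attrs['failures']``
    report rather than aborting the whole sweep.
    """
    settings = settings or ImpactSettings()
    sys_ = build_spring_system(h, emb, beta=settings.beta)
    degrees = h.degrees()
    rows, failures = [], {}
    for j, m in enumerate(h.muscle_labels):
        try:
            imp = impact_score(h, emb, m, mode, settings, system=sys_)
            rows.append({"muscle": m, "degree": int(degrees[j]),
                         "impact": imp, "mode": mode})
        except (InstabilityError, ConvergenceError) as exc:
            failures[m] = str(exc)
    table = pd.DataFrame(rows, columns=["muscle", "degree", "impact", "mode"])
    table.attrs["settings"] = settings
    table.attrs["failures"] = failures
    return table


def most_impacted(h: Hypergraph, emb: PhysicalEmbedding,
                  source_muscles: Sequence[str],
                  exclude: Iterable[str] = (),
                  mode: Mode = "steady_state_4d",
                  settings: ImpactSettings | None = None) -> pd.DataFrame:
    """Rank non-source muscles by how much the perturbation of the
    source muscles moves them.

    For each source, the displacement of a target muscle is the mean
    displacement of its member bones (time-summed in the dynamic mode,
    equilibrium in the steady-state mode); these are averaged over
    sources and ranked descending.
    """
    if not source_muscles:
        raise ValueError("source set must be nonempty")
    settings = settings or ImpactSettings()
    sys_ = build_spring_system(h, emb, beta=settings.beta)
    skip = set(source_muscles) | set(exclude)
    targets = [m for m in h.muscle_labels if m not in skip]
    if not targets:
        raise ValueError("no target muscles remain after exclusion")
    per_node = np.zeros(h.n_bones)
    for src in source_muscles:
        state = perturb_muscle(sys_, src, settings.d)
        if mode.startswith("dynamic"):
            traj = integrate_dynamics(state, dt=settings.dt,
                                      speed_tol=settings.speed_tol,
                                      t_max=settings.t_max,
                                      dwell=settings.dwell, record=True)
            disp = np.zeros(h.n_bones)
            for frame in traj.positions:
                disp += settings.dt * np.linalg.norm(
                    frame - sys_.positions0, axis=1)
        else:
            eq = steady_state_solve(state, force_tol=settings.force_tol)
            disp = eq.displacements
        per_node += disp / len(source_muscles)
    rows = [{"muscle": m,
             "displacement": float(per_node[sys_.membership[m]].mean())}
            for m in targets]
    return (pd.DataFrame(rows)
            .sort_values("displacement", ascending=False, kind="stable")
            .reset_index(drop=True))
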