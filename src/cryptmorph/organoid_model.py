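"""Off-lattice cell-centre model of a growing organoid cross-section.

The simulated system is a 2D slice through an organoid embedded in
Matrigel: a closed ring of epithelial cells (the monolayer) sits in a
hexagonal lattice of non-cellular mesh nodes — Matrigel nodes outside the
ring, lumen nodes inside it. All nodes interact through linear springs
along the edges of a Delaunay triangulation (edges longer than a cut-off
are severed), and move with overdamped dynamics

    eta * dx/dt = F  ->  x <- x + (F / eta) * dt          (forward Euler).

Epithelial cells additionally feel a basement-membrane restoring force that
drives the local three-point curvature of the ring toward a target value
kappa0, and they proliferate:

* ``original`` variant (two types): every cell divides forever; each
  division yields one daughter identical to the parent and one that is soft
  with probability ``p_soft``, else hard (stiffness ratio 4.5).
* ``proposed`` variant (four types): stem cells (SC, soft) divide into
  {SC 89%, PC 9%, TA 2%}; transit-amplifying cells (TA, hard) divide into
  {TA 90%, EC 10%} before the day-5 switch and {TA 70%, EC 30%} after;
  Paneth (PC) and differentiated enteroid (EC) cells never divide.

Cell cycles are G1 ~ U(12, 14) h plus a fixed 10 h remainder (22-24 h
total). A dividing cell is replaced by two daughters 0.05 CD either side of
it along a random axis, joined by a spring whose rest length grows linearly
from 0.1 to 1 CD over the first hour. Cells that leave the monolayer —
losing epithelial contact altogether, or losing their Matrigel or lumen
contact for a sustained stretch — are removed by anoikis. Lengths are in
cell diameters (CD), time in hours; force units are arbitrary because only
F/eta enters the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .boundary_io import LabeledPointCloud

__all__ = [
    "SimulationConfig",
    "CellAgent",
    "SimulationState",
    "Snapshot",
    "build_initial_state",
    "compute_forces",
    "advance",
    "sample_daughter_type",
    "perform_division",
    "apply_anoikis",
    "run_simulation",
    "spring_potential_energy",
    "epithelial_cloud",
]

# cell-type codes (int8); negative codes mark non-cellular mesh nodes:
# -1 = Matrigel (outside the monolayer), -2 = lumen (inside it)
TYPE_NAMES = ("SC", "PC", "TA", "EC", "SOFT", "HARD")
SC, PC, TA, EC, SOFT, HARD = range(6)
GEL = -1
LUMEN = -2
PROLIFERATIVE = {"proposed": (SC, TA), "original": (SOFT, HARD)}
SOFT_TYPES = (SC, SOFT)  # stiffness multiplier 1; everything else is "hard"


@dataclass(frozen=True)
class SimulationConfig:
    """All model constants, preset to the study conditions.

    Only ``variant`` and ``seed`` normally need choosing. ``mesh_dims`` is
    (rows, cols) of the hexagonal gel lattice; it defaults per variant
    (36x40 proposed, 20x20 original) when left as None.
    """

    variant: str = "proposed"
    seed: int = 0
    spring_stiffness: float = 15.0  # k, force per CD of extension
    drag: float = 1.0  # eta, force*hours per CD
    stiffness_ratio_hard: float = 4.5  # multiplier for non-soft cells
    bm_stiffness: float = 10.0  # beta
    target_curvature: float = 0.2  # kappa0, 1/CD
    monolayer_length: int = 20  # initial epithelial ring, cells
    mesh_dims: tuple[int, int] | None = None
    g1_range: tuple[float, float] = (12.0, 14.0)  # hours
    sc_g1_range: tuple[float, float] | None = None  # SC-only override (sensitivity runs)
    stiffness_ratio_ta: float | None = None  # TA-only override (sensitivity runs)
    fixed_post_g1: float = 10.0  # hours; total cycle 22-24 h
    dt: float = 0.005  # hours
    total_time: float = 168.0  # hours
    cutoff_length: float = 1.5  # CD; neighbour-loss distance
    p_soft: float = 0.2  # original variant
    init_props: tuple[float, float, float] = (0.42, 0.49, 0.09)  # SC, TA, PC
    sc_division_probs: tuple[float, float, float] = (0.89, 0.09, 0.02)  # SC, PC, TA
    ta_probs_early: tuple[float, float] = (0.90, 0.10)  # TA, EC
    ta_probs_late: tuple[float, float] = (0.70, 0.30)
    ta_switch_time: float = 120.0  # hours (day 5), global simulated time
    reconnect_period: float = 0.1  # hours between Delaunay rebuilds
    lumen_clearance: float = 0.5  # CD; gel kept this far outside the ring
    detachment_time: float = 2.0  # h of sustained media loss before anoikis

    def __post_init__(self) -> None:
        if self.variant not in ("original", "proposed"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.dt <= 0 or self.total_time <= 0:
            raise ValueError("dt and total_time must be positive")
        for name, probs in (
            ("init_props", self.init_props),
            ("sc_division_probs", self.sc_division_probs),
            ("ta_probs_early", self.ta_probs_early),
            ("ta_probs_late", self.ta_probs_late),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {probs}")
        if not 0.0 <= self.p_soft <= 1.0:
            raise ValueError("p_soft must be a probability")
        if self.reconnect_period <= 0:
            raise ValueError("reconnect_period must be positive")

    @property
    def dims(self) -> tuple[int, int]:
        if self.mesh_dims is not None:
            return self.mesh_dims
        return (36, 40) if self.variant == "proposed" else (20, 20)


@dataclass(frozen=True)
class CellAgent:
    """Read-only view of one epithelial cell (for inspection and tests)."""

    id: int
    position: tuple[float, float]
    type: str
    stiffness_multiplier: float
    birth_time: float
    cycle_complete_time: float
    partner_id: int | None
    division_time: float | None


@dataclass
class SimulationState:
    """Array-of-structs simulation state; mutated in place by ``advance``.

    Node arrays cover media and epithelial nodes together; ``cell_type``
    is -1 for Matrigel nodes and -2 for lumen nodes. ``edges`` is the
    current (pruned) Delaunay connectivity;
    ``partner``/``division_time`` implement the growing newborn springs.
    """

    time: float
    positions: np.ndarray  # (N, 2)
    cell_type: np.ndarray  # (N,) int8, GEL for gel nodes
    fixed: np.ndarray  # (N,) bool, pinned lattice rim
    birth_time: np.ndarray  # (N,)
    cycle_complete_time: np.ndarray  # (N,), inf = never divides
    partner: np.ndarray  # (N,) intp, -1 = none
    division_time: np.ndarray  # (N,)
    rng: np.random.Generator
    edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.intp))
    bm_triples: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=np.intp)
    )
    steps: int = 0
    _mult_cache: np.ndarray | None = None  # per-node stiffness multipliers
    detached_since: np.ndarray | None = None  # (N,) anoikis persistence clock

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def epithelial(self) -> np.ndarray:
        return self.cell_type >= 0

    @property
    def n_epithelial(self) -> int:
        return int(self.epithelial.sum())

    def agents(self, stiffness_ratio_hard: float = 4.5) -> list[CellAgent]:
        """Epithelial cells as read-only :class:`CellAgent` records."""
        mult = _multipliers(self, stiffness_ratio_hard)
        out = []
        for i in np.flatnonzero(self.epithelial):
            out.append(
                CellAgent(
                    id=int(i),
                    position=tuple(self.positions[i]),
                    type=TYPE_NAMES[self.cell_type[i]],
                    stiffness_multiplier=float(mult[i]),
                    birth_time=float(self.birth_time[i]),
                    cycle_complete_time=float(self.cycle_complete_time[i]),
                    partner_id=int(self.partner[i]) if self.partner[i] >= 0 else None,
                    division_time=float(self.division_time[i])
                    if self.partner[i] >= 0
                    else None,
                )
            )
        return out


def _multipliers(
    state: SimulationState, ratio: float, ta_ratio: float | None = None
) -> np.ndarray:
    """Per-node stiffness multiplier: 1 for media and soft cells, else ratio.

    ``ta_ratio`` overrides the multiplier of TA cells alone (stiffness-
    sensitivity runs). Cached on the state; invalidated whenever the cell
    roster changes.
    """
    if state._mult_cache is not None and len(state._mult_cache) == state.n_nodes:
        return state._mult_cache
    mult = np.ones(state.n_nodes)
    hard = (state.cell_type >= 0) & (state.cell_type != SC) & (state.cell_type != SOFT)
    mult[hard] = ratio
    if ta_ratio is not None:
        mult[state.cell_type == TA] = ta_ratio
    state._mult_cache = mult
    return mult


def _hex_lattice(nrows: int, ncols: int) -> np.ndarray:
    i, j = np.mgrid[0:nrows, 0:ncols]
    x = j + 0.5 * (i % 2)
    y = i * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


def _sample_cycle(
    config: SimulationConfig,
    rng: np.random.Generator,
    size: int,
    cell_type: int | np.ndarray | None = None,
) -> np.ndarray:
    """Fresh total cycle lengths: G1 ~ U(range) plus the fixed remainder.

    Stem cells use ``sc_g1_range`` when configured (cycle-length
    sensitivity runs); everyone else uses the shared ``g1_range``.
    """
    g1 = rng.uniform(*config.g1_range, size=size)
    if config.sc_g1_range is not None and cell_type is not None:
        is_sc = np.asarray(cell_type) == SC
        if np.any(is_sc):
            g1 = np.where(
                is_sc, rng.uniform(*config.sc_g1_range, size=size), g1
            )
    return g1 + config.fixed_post_g1


def build_initial_state(config: SimulationConfig) -> SimulationState:
    """Assemble the gel lattice, lumen cavity and epithelial ring at t = 0.

    Mesh nodes form a unit-spacing hexagonal lattice of ``config.dims``;
    the lattice rim is pinned (the rendered simulation boundary). A closed
    ring of ``monolayer_length`` cells, one cell diameter apart along its
    circumference, is centred in the mesh. Lattice nodes within a clearance
    annulus of the ring are deleted to make room for it; nodes inside the
    annulus become lumen nodes, nodes outside stay Matrigel. Both media are
    mobile spring nodes (stiffness multiplier 1) that differ only in which
    side of the monolayer they support. Cell types are i.i.d. from the
    variant's initial proportions, and each cell starts at a uniformly
    random phase of its first cycle so divisions desynchronise immediately.
    """
    nrows, ncols = config.dims
    gel = _hex_lattice(nrows, ncols)
    centre = gel.mean(axis=0)
    radius = config.monolayer_length / (2.0 * np.pi)
    half_extent = min(
        centre[0] - gel[:, 0].min(),
        gel[:, 0].max() - centre[0],
        centre[1] - gel[:, 1].min(),
        gel[:, 1].max() - centre[1],
    )
    if radius + 1.0 >= half_extent:
        raise ValueError(
            f"epithelial ring (radius {radius:.2f} CD) does not fit in "
            f"{nrows}x{ncols} mesh"
        )

    i, j = np.mgrid[0:nrows, 0:ncols]
    rim = (i == 0) | (i == nrows - 1) | (j == 0) | (j == ncols - 1)
    rim = rim.ravel()
    r_gel = np.linalg.norm(gel - centre, axis=1)
    keep = np.abs(r_gel - radius) > config.lumen_clearance
    lumen = r_gel < radius
    gel, rim, lumen = gel[keep], rim[keep], lumen[keep]

    rng = np.random.default_rng(config.seed)
    m = config.monolayer_length
    ang = 2.0 * np.pi * np.arange(m) / m
    ring = centre + radius * np.column_stack([np.cos(ang), np.sin(ang)])

    if config.variant == "proposed":
        types = rng.choice([SC, TA, PC], size=m, p=config.init_props).astype(np.int8)
    else:
        types = np.where(rng.random(m) < config.p_soft, SOFT, HARD).astype(np.int8)

    n_gel = len(gel)
    n = n_gel + m
    positions = np.vstack([gel, ring])
    cell_type = np.full(n, GEL, dtype=np.int8)
    cell_type[:n_gel][lumen] = LUMEN
    cell_type[n_gel:] = types
    fixed = np.zeros(n, dtype=bool)
    fixed[:n_gel] = rim

    birth = np.zeros(n)
    cycle_end = np.full(n, np.inf)
    cycles = _sample_cycle(config, rng, m, cell_type=types)
    age0 = rng.uniform(0.0, cycles)  # random initial cell-cycle phase
    proliferative = np.isin(types, PROLIFERATIVE[config.variant])
    birth[n_gel:] = -age0
    cycle_end[n_gel:] = np.where(proliferative, cycles - age0, np.inf)

    state = SimulationState(
        time=0.0,
        positions=positions,
        cell_type=cell_type,
        fixed=fixed,
        birth_time=birth,
        cycle_complete_time=cycle_end,
        partner=np.full(n, -1, dtype=np.intp),
        division_time=np.full(n, np.nan),
        rng=rng,
        detached_since=np.full(n, np.nan),
    )
    _rebuild_connectivity(state, config)
    return state


def _rebuild_connectivity(state: SimulationState, config: SimulationConfig) -> None:
    """Delaunay triangulation -> unique edges -> prune beyond cutoff.

    Also caches, per epithelial cell with exactly two epithelial
    neighbours, the (left, cell, right) triple used by the basement-
    membrane force.
    """
    for _pass in range(3):
        tri = Delaunay(state.positions)
        s = tri.simplices
        i = np.concatenate([s[:, 0], s[:, 1], s[:, 0]])
        j = np.concatenate([s[:, 1], s[:, 2], s[:, 2]])
        lo = np.minimum(i, j).astype(np.int64)
        hi = np.maximum(i, j).astype(np.int64)
        key = np.unique(lo * state.n_nodes + hi)  # dedup shared simplex edges
        e = np.column_stack([key // state.n_nodes, key % state.n_nodes])
        dvec = state.positions[e[:, 0]] - state.positions[e[:, 1]]
        d2 = np.einsum("ij,ij->i", dvec, dvec)
        if _pass < 2 and (_decompress_media(state, e, d2) or _refill_lumen(state, e, d2)):
            continue  # re-triangulate with the updated medium nodes
        break
    state.edges = e[d2 <= config.cutoff_length**2].astype(np.intp)

    epi = state.epithelial
    ee = state.edges[epi[state.edges[:, 0]] & epi[state.edges[:, 1]]]
    n = state.n_nodes
    deg = np.bincount(ee.ravel(), minlength=n)
    two = deg == 2
    if not two.any():
        state.bm_triples = np.empty((0, 3), dtype=np.intp)
        return
    # adjacency for degree-2 nodes via a sorted flat edge list
    flat = np.concatenate([ee[:, 0], ee[:, 1]])
    nbr = np.concatenate([ee[:, 1], ee[:, 0]])
    order = np.argsort(flat, kind="stable")
    flat, nbr = flat[order], nbr[order]
    cells = np.flatnonzero(two)
    starts = np.searchsorted(flat, cells)
    nbr1 = nbr[starts]
    nbr2 = nbr[starts + 1]

    # orient triples by walking the epithelial chain: inside a folded bud
    # the membrane's outward side cannot be inferred from the organoid
    # centroid, but it is always the left/right of the ccw chain traversal
    nbr_of = {int(c): (int(a), int(b)) for c, a, b in zip(cells, nbr1, nbr2)}
    visited: set[int] = set()
    triples: list[tuple[int, int, int]] = []
    centroid = state.positions[epi].mean(axis=0)
    for c0 in nbr_of:
        if c0 in visited:
            continue
        path = [c0]
        visited.add(c0)
        prev, cur = c0, nbr_of[c0][0]
        closed = False
        while cur in nbr_of and cur not in visited:
            path.append(cur)
            visited.add(cur)
            a, b = nbr_of[cur]
            prev, cur = cur, (b if a == prev else a)
        if cur == c0 and len(path) >= 3:
            closed = True
        if closed:
            pts = state.positions[path]
            x, y = pts[:, 0], pts[:, 1]
            area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
            if area2 < 0:
                path.reverse()
            m = len(path)
            for i in range(m):
                triples.append((path[i - 1], path[i], path[(i + 1) % m]))
        else:
            # open chain (touches a junction): orient by the centroid side
            for cell in path:
                a, b = nbr_of[cell]
                pa, pb, pc = state.positions[a], state.positions[b], state.positions[cell]
                t = pb - pa
                right = np.array([t[1], -t[0]])  # outward side of a ccw chain
                if np.dot(right, pc - centroid) >= 0:
                    triples.append((a, cell, b))
                else:
                    triples.append((b, cell, a))
    state.bm_triples = np.array(triples, dtype=np.intp).reshape(-1, 3)


def _refill_lumen(state: SimulationState, edges: np.ndarray, d2: np.ndarray) -> bool:
    """Keep the lumen medium at ~unit node density as the cavity inflates.

    The lumen behaves as a fluid filling the cavity: it neither pushes nor
    pulls at rest spacing, so when the monolayer moves outward (growth, bud
    inflation) new lumen nodes are seeded at the midpoints of over-
    stretched lumen edges from the raw triangulation. Without the refill
    the fixed initial node set dilutes and the cavity — and every budding
    crypt — loses its inner support. Returns True when nodes were added.
    """
    ct = state.cell_type
    k0, k1 = ct[edges[:, 0]], ct[edges[:, 1]]
    lumenish = (k0 == LUMEN) & (k1 != GEL) | (k1 == LUMEN) & (k0 != GEL)
    stretch = lumenish & (d2 > 1.8**2) & (d2 < 3.5**2)
    if not stretch.any():
        return False
    mid = 0.5 * (
        state.positions[edges[stretch, 0]] + state.positions[edges[stretch, 1]]
    )
    m = len(mid)
    state.positions = np.vstack([state.positions, mid])
    state.cell_type = np.append(state.cell_type, np.full(m, LUMEN, dtype=np.int8))
    state.fixed = np.append(state.fixed, np.zeros(m, dtype=bool))
    state.birth_time = np.append(state.birth_time, np.full(m, state.time))
    state.cycle_complete_time = np.append(
        state.cycle_complete_time, np.full(m, np.inf)
    )
    state.partner = np.append(state.partner, np.full(m, -1, dtype=np.intp))
    state.division_time = np.append(state.division_time, np.full(m, np.nan))
    if state.detached_since is not None:
        state.detached_since = np.append(state.detached_since, np.full(m, np.nan))
    state._mult_cache = None
    return True


def _decompress_media(
    state: SimulationState, edges: np.ndarray, d2: np.ndarray, min_spacing: float = 0.55
) -> bool:
    """Delete medium nodes squeezed below ``min_spacing`` of any neighbour.

    Together with :func:`_refill_lumen` this makes the two non-cellular
    media behave as constant-density fluids: nodes appear where the medium
    is stretched and vanish where it is compressed. Deleting the squeezed
    node is what lets the epithelial ring actually lengthen — a freshly
    inserted daughter compresses the medium next to it, the medium yields,
    and the insertion completes instead of expelling a cell. The pinned rim
    is never deleted. Returns True when nodes were removed.
    """
    short = d2 < min_spacing**2
    if not short.any():
        return False
    medium = (state.cell_type < 0) & ~state.fixed
    i0, i1 = edges[short, 0], edges[short, 1]
    m0, m1 = medium[i0], medium[i1]
    # remove one node per crowded pair: the medium endpoint (the higher-
    # index one when both are medium, for determinism)
    doomed = np.zeros(state.n_nodes, dtype=bool)
    doomed[i0[m0 & ~m1]] = True
    doomed[i1[m1 & ~m0]] = True
    both = m0 & m1
    doomed[np.maximum(i0[both], i1[both])] = True
    if not doomed.any():
        return False
    _remove_nodes(state, doomed)
    return True


def _remove_nodes(state: SimulationState, doomed: np.ndarray) -> None:
    """Compact all node arrays, dropping ``doomed``; remaps partner links."""
    keep = ~doomed
    remap = np.cumsum(keep) - 1
    state.positions = state.positions[keep]
    state.cell_type = state.cell_type[keep]
    state.fixed = state.fixed[keep]
    state.birth_time = state.birth_time[keep]
    state.cycle_complete_time = state.cycle_complete_time[keep]
    part = state.partner[keep]
    lost = (part >= 0) & ~keep[np.clip(part, 0, len(keep) - 1)]
    part[lost] = -1
    part[part >= 0] = remap[part[part >= 0]]
    state.partner = part
    state.division_time = state.division_time[keep]
    if state.detached_since is not None:
        state.detached_since = state.detached_since[keep]
    state.edges = np.empty((0, 2), dtype=np.intp)
    state.bm_triples = np.empty((0, 3), dtype=np.intp)
    state._mult_cache = None


def _rest_lengths(state: SimulationState) -> np.ndarray:
    """Per-edge spring rest length: 1, except growing newborn pairs."""
    e = state.edges
    rest = np.ones(len(e))
    p0 = state.partner[e[:, 0]]
    pair = p0 == e[:, 1]
    if pair.any():
        age = state.time - state.division_time[e[:, 0][pair]]
        rest[pair] = np.clip(0.1 + 0.9 * age, 0.1, 1.0)
    return rest


def compute_forces(
    state: SimulationState, config: SimulationConfig
) -> np.ndarray:
    """Net force on every node: pairwise springs + basement membrane.

    Spring pairs at distance d with rest length s feel equal and opposite
    forces of magnitude k_eff * (d - s) along the pair axis (attractive
    when stretched), with k_eff = k * mean of the endpoint stiffness
    multipliers. Each epithelial cell with exactly two epithelial
    neighbours feels beta * (kappa0 - kappa_local) along its outward
    normal, where kappa_local is the signed curvature of the circumcircle
    through the cell and its neighbours (positive when locally convex
    toward the gel); the force vanishes when the ring already has the
    target curvature.
    """
    pos = state.positions
    n = state.n_nodes
    F = np.zeros((n, 2))
    e = state.edges
    if len(e):
        i0, i1 = e[:, 0], e[:, 1]
        dvec = pos[i1] - pos[i0]
        dist = np.linalg.norm(dvec, axis=1)
        ok = dist > 1e-12
        mult = _multipliers(state, config.stiffness_ratio_hard, config.stiffness_ratio_ta)
        k_eff = config.spring_stiffness * 0.5 * (mult[i0] + mult[i1])
        rest = _rest_lengths(state)
        mag = np.where(ok, k_eff * (dist - rest) / np.maximum(dist, 1e-12), 0.0)
        fx = mag * dvec[:, 0]
        fy = mag * dvec[:, 1]
        F[:, 0] += np.bincount(i0, weights=fx, minlength=n)
        F[:, 0] -= np.bincount(i1, weights=fx, minlength=n)
        F[:, 1] += np.bincount(i0, weights=fy, minlength=n)
        F[:, 1] -= np.bincount(i1, weights=fy, minlength=n)

    t = state.bm_triples
    if len(t):
        # triples are stored in ccw chain order (see _rebuild_connectivity):
        # left turns are convex toward the gel, the outward normal is the
        # right-hand perpendicular of the local tangent p2 - p0
        p0, p1, p2 = pos[t[:, 0]], pos[t[:, 1]], pos[t[:, 2]]
        u = p1 - p0
        v = p2 - p1
        w = p2 - p0
        cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        norms = (
            np.linalg.norm(u, axis=1)
            * np.linalg.norm(v, axis=1)
            * np.linalg.norm(w, axis=1)
        )
        kappa_local = np.where(
            norms > 1e-12, 2.0 * cross / np.maximum(norms, 1e-12), 0.0
        )
        tangent_len = np.linalg.norm(w, axis=1)
        out_hat = np.column_stack([w[:, 1], -w[:, 0]]) / np.maximum(
            tangent_len, 1e-12
        )[:, None]
        mag = np.where(
            tangent_len > 1e-9,
            config.bm_stiffness * (config.target_curvature - kappa_local),
            0.0,
        )
        F[t[:, 1]] += mag[:, None] * out_hat

    F[state.fixed] = 0.0
    return F


def sample_daughter_type(
    parent_type: int | str,
    time: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> int:
    """Type of the second daughter of a dividing cell (first keeps parent's).

    Raises on terminally differentiated parents (PC/EC): they never divide.
    """
    code = TYPE_NAMES.index(parent_type) if isinstance(parent_type, str) else parent_type
    if config.variant == "original":
        if code not in (SOFT, HARD):
            raise ValueError(f"original variant has no type {TYPE_NAMES[code]}")
        return SOFT if rng.random() < config.p_soft else HARD
    if code == SC:
        return int(rng.choice([SC, PC, TA], p=config.sc_division_probs))
    if code == TA:
        probs = (
            config.ta_probs_early
            if time < config.ta_switch_time
            else config.ta_probs_late
        )
        return int(rng.choice([TA, EC], p=probs))
    raise ValueError(f"{TYPE_NAMES[code]} cells do not divide")


def perform_division(
    state: SimulationState, cell_id: int, config: SimulationConfig
) -> None:
    """Replace one cell whose cycle has completed by two daughters.

    The parent slot becomes daughter 1 (same type) at -0.05 CD along a
    uniformly random axis; daughter 2 (type from
    :func:`sample_daughter_type`) is appended at +0.05 CD. The pair is
    registered so its connecting spring rest length grows 0.1 -> 1 over the
    first hour. Both daughters draw fresh cycles (infinite for PC/EC).
    """
    if not np.isfinite(state.cycle_complete_time[cell_id]):
        raise ValueError(f"cell {cell_id} ({TYPE_NAMES[state.cell_type[cell_id]]}) does not divide")
    rng = state.rng
    parent_pos = state.positions[cell_id].copy()
    parent_type = int(state.cell_type[cell_id])
    theta = rng.uniform(0.0, 2.0 * np.pi)
    axis = np.array([np.cos(theta), np.sin(theta)])
    d2_type = sample_daughter_type(parent_type, state.time, config, rng)

    # daughter 1 reuses the parent's slot
    state.positions[cell_id] = parent_pos - 0.05 * axis
    state.birth_time[cell_id] = state.time
    c1 = _sample_cycle(config, rng, 1, cell_type=parent_type)[0]
    prolif1 = parent_type in PROLIFERATIVE[config.variant]
    state.cycle_complete_time[cell_id] = state.time + c1 if prolif1 else np.inf

    # daughter 2 appended
    new_id = state.n_nodes
    state.positions = np.vstack([state.positions, parent_pos + 0.05 * axis])
    state.cell_type = np.append(state.cell_type, np.int8(d2_type))
    state.fixed = np.append(state.fixed, False)
    state.birth_time = np.append(state.birth_time, state.time)
    c2 = _sample_cycle(config, rng, 1, cell_type=d2_type)[0]
    prolif2 = d2_type in PROLIFERATIVE[config.variant]
    state.cycle_complete_time = np.append(
        state.cycle_complete_time, state.time + c2 if prolif2 else np.inf
    )
    state.partner = np.append(state.partner, cell_id)
    state.partner[cell_id] = new_id
    state.division_time = np.append(state.division_time, state.time)
    state.division_time[cell_id] = state.time
    if state.detached_since is not None:
        state.detached_since = np.append(state.detached_since, np.nan)
        state.detached_since[cell_id] = np.nan
    state._mult_cache = None

    # incremental connectivity: daughter 2 inherits the parent slot's
    # neighbourhood plus the pair spring; the next periodic Delaunay
    # rebuild replaces this local approximation
    e = state.edges
    touching = (e[:, 0] == cell_id) | (e[:, 1] == cell_id)
    nbrs = np.unique(e[touching])
    nbrs = nbrs[nbrs != cell_id]
    new_edges = np.column_stack(
        [np.full(len(nbrs) + 1, new_id), np.append(nbrs, cell_id)]
    ).astype(np.intp)
    state.edges = np.vstack([e, new_edges])


def apply_anoikis(state: SimulationState, config: SimulationConfig | None = None) -> int:
    """Remove epithelial cells that have left the monolayer; return count.

    A monolayer cell touches epithelium along the ring, Matrigel on its
    outer side and lumen on its inner side. Losing the epithelial contact
    removes a cell immediately (it is fully detached). Losing a medium
    contact — no Matrigel edge means the cell was shed inward into the
    lumen, no lumen edge that it was expelled outward into the Matrigel —
    starts a detachment clock: only a cell that stays out of contact for
    ``config.detachment_time`` consecutive hours is removed. The
    persistence window distinguishes real expulsion from the transient
    shadowing every fresh division causes while the newborn pair is pulled
    into line; newborns additionally get a one-hour grace while their pair
    spring matures.

    Node arrays are compacted and partner links remapped; connectivity must
    be rebuilt by the caller (``advance`` does) after a removal.
    """
    epi = state.epithelial
    e = state.edges
    if not len(e):
        return 0
    epi0, epi1 = epi[e[:, 0]], epi[e[:, 1]]
    ee = e[epi0 & epi1]
    deg = np.bincount(ee.ravel(), minlength=state.n_nodes)
    gel0 = state.cell_type[e[:, 0]] == GEL
    gel1 = state.cell_type[e[:, 1]] == GEL
    eg = e[(epi0 & gel1) | (gel0 & epi1)]  # epithelial-Matrigel contacts
    gel_deg = np.bincount(eg.ravel(), minlength=state.n_nodes)
    lum0 = state.cell_type[e[:, 0]] == LUMEN
    lum1 = state.cell_type[e[:, 1]] == LUMEN
    el = e[(epi0 & lum1) | (lum0 & epi1)]  # epithelial-lumen contacts
    lum_deg = np.bincount(el.ravel(), minlength=state.n_nodes)
    mature = (state.time - state.birth_time) > 1.0
    failing = epi & ((gel_deg == 0) | (lum_deg == 0)) & mature
    if state.detached_since is None:
        state.detached_since = np.full(state.n_nodes, np.nan)
    clock = state.detached_since
    clock[epi & ~failing] = np.nan
    newly = failing & np.isnan(clock)
    clock[newly] = state.time
    t_detach = config.detachment_time if config is not None else 2.0
    expelled = failing & (state.time - clock >= t_detach)
    doomed = epi & ((deg == 0) | expelled)
    n_removed = int(doomed.sum())
    if n_removed == 0:
        return 0
    _remove_nodes(state, doomed)  # leaves connectivity stale; caller rebuilds
    return n_removed


def advance(state: SimulationState, config: SimulationConfig) -> SimulationState:
    """One timestep: move, reconnect, divide, cull.

    Order within the step: overdamped Euler update of all mobile nodes ->
    connectivity refresh (full Delaunay rebuild plus anoikis pass every
    ``config.reconnect_period`` hours; cheap over-cutoff edge pruning on
    the steps in between) -> divisions due this step, inserted with local
    connectivity. Raises on numerical blow-up (any displacement exceeding
    1 CD in a single step).
    """
    F = compute_forces(state, config)
    disp = (F / config.drag) * config.dt
    max_disp = float(np.abs(disp).max()) if len(disp) else 0.0
    if max_disp > 1.0:
        raise FloatingPointError(
            f"instability: displacement {max_disp:.3f} CD in one step at "
            f"t={state.time:.3f} h; reduce dt={config.dt}"
        )
    state.positions = state.positions + disp
    state.time += config.dt
    state.steps += 1

    interval = max(1, int(round(config.reconnect_period / config.dt)))
    if state.steps % interval == 0:
        _rebuild_connectivity(state, config)
        if apply_anoikis(state, config):
            _rebuild_connectivity(state, config)
    elif len(state.edges):
        dvec = state.positions[state.edges[:, 0]] - state.positions[state.edges[:, 1]]
        d2 = np.einsum("ij,ij->i", dvec, dvec)
        over = d2 > config.cutoff_length**2
        if over.any():
            state.edges = state.edges[~over]

    due = np.flatnonzero(state.cycle_complete_time <= state.time)
    for cid in due:
        perform_division(state, int(cid), config)
    return state


@dataclass(frozen=True)
class Snapshot:
    """Cell positions and types recorded at one requested time."""

    time: float
    cells: pd.DataFrame  # cell_id, x, y, type

    def cloud(self) -> LabeledPointCloud:
        return LabeledPointCloud(
            self.cells[["x", "y"]].to_numpy(float),
            self.cells["type"].to_numpy(object),
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.cells.copy()
        df.insert(0, "time", self.time)
        df.to_csv(path, index=False)


def _snapshot(state: SimulationState, t_label: float | None = None) -> Snapshot:
    idx = np.flatnonzero(state.epithelial)
    return Snapshot(
        time=state.time if t_label is None else t_label,
        cells=pd.DataFrame(
            {
                "cell_id": idx,
                "x": state.positions[idx, 0],
                "y": state.positions[idx, 1],
                "type": [TYPE_NAMES[c] for c in state.cell_type[idx]],
            }
        ),
    )


def run_simulation(
    config: SimulationConfig,
    snapshot_times: tuple[float, ...] = (72.0, 120.0, 168.0),
    progress: bool = False,
) -> list[Snapshot]:
    """Integrate from t = 0 to the last requested snapshot time.

    Snapshots record epithelial positions and types at (just past) each
    requested time; identical config and seed give identical output,
    byte-for-byte once serialised.
    """
    for t_req in snapshot_times:
        if t_req > config.total_time + 1e-9:
            raise ValueError(
                f"snapshot time {t_req} exceeds total_time {config.total_time}"
            )
    state = build_initial_state(config)
    remaining = sorted(snapshot_times)
    snaps: list[Snapshot] = []
    t_end = remaining[-1]
    n_steps = int(round(t_end / config.dt))
    for _ in range(n_steps):
        advance(state, config)
        while remaining and state.time >= remaining[0] - 1e-9:
            snaps.append(_snapshot(state, t_label=remaining[0]))
            remaining.pop(0)
        if progress and state.steps % 4000 == 0:
            print(
                f"  t={state.time:7.2f} h  cells={state.n_epithelial}",
                flush=True,
            )
    while remaining:
        snaps.append(_snapshot(state, t_label=remaining[0]))
        remaining.pop(0)
    return snaps


def config_from_file(path: str | Path, **overrides) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML/JSON mapping.

    Keys mirror the dataclass fields; unknown keys raise. Keyword
    ``overrides`` (e.g. a CLI seed) take precedence over file values.
    """
    import json

    import yaml

    path = Path(path)
    raw = (
        json.loads(path.read_text())
        if path.suffix.lower() == ".json"
        else yaml.safe_load(path.read_text())
    ) or {}
    valid = {f.name for f in SimulationConfig.__dataclass_fields__.values()}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    for key in ("mesh_dims", "g1_range", "sc_g1_range", "init_props",
                "sc_division_probs", "ta_probs_early", "ta_probs_late"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    raw.update(overrides)
    return SimulationConfig(**raw)


def render_snapshot(
    state_or_snapshot, path: str | Path, config: SimulationConfig | None = None
) -> None:
    """Write a quick overview PNG of a state (media + typed cells)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colours = {"SC": "tab:blue", "TA": "gold", "PC": "tab:green",
               "EC": "purple", "SOFT": "tab:blue", "HARD": "tab:green"}
    fig, ax = plt.subplots(figsize=(7, 7))
    if isinstance(state_or_snapshot, SimulationState):
        st = state_or_snapshot
        gel = st.positions[st.cell_type == GEL]
        lum = st.positions[st.cell_type == LUMEN]
        ax.scatter(gel[:, 0], gel[:, 1], s=4, c="pink", label="Matrigel")
        ax.scatter(lum[:, 0], lum[:, 1], s=4, c="navy", label="lumen")
        cells = _snapshot(st).cells
        title = f"t = {st.time:.1f} h"
    else:
        cells = state_or_snapshot.cells
        title = f"t = {state_or_snapshot.time:.1f} h"
    for name, grp in cells.groupby("type"):
        ax.scatter(grp["x"], grp["y"], s=22, c=colours.get(name, "gray"), label=name)
    ax.set_aspect("equal")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.savefig(path, dpi=110)
    plt.close(fig)


def spring_potential_energy(state: SimulationState, config: SimulationConfig) -> float:
    """Total 0.5 * k_eff * (d - rest)^2 over current edges (BM excluded)."""
    e = state.edges
    if not len(e):
        return 0.0
    d = np.linalg.norm(state.positions[e[:, 0]] - state.positions[e[:, 1]], axis=1)
    mult = _multipliers(state, config.stiffness_ratio_hard, config.stiffness_ratio_ta)
    k_eff = config.spring_stiffness * 0.5 * (mult[e[:, 0]] + mult[e[:, 1]])
    return float(np.sum(0.5 * k_eff * (d - _rest_lengths(state)) ** 2))


def epithelial_cloud(state: SimulationState) -> LabeledPointCloud:
    idx = np.flatnonzero(state.epithelial)
    return LabeledPointCloud(
        state.positions[idx],
        np.array([TYPE_NAMES[c] for c in state.cell_type[idx]], dtype=object),
    )
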