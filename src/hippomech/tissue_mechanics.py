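"""Viscoelastic cell-network mechanics of a 7-cell hexagonal patch.

The apical plane of a small patch of wing-disc epithelium — one central
cell and its six neighbors, all initially regular hexagons — is modeled as
a planar spring network.  Tricellular junctions are nodes; the actin belt
along each cell-cell interface is a belt edge; the apical actomyosin
network inside each cell is represented by transverse spokes that connect
the cell's corner nodes to a virtual node at the cell center.  Each edge
is a Kelvin-Voigt element (linear spring in parallel with a dashpot) in
parallel with a constant contractile active force — the KVA element.

Node dynamics follow the force balance

    M x'' = F_spring + F_dashpot + F_active + F_imposed,

with per-edge spring force K*(L - l) along the edge, per-edge dashpot
damping of the relative velocity projected on the edge, and an active
force F_A pulling the edge's endpoints together.  Externally imposed
forces act on the 18 exterior nodes, directed along the ray from the patch
centroid through the node (positive = stretching).  The overdamped mode
drops the inertial term and moves nodes down the net force against a drag
coefficient; since stationary states satisfy F = 0 with zero velocity they
are mode-independent.

Rest lengths are dynamic: swelling rescales one cell's rest lengths, and
the growth law multiplies rest lengths exponentially at a prescribed rate
(the mechanics-side half of the Yki-dependent growth feedback).

Units: positions um, forces pN, stiffness pN/um, damping pN*s/um, time s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

__all__ = [
    "MechParams",
    "MechNetwork",
    "network_state_frame",
    "cell_polygons",
    "build_hex_patch",
    "graph_laplacians",
    "edge_forces",
    "integrate",
    "relax",
    "apply_swelling",
    "grow_rest_lengths",
]


@dataclass(frozen=True)
class MechParams:
    """Default mechanical constants of the KVA network."""

    KN: float = 100.0      # pN/um, belt stiffness
    KT: float = 100.0      # pN/um, transverse stiffness
    damping: float = 100.0  # pN*s/um, dashpot coefficient (both edge types)
    #: constant contractile force per belt edge, pN.  The default places
    #: baseline junctional tensions in the low hundreds of pN, so that at
    #: physiological alpha-catenin levels (tens of molecules per node) the
    #: per-molecule load sits near the unfolding transitions.
    FA_belt: float = 100.0
    FA_trans: float = 0.0
    node_mass: float = 1.0   # pg; small enough to be effectively overdamped
    speed_tol: float = 1e-4  # um/s, stationarity criterion

    def __post_init__(self) -> None:
        for name in ("KN", "KT", "damping", "node_mass", "speed_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MechParams.{name} must be positive")
        if self.FA_belt < 0 or self.FA_trans < 0:
            raise ValueError("active forces must be non-negative")


@dataclass
class MechNetwork:
    """Planar KVA network: nodes, belt edges, and transverse spokes.

    ``cells`` lists each cell's corner nodes in order (polygon); the last
    ``n_cells`` nodes are the per-cell virtual center nodes carrying the
    transverse spokes.
    """

    x: np.ndarray                 # (N, 2) positions, um
    v: np.ndarray                 # (N, 2) velocities, um/s
    mass: np.ndarray              # (N,) pg
    belt_edges: np.ndarray        # (Eb, 2) int
    trans_edges: np.ndarray       # (Et, 2) int
    l_belt: np.ndarray            # (Eb,) rest lengths, um
    l_trans: np.ndarray           # (Et,)
    k_belt: np.ndarray            # (Eb,) pN/um
    k_trans: np.ndarray           # (Et,)
    c_belt: np.ndarray            # (Eb,) damping pN*s/um
    c_trans: np.ndarray
    fa_belt: np.ndarray           # (Eb,) active contractile force, pN
    fa_trans: np.ndarray
    cells: list                   # per cell: ordered corner node indices
    cell_centers: np.ndarray      # (n_cells,) center-node index
    cell_belt_edges: list         # per cell: belt edge indices
    cell_trans_edges: list        # per cell: transverse edge indices
    boundary_nodes: np.ndarray    # exterior (belt) nodes
    params: MechParams = field(default_factory=MechParams)

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.x[np.concatenate(
            [np.asarray(c) for c in self.cells])].mean(axis=0)

    def copy(self) -> "MechNetwork":
        return MechNetwork(
            self.x.copy(), self.v.copy(), self.mass.copy(),
            self.belt_edges.copy(), self.trans_edges.copy(),
            self.l_belt.copy(), self.l_trans.copy(),
            self.k_belt.copy(), self.k_trans.copy(),
            self.c_belt.copy(), self.c_trans.copy(),
            self.fa_belt.copy(), self.fa_trans.copy(),
            [list(c) for c in self.cells], self.cell_centers.copy(),
            [list(e) for e in self.cell_belt_edges],
            [list(e) for e in self.cell_trans_edges],
            self.boundary_nodes.copy(), self.params)

    def cell_area(self, cell_id: int) -> float:
        """Shoelace area of the cell polygon, um^2."""
        poly = self.x[self.cells[cell_id]]
        xs, ys = poly[:, 0], poly[:, 1]
        return 0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))

    def total_area(self) -> float:
        return float(sum(self.cell_area(i) for i in range(len(self.cells))))

    def side_length_cv(self, cell_id: int) -> float:
        """Coefficient of variation of the cell's side lengths."""
        poly = self.x[self.cells[cell_id]]
        sides = np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1)
        return float(sides.std() / sides.mean())

    def belt_tensions(self) -> np.ndarray:
        """Total tension per belt edge: spring force plus active force, pN."""
        d = self.x[self.belt_edges[:, 1]] - self.x[self.belt_edges[:, 0]]
        L = np.linalg.norm(d, axis=1)
        return self.k_belt * (L - self.l_belt) + self.fa_belt


def network_state_frame(network: "MechNetwork"):
    """Snapshot of node positions/velocities and edge rest lengths.

    Returns a tidy pandas frame (one row per node, then one per edge)
    suitable for CSV export of simulation snapshots.
    """
    import pandas as pd
    rows = []
    for i in range(network.n_nodes):
        rows.append({"kind": "node", "id": i,
                     "x": network.x[i, 0], "y": network.x[i, 1],
                     "vx": network.v[i, 0], "vy": network.v[i, 1],
                     "rest_length": np.nan})
    for name, edges, l in (("belt", network.belt_edges, network.l_belt),
                           ("transverse", network.trans_edges,
                            network.l_trans)):
        for e, (i, j) in enumerate(edges):
            rows.append({"kind": f"{name}_edge", "id": e,
                         "x": float(i), "y": float(j),
                         "vx": np.nan, "vy": np.nan,
                         "rest_length": float(l[e])})
    return pd.DataFrame(rows)


def cell_polygons(network: "MechNetwork") -> dict:
    """Per-cell polygon vertex lists (JSON-serializable), for plotting."""
    return {str(c): network.x[corners].tolist()
            for c, corners in enumerate(network.cells)}


def build_hex_patch(edge_length: float = 1.0,
                    params: MechParams | None = None) -> MechNetwork:
    """Seven regular hexagonal cells: a central cell and six neighbors.

    The belt graph has 24 nodes and 30 edges; every interior node has belt
    degree 3.  Transverse spokes connect each cell's six corners to a
    virtual center node.  All rest lengths are set to the current lengths,
    so the passive network starts prestress-free.
    """
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    a = float(edge_length)
    params = params or MechParams()

    centers = [np.zeros(2)]
    for k in range(6):
        ang = np.deg2rad(30 + 60 * k)
        centers.append(np.sqrt(3) * a * np.array([np.cos(ang), np.sin(ang)]))

    verts: list[np.ndarray] = []
    index: dict[tuple, int] = {}

    def vid(pt: np.ndarray) -> int:
        key = (round(pt[0] / a, 6), round(pt[1] / a, 6))
        if key not in index:
            index[key] = len(verts)
            verts.append(pt)
        return index[key]

    cells = []
    for c in centers:
        corners = [vid(c + a * np.array([np.cos(np.deg2rad(60 * k)),
                                         np.sin(np.deg2rad(60 * k))]))
                   for k in range(6)]
        cells.append(corners)

    n_corner = len(verts)
    belt_set: dict[tuple, None] = {}
    for corners in cells:
        for i in range(6):
            e = tuple(sorted((corners[i], corners[(i + 1) % 6])))
            belt_set[e] = None
    belt_edges = np.array(list(belt_set.keys()), dtype=int)

    # virtual center nodes and spokes
    center_ids = []
    trans = []
    for ci, c in enumerate(centers):
        cid = len(verts)
        verts.append(c.copy())
        center_ids.append(cid)
        for corner in cells[ci]:
            trans.append((corner, cid))
    trans_edges = np.array(trans, dtype=int)

    x = np.array(verts)
    n = len(verts)

    def lengths(edges):
        d = x[edges[:, 1]] - x[edges[:, 0]]
        return np.linalg.norm(d, axis=1)

    belt_lookup = {tuple(sorted(e)): i for i, e in enumerate(belt_edges)}
    cell_belt, cell_trans = [], []
    for ci, corners in enumerate(cells):
        cell_belt.append([belt_lookup[tuple(sorted((corners[i],
                                                    corners[(i + 1) % 6])))]
                          for i in range(6)])
        cell_trans.append(list(range(6 * ci, 6 * ci + 6)))

    membership = np.zeros(n_corner, dtype=int)
    for corners in cells:
        for c in corners:
            membership[c] += 1
    boundary = np.nonzero(membership < 3)[0]

    eb, et = len(belt_edges), len(trans_edges)
    return MechNetwork(
        x=x, v=np.zeros_like(x), mass=np.full(n, params.node_mass),
        belt_edges=belt_edges, trans_edges=trans_edges,
        l_belt=lengths(belt_edges), l_trans=lengths(trans_edges),
        k_belt=np.full(eb, params.KN), k_trans=np.full(et, params.KT),
        c_belt=np.full(eb, params.damping), c_trans=np.full(et, params.damping),
        fa_belt=np.full(eb, params.FA_belt), fa_trans=np.full(et, params.FA_trans),
        cells=cells, cell_centers=np.array(center_ids),
        cell_belt_edges=cell_belt, cell_trans_edges=cell_trans,
        boundary_nodes=boundary, params=params)


def graph_laplacians(network: MechNetwork, weighted: bool = False):
    """Graph Laplacians (Delta_N, Delta_T) of the belt and transverse graphs.

    Unweighted by default (off-diagonal -1 per edge); ``weighted=True``
    uses the edge stiffnesses as weights.  Both are symmetric with zero
    row sums.
    """
    n = network.n_nodes

    def lap(edges, w):
        L = np.zeros((n, n))
        for (i, j), wij in zip(edges, w):
            L[i, i] += wij
            L[j, j] += wij
            L[i, j] -= wij
            L[j, i] -= wij
        return L

    wb = network.k_belt if weighted else np.ones(len(network.belt_edges))
    wt = network.k_trans if weighted else np.ones(len(network.trans_edges))
    return lap(network.belt_edges, wb), lap(network.trans_edges, wt)


def imposed_force_vectors(network: MechNetwork, magnitude,
                          x: np.ndarray | None = None) -> np.ndarray:
    """Per-node imposed forces: radial through each boundary node.

    ``magnitude`` is a scalar (pN per boundary node, + stretch / -
    compress) or an array over boundary nodes.  Directions are rays from
    the current patch centroid through the node; tying the rays to the
    moving centroid keeps rigid translation force-neutral.
    """
    x = network.x if x is None else x
    F = np.zeros_like(x)
    if np.isscalar(magnitude):
        mags = np.full(len(network.boundary_nodes), float(magnitude))
    else:
        mags = np.asarray(magnitude, dtype=float)
    corner = np.unique(network.belt_edges)
    c = x[corner].mean(axis=0)
    for b, m in zip(network.boundary_nodes, mags):
        d = x[b] - c
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        F[b] += m * d / norm
    return F


def _pair_forces(x, v, edges, k, l, c, fa):
    """Per-node accumulated spring + dashpot + active forces for one edge set."""
    i, j = edges[:, 0], edges[:, 1]
    d = x[j] - x[i]
    L = np.linalg.norm(d, axis=1)
    if np.any(L < 1e-12):
        raise ValueError("zero-length edge")
    u = d / L[:, None]
    tension = k * (L - l) + fa                      # + pulls endpoints together
    rel_v = ((v[j] - v[i]) * u).sum(axis=1)
    f_along = tension + c * rel_v
    F = np.zeros_like(x)
    np.add.at(F, i, f_along[:, None] * u)
    np.add.at(F, j, -f_along[:, None] * u)
    return F


def edge_forces(network: MechNetwork, imposed=0.0,
                x: np.ndarray | None = None,
                v: np.ndarray | None = None) -> np.ndarray:
    """Net per-node force vectors (pN): springs, dashpots, active, imposed."""
    x = network.x if x is None else x
    v = network.v if v is None else v
    F = _pair_forces(x, v, network.belt_edges, network.k_belt,
                     network.l_belt, network.c_belt, network.fa_belt)
    F += _pair_forces(x, v, network.trans_edges, network.k_trans,
                      network.l_trans, network.c_trans, network.fa_trans)
    F += imposed_force_vectors(network, imposed, x)
    return F


def _energy_and_grad(flat_x, network, imposed):
    x = flat_x.reshape(-1, 2)
    E = 0.0
    for edges, k, l, fa in (
        (network.belt_edges, network.k_belt, network.l_belt, network.fa_belt),
        (network.trans_edges, network.k_trans, network.l_trans,
         network.fa_trans),
    ):
        d = x[edges[:, 1]] - x[edges[:, 0]]
        L = np.linalg.norm(d, axis=1)
        E += float((0.5 * k * (L - l) ** 2 + fa * L).sum())
    corner = np.unique(network.belt_edges)
    c = x[corner].mean(axis=0)
    if np.isscalar(imposed):
        mags = np.full(len(network.boundary_nodes), float(imposed))
    else:
        mags = np.asarray(imposed, dtype=float)
    r = np.linalg.norm(x[network.boundary_nodes] - c, axis=1)
    E -= float((mags * r).sum())
    v0 = np.zeros_like(x)
    G = -edge_forces(network, imposed, x, v0)
    return E, G.ravel()


def relax(network: MechNetwork, imposed=0.0,
          tol: float = 1e-9) -> MechNetwork:
    """Stationary state by energy minimization (quasi-static relaxation).

    The KVA element with constant active force admits the potential
    sum(K/2 (L-l)^2 + FA*L) minus the work of the radial imposed forces;
    its minima are exactly the zero-velocity stationary states of the
    dynamics.
    """
    res = minimize(_energy_and_grad, network.x.ravel(),
                   args=(network, imposed), jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": tol, "gtol": 1e-8})
    out = network.copy()
    out.x = res.x.reshape(-1, 2)
    out.v = np.zeros_like(out.x)
    return out


def integrate(network: MechNetwork, imposed=0.0, horizon: float = 100.0,
              mode: str = "overdamped", max_speed: float = 1e4):
    """Integrate the network dynamics and return (trajectory, final network).

    ``inertial`` integrates the full second-order system with edge
    dashpots; ``overdamped`` drops the mass term and moves nodes at
    velocity F/damping.  Integration stops early at stationarity (max node
    speed below ``params.speed_tol``); node speeds above ``max_speed``
    raise an instability error.
    """
    n = network.n_nodes
    gamma = float(np.mean(network.c_belt))

    if mode == "overdamped":
        def rhs(t, y):
            x = y.reshape(n, 2)
            F = edge_forces(network, imposed, x, np.zeros_like(x))
            return (F / gamma).ravel()

        def stationary(t, y):
            speed = np.linalg.norm(rhs(t, y).reshape(n, 2), axis=1).max()
            return speed - network.params.speed_tol
        y0 = network.x.ravel()
    elif mode == "inertial":
        def rhs(t, y):
            x = y[:2 * n].reshape(n, 2)
            v = y[2 * n:].reshape(n, 2)
            F = edge_forces(network, imposed, x, v)
            return np.concatenate([v.ravel(), (F / network.mass[:, None]).ravel()])

        def stationary(t, y):
            v = y[2 * n:].reshape(n, 2)
            return np.linalg.norm(v, axis=1).max() - network.params.speed_tol
        y0 = np.concatenate([network.x.ravel(), network.v.ravel()])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    stationary.terminal = True
    stationary.direction = -1

    def diverged(t, y):
        if mode == "inertial":
            v = y[2 * n:].reshape(n, 2)
        else:
            v = rhs(t, y).reshape(n, 2)
        return max_speed - np.linalg.norm(v, axis=1).max()
    diverged.terminal = True
    diverged.direction = -1

    # cap the step: after the transient decays, unboundedly growing steps
    # destabilize the lightly loaded oscillatory modes
    max_step = 0.5 * float(np.mean(network.c_belt) /
                           max(np.max(network.k_belt), 1.0))
    sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA",
                    events=[stationary, diverged], rtol=1e-8, atol=1e-10,
                    max_step=max_step, dense_output=True)
    if not sol.success:
        raise RuntimeError(f"mechanics integration failed: {sol.message}")
    if sol.t_events[1].size:
        raise RuntimeError(
            "mechanics integration diverged (node speed bound exceeded); "
            "reduce the step or forcing")
    out = network.copy()
    yf = sol.y[:, -1]
    out.x = yf[:2 * n].reshape(n, 2)
    out.v = (yf[2 * n:].reshape(n, 2) if mode == "inertial"
             else np.zeros_like(out.x))
    return sol, out


def apply_swelling(network: MechNetwork, cell_id: int,
                   area_scale: float) -> MechNetwork:
    """Scale the target cell's rest lengths by sqrt(area_scale).

    Models an osmotic volume change: positions are untouched (relaxation
    happens separately) and no volume conservation is imposed.
    """
    if area_scale <= 0:
        raise ValueError("area_scale must be positive")
    if not 0 <= cell_id < len(network.cells):
        raise KeyError(f"unknown cell {cell_id}")
    out = network.copy()
    s = np.sqrt(area_scale)
    out.l_belt[network.cell_belt_edges[cell_id]] *= s
    out.l_trans[network.cell_trans_edges[cell_id]] *= s
    return out


def grow_rest_lengths(network: MechNetwork, belt_rates=0.0, trans_rates=0.0,
                      dt: float = 1.0) -> MechNetwork:
    """Relative rest-length growth l <- l * exp(rate * dt), rates in 1/s."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = network.copy()
    out.l_belt = out.l_belt * np.exp(np.asarray(belt_rates, dtype=float) * dt)
    out.l_trans = out.l_trans * np.exp(np.asarray(trans_rates, dtype=float) * dt)
    return out
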