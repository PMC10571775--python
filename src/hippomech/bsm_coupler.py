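"""The coupled biochemical-signaling-and-mechanics (BSM) model.

This module closes the loop between the three component models:

    mechanics -> junctional tension -> per-molecule force on alpha-catenin
    -> conformational occupancies -> bound Jub -> Wts sequestration
    -> active Wts -> Yki -> rest-length growth -> mechanics.

Per coupling step the mechanics is relaxed quasi-statically (tissue
mechanics equilibrates in seconds), the catenin/Jub module is taken at
quasi-equilibrium (Jub binds in seconds), and the Hippo ODEs together with
the Jub-Wts sequestration pool advance on the minutes timescale.

Conventions used throughout:

* Junctional tension at a node is the mean of the positive (tensile)
  components of the belt-edge tensions incident on it; compressed edges
  contribute zero, because alpha-catenin transduces tension only.  A
  cell's tension is the mean over its six corner nodes.
* The per-molecule force is the node tension divided by the number of
  alpha-catenin molecules at the node (default 30, within the 26-46
  molecules/node range of junctional E-cadherin densities).
* Cellular Jub follows production/decay kinetics in nM; the node-level
  pool offered to catenin is ``conv_jub * [Jub]`` in molecules/node.
* Bound Jub sequesters cytosolic Wts by mass action
  (kJW_on * [Wts] * JubBound - kJW_off * [JubWts]); sequestered Wts is a
  separate pool excluded from Ex activation.
* Growth: every edge of a cell grows at g0 * max(0, Yki - Y0), saturating
  at rate_max; shared belt edges grow at the mean of the two owners'
  rates.  The growth readout R is the final/initial belt rest length
  averaged over the cell's edges.

In the tissue runs each cell's biochemistry uses one aggregate membrane
region closed by a mean-field identical-neighbor assumption for Fat-Ds
trans binding; intercellular interaction flows through the mechanics, as
in the experiments this module reproduces.  The model is deterministic:
identical configurations give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .catenin_gate import BellParams, bound_jub
from .hippo_network import (CellGeometry, HippoParams, HippoState, hippo_rhs)
from .tissue_mechanics import (MechNetwork, MechParams, build_hex_patch,
                               grow_rest_lengths, relax)

__all__ = [
    "GrowthParams",
    "BSMConfig",
    "node_tension",
    "cell_tension",
    "per_molecule_force",
    "jub_wts_coupling",
    "yki_growth_rate",
    "active_force_under_growth",
    "run_bsm",
    "run_bsm_steady",
    "replace_cells",
    "tension_catenin_heatmap",
    "center_perturbation",
    "differential_response_scan",
    "jub_production_scan",
]

N_CELLS = 7
CENTER = 0


@dataclass(frozen=True)
class GrowthParams:
    """Yki-dependent rest-length growth law FG = g0 * max(0, Yki - Y0).

    The active contractile force responds to growth: an edge growing at
    rate r exerts ``FA = fa0 * max(0, 1 - fa_inhibition * r / fa_rate_ref)``
    — the FA(dl/dt) dependence of the momentum balance.  Freshly assembled
    actomyosin engages fewer crossbridges, so fast-growing junctions are
    transiently less contractile; this is the route by which unbalanced
    growth feeds back on junctional tension.
    """

    g0: float = 2e-5            # 1/(nM*s)
    Y0: float = 4.0             # nM, Yki reference below which growth stops
    rate_max: float = 5e-4      # 1/s, growth-rate cap
    fa_rate_ref: float = 1e-4   # 1/s, growth rate halving... scale of FA loss
    fa_inhibition: float = 0.35  # dimensionless strength of FA(dl/dt)
    enabled: bool = True


def active_force_under_growth(fa0, rate, growth: "GrowthParams"):
    """Per-edge active force FA(dl/dt), pN; clipped at zero."""
    scale = 1.0 - growth.fa_inhibition * np.asarray(rate) / growth.fa_rate_ref
    return fa0 * np.clip(scale, 0.0, None)


@dataclass
class BSMConfig:
    """Full parameterization of the coupled 7-cell model."""

    hippo: HippoParams = field(default_factory=HippoParams)
    bell: BellParams = field(default_factory=BellParams)
    mech: MechParams = field(default_factory=lambda: MechParams(
        KN=1200.0, KT=1200.0, FA_belt=255.0))
    growth: GrowthParams = field(default_factory=GrowthParams)
    edge_length: float = 1.0                  # um
    catenin_per_cell: np.ndarray = field(
        default_factory=lambda: np.full(N_CELLS, 30.0))  # molecules/node
    vinculin: float = 0.0
    jub_production: np.ndarray = field(
        default_factory=lambda: np.full(N_CELLS, 250.0))  # nM/min
    jub_degradation: float = 0.5              # 1/min
    jub_affinity: tuple = (0.012, 0.008, 0.09)
    conv_jub: float = 0.16                    # (molecules/node) per nM
    kJW_on: float = 0.2                       # 1/(molecule*min)
    kJW_off: float = 0.5                      # 1/min
    boundary_force: float = 100.0             # pN/node, + stretch / - compress
    horizon: float = 30.0                     # min of coupled evolution
    coupling_dt: float = 30.0                 # s per coupling step
    tension_mode: str = "network"             # or "fixed"
    fixed_tension: float = 0.0                # pN/node when tension_mode=fixed

    def __post_init__(self) -> None:
        self.catenin_per_cell = np.asarray(self.catenin_per_cell, dtype=float)
        self.jub_production = np.asarray(self.jub_production, dtype=float)
        if np.any(self.catenin_per_cell <= 0):
            raise ValueError("alpha-catenin per node must be positive")
        if self.conv_jub <= 0:
            raise ValueError("conv_jub must be positive")
        if self.tension_mode not in ("network", "fixed"):
            raise ValueError(f"unknown tension_mode {self.tension_mode!r}")

    def geometry(self) -> CellGeometry:
        """Aggregate one-region-per-cell biochemical geometry, self-closed."""
        nc = np.arange(N_CELLS, dtype=int).reshape(-1, 1)
        nr = np.zeros((N_CELLS, 1), dtype=int)
        return CellGeometry(N_CELLS, 1, nc, nr)


# ---------------------------------------------------------------------------
# elementary couplings

def node_tension(network: MechNetwork, node: int) -> float:
    """Mean positive belt-edge tension at a node, pN; compression counts 0."""
    incident = np.nonzero((network.belt_edges == node).any(axis=1))[0]
    if incident.size == 0:
        raise ValueError(f"node {node} carries no belt edges")
    t = network.belt_tensions()[incident]
    return float(np.maximum(t, 0.0).mean())


def cell_tension(network: MechNetwork, cell_id: int) -> float:
    """Cell-level junctional tension: mean node tension over its corners."""
    return float(np.mean([node_tension(network, n)
                          for n in network.cells[cell_id]]))


def per_molecule_force(tension: float, n_catenin: float) -> float:
    """Force per alpha-catenin molecule: node tension / molecules per node."""
    if n_catenin < 1:
        raise ValueError("n_catenin must be >= 1")
    return float(tension) / float(n_catenin)


def jub_wts_coupling(bound: float, wts_c: float, jub_wts: float,
                     kJW_on: float, kJW_off: float) -> float:
    """Net Wts-sequestration rate (nM/min) by junctional Jub, mass action."""
    if bound < 0:
        raise ValueError("bound Jub must be non-negative")
    return kJW_on * wts_c * bound - kJW_off * jub_wts


def yki_growth_rate(yki: float, growth: GrowthParams) -> float:
    """Rest-length growth rate (1/s): g0*max(0, Yki-Y0), capped at rate_max."""
    if yki < 0:
        raise ValueError("Yki must be non-negative")
    return float(min(growth.g0 * max(0.0, yki - growth.Y0), growth.rate_max))


# ---------------------------------------------------------------------------
# coupled biochemical state: Hippo state + per-cell JubWts + per-cell [Jub]

def _bound_jub_per_cell(config: BSMConfig, tensions: np.ndarray,
                        jub_conc: np.ndarray) -> np.ndarray:
    out = np.empty(N_CELLS)
    for i in range(N_CELLS):
        f = per_molecule_force(tensions[i], config.catenin_per_cell[i])
        pool = config.conv_jub * jub_conc[i]
        out[i], _ = bound_jub(f, config.bell, V=config.vinculin,
                              jub_pool=pool, n_cat=config.catenin_per_cell[i],
                              affinity=config.jub_affinity)
    return out


def _chem_rhs(t, y, config: BSMConfig, geometry: CellGeometry,
              tensions: np.ndarray):
    """RHS of the per-cell biochemistry at frozen mechanics (units: minutes).

    State layout: [hippo state, JubWts (7), Jub (7)].
    """
    n_h = N_CELLS * 9 + N_CELLS * 1 * 10
    y = np.clip(y, 0.0, None)
    st = HippoState.unpack(y[:n_h], geometry)
    jw = y[n_h:n_h + N_CELLS]
    jub = y[n_h + N_CELLS:]

    bound = _bound_jub_per_cell(config, tensions, jub)
    sink = np.array([jub_wts_coupling(bound[i], st.cyt[i, 6], jw[i],
                                      config.kJW_on, config.kJW_off)
                     for i in range(N_CELLS)])
    dst = hippo_rhs(st, config.hippo, geometry, sink.reshape(-1, 1))
    # sequestered Wts turns over like every other Wts pool; without this
    # the sequestration flux would vanish at steady state
    djw = sink - config.hippo.deg_cyt * jw
    djub = config.jub_production - config.jub_degradation * jub
    return np.concatenate([dst.pack(), djw, djub])


def _chem_steady(config: BSMConfig, geometry: CellGeometry,
                 tensions: np.ndarray, y0: np.ndarray | None = None,
                 horizon: float = 1500.0) -> np.ndarray:
    if y0 is None:
        n_h = N_CELLS * 9 + N_CELLS * 10
        y0 = np.zeros(n_h + 2 * N_CELLS)
        y0[n_h + N_CELLS:] = config.jub_production / config.jub_degradation
    sol = solve_ivp(_chem_rhs, (0.0, horizon), y0,
                    args=(config, geometry, tensions),
                    method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"biochemical equilibration failed: {sol.message}")
    return np.clip(sol.y[:, -1], 0.0, None)


def _network_tensions(net: MechNetwork) -> np.ndarray:
    return np.array([cell_tension(net, i) for i in range(N_CELLS)])


def _growth_edge_rates(net: MechNetwork, rates: np.ndarray):
    """Per-edge rates from per-cell rates; shared belt edges take the mean."""
    belt = np.zeros(len(net.belt_edges))
    cnt = np.zeros(len(net.belt_edges))
    trans = np.zeros(len(net.trans_edges))
    for c in range(N_CELLS):
        for e in net.cell_belt_edges[c]:
            belt[e] += rates[c]
            cnt[e] += 1
        for e in net.cell_trans_edges[c]:
            trans[e] = rates[c]
    belt = np.where(cnt > 0, belt / np.maximum(cnt, 1), 0.0)
    return belt, trans


def run_bsm(config: BSMConfig, record_every: int = 1) -> pd.DataFrame:
    """Run the coupled model and return a tidy per-cell time series.

    Columns: time_min, cell, cell_class (center/boundary), yki, bound_jub,
    tension, rest_length_ratio.  The run starts from the coupled
    steady state at the initial mechanics (growth off), then advances
    ``horizon`` minutes in operator-split coupling steps; with growth
    disabled the state simply stays at that steady state.
    """
    geometry = config.geometry()
    net = build_hex_patch(config.edge_length, config.mech)
    l0_belt = net.l_belt.copy()
    fa0_belt = net.fa_belt.copy()
    fa0_trans = net.fa_trans.copy()

    if config.tension_mode == "fixed":
        tensions = np.full(N_CELLS, config.fixed_tension)
    else:
        net = relax(net, config.boundary_force)
        tensions = _network_tensions(net)

    y = _chem_steady(config, geometry, tensions)
    n_h = N_CELLS * 9 + N_CELLS * 10

    dt_min = config.coupling_dt / 60.0
    n_steps = int(round(config.horizon / dt_min))
    rows = []

    def record(t_min, y, tensions, net):
        st = HippoState.unpack(y[:n_h], geometry)
        jub = y[n_h + N_CELLS:]
        bound = _bound_jub_per_cell(config, tensions, jub)
        for c in range(N_CELLS):
            edges = net.cell_belt_edges[c]
            R = float(np.mean(net.l_belt[edges] / l0_belt[edges]))
            rows.append({
                "time_min": t_min, "cell": c,
                "cell_class": "center" if c == CENTER else "boundary",
                "yki": float(st.cyt[c, 7]), "bound_jub": float(bound[c]),
                "tension": float(tensions[c]), "rest_length_ratio": R,
            })

    record(0.0, y, tensions, net)
    for step in range(n_steps):
        if config.growth.enabled:
            st = HippoState.unpack(y[:n_h], geometry)
            rates = np.array([yki_growth_rate(st.cyt[c, 7], config.growth)
                              for c in range(N_CELLS)])
            br, tr = _growth_edge_rates(net, rates)
            net = grow_rest_lengths(net, br, tr, config.coupling_dt)
            net.fa_belt = active_force_under_growth(fa0_belt, br, config.growth)
            net.fa_trans = active_force_under_growth(fa0_trans, tr,
                                                     config.growth)
            if config.tension_mode == "network":
                net = relax(net, config.boundary_force)
                tensions = _network_tensions(net)
        sol = solve_ivp(_chem_rhs, (0.0, dt_min), y,
                        args=(config, geometry, tensions),
                        method="LSODA", rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise RuntimeError(
                f"BSM coupling step {step} failed in the biochemical stage: "
                f"{sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, None)
        if (step + 1) % record_every == 0 or step == n_steps - 1:
            record((step + 1) * dt_min, y, tensions, net)
    return pd.DataFrame(rows)


def _final_by_class(ts: pd.DataFrame) -> dict:
    last = ts[ts.time_min == ts.time_min.max()]
    center = last[last.cell_class == "center"].iloc[0]
    boundary = last[last.cell_class == "boundary"]
    return {
        "yki_center": float(center.yki),
        "yki_boundary": float(boundary.yki.mean()),
        "R_center": float(center.rest_length_ratio),
        "R_boundary": float(boundary.rest_length_ratio.mean()),
        "tension_center": float(center.tension),
        "tension_boundary": float(boundary.tension.mean()),
        "bound_jub_center": float(center.bound_jub),
        "bound_jub_boundary": float(boundary.bound_jub.mean()),
    }


# ---------------------------------------------------------------------------
# experiments

def tension_catenin_heatmap(config: BSMConfig, tension_grid,
                            catenin_grid) -> pd.DataFrame:
    """Steady-state Yki over (node tension, alpha-catenin) grids.

    Tension is applied uniformly across cells (no perturbation), so one
    representative cell is solved per grid point.  Non-converged points
    are flagged rather than aborting the scan.
    """
    tension_grid = np.asarray(tension_grid, dtype=float)
    catenin_grid = np.asarray(catenin_grid, dtype=float)
    if np.any(np.diff(tension_grid) <= 0) or np.any(np.diff(catenin_grid) <= 0):
        raise ValueError("grids must be sorted ascending")
    rows = []
    for ncat in catenin_grid:
        cfg = replace_cells(config, catenin=np.full(N_CELLS, ncat))
        cfg.tension_mode = "fixed"
        y = None
        for T in tension_grid:
            cfg.fixed_tension = float(T)
            try:
                ts = run_bsm_steady(cfg, y0=y)
                yki, bound, y = ts
                ok = True
            except RuntimeError:
                yki, bound, ok = np.nan, np.nan, False
            rows.append({"experiment": "heatmap", "tension": float(T),
                         "n_catenin": float(ncat), "yki": yki,
                         "bound_jub": bound, "converged": ok})
    return pd.DataFrame(rows)


def run_bsm_steady(config: BSMConfig, y0=None):
    """Coupled biochemical steady state at fixed tension (growth off).

    Returns (yki of cell 0, bound Jub of cell 0, raw state) — all cells
    are identical in this uniform mode.
    """
    geometry = config.geometry()
    tensions = np.full(N_CELLS, config.fixed_tension)
    y = _chem_steady(config, geometry, tensions, y0=y0)
    n_h = N_CELLS * 9 + N_CELLS * 10
    st = HippoState.unpack(y[:n_h], geometry)
    jub = y[n_h + N_CELLS:]
    bound = _bound_jub_per_cell(config, tensions, jub)
    return float(st.cyt[0, 7]), float(bound[0]), y


def replace_cells(config: BSMConfig, catenin=None, jub_production=None,
                  **kw) -> BSMConfig:
    """Copy the config with new per-cell arrays and/or scalar fields."""
    cfg = BSMConfig(
        hippo=config.hippo, bell=config.bell, mech=config.mech,
        growth=config.growth, edge_length=config.edge_length,
        catenin_per_cell=(config.catenin_per_cell.copy()
                          if catenin is None else catenin),
        vinculin=config.vinculin,
        jub_production=(config.jub_production.copy()
                        if jub_production is None else jub_production),
        jub_degradation=config.jub_degradation,
        jub_affinity=config.jub_affinity, conv_jub=config.conv_jub,
        kJW_on=config.kJW_on, kJW_off=config.kJW_off,
        boundary_force=config.boundary_force, horizon=config.horizon,
        coupling_dt=config.coupling_dt, tension_mode=config.tension_mode,
        fixed_tension=config.fixed_tension)
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


def center_perturbation(config: BSMConfig, center_catenin_range,
                        boundary_catenin: float = 30.0,
                        boundary_forces=(-100.0, 100.0)) -> pd.DataFrame:
    """Sweep the center cell's alpha-catenin; boundary cells stay fixed.

    Per sweep point and boundary force, the coupled model runs to its final
    time and center/boundary Yki (and growth readouts) are recorded.
    """
    rng = np.asarray(center_catenin_range, dtype=float)
    if np.any(rng < 5) or np.any(rng > 100):
        raise ValueError("center alpha-catenin range out of bounds")
    rows = []
    for force in boundary_forces:
        for nc in rng:
            cat = np.full(N_CELLS, float(boundary_catenin))
            cat[CENTER] = float(nc)
            cfg = replace_cells(config, catenin=cat, boundary_force=float(force))
            ts = run_bsm(cfg, record_every=max(1, len(ts_steps(cfg))))
            out = _final_by_class(ts)
            out.update({"experiment": "center_perturbation",
                        "center_catenin": float(nc),
                        "boundary_force": float(force)})
            rows.append(out)
    return pd.DataFrame(rows)


def ts_steps(config: BSMConfig) -> range:
    return range(int(round(config.horizon * 60.0 / config.coupling_dt)))


def differential_response_scan(config: BSMConfig, center_catenin_range,
                               boundary_forces=(800.0, 100.0),
                               boundary_catenin: float = 30.0) -> pd.DataFrame:
    """Center-minus-boundary differences in Yki and growth ratio R."""
    df = center_perturbation(config, center_catenin_range,
                             boundary_catenin=boundary_catenin,
                             boundary_forces=boundary_forces)
    df = df.copy()
    df["delta_yki"] = df.yki_center - df.yki_boundary
    df["delta_R"] = df.R_center - df.R_boundary
    df["experiment"] = "differential_response"
    return df


def jub_production_scan(config: BSMConfig, center_jub_range,
                        boundary_jub: float = 250.0,
                        boundary_force: float = 800.0) -> pd.DataFrame:
    """Sweep the center cell's Jub production; boundary cells at 250 nM/min."""
    rng = np.asarray(center_jub_range, dtype=float)
    if np.any(rng < 0):
        raise ValueError("Jub production must be non-negative")
    rows = []
    for pj in rng:
        prod = np.full(N_CELLS, float(boundary_jub))
        prod[CENTER] = float(pj)
        cfg = replace_cells(config, jub_production=prod,
                            boundary_force=float(boundary_force))
        ts = run_bsm(cfg, record_every=max(1, len(ts_steps(cfg))))
        out = _final_by_class(ts)
        out["delta_yki"] = out["yki_center"] - out["yki_boundary"]
        out["delta_R"] = out["R_center"] - out["R_boundary"]
        out.update({"experiment": "jub_production",
                    "center_jub_production": float(pj),
                    "boundary_force": float(boundary_force)})
        rows.append(out)
    return pd.DataFrame(rows)
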