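"""Drivers wiring geometry, regulatory model, and solver into experiments.

Three kinds of runs mirror the study design:

* two-cell runs (mutual neighbors, ``table1_twocell`` parameters) probing
  the segregation regimes of cis/trans interaction strength;
* tissue runs on the labeled 400-cell packing (``table1_3d`` parameters,
  uniform initial state 0.1, 3600 min horizon) in which epithelial cells
  evolve while mesenchymal cells remain signaling-inert;
* parameter sweeps repeating a tissue run across values of one parameter
  on a shared geometry so differences are attributable to the parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from notchsim.dde import Trajectory, integrate
from notchsim.geometry import (
    EPITHELIAL,
    TissueGraph,
    build_neighbor_graph,
    build_uniform_graph,
    label_mesenchyme,
    relax_packing,
)
from notchsim.model import (
    ParameterSet,
    PerturbationSpec,
    apply_perturbation,
    grn_rhs,
)

__all__ = [
    "RunConfig",
    "TrajectorySet",
    "SweepResult",
    "default_tissue_graph",
    "run_two_cell",
    "run_two_cell_delay_variant",
    "run_tissue",
    "sweep",
]

TWO_CELL_INITIAL = np.array(
    [[0.5, 1.1, 0.0, 1.0, 0.0], [0.6, 1.0, 0.0, 1.0, 0.0]]
)
TISSUE_INITIAL_LEVEL = 0.1


@dataclass(frozen=True)
class RunConfig:
    """One simulation's complete configuration.

    ``initial_noise`` applies i.i.d. uniform multiplicative noise of the
    given relative half-width to the tissue initial state (used by the
    equal-neighbor variant, where symmetry must be broken explicitly).
    """

    preset: str = "table1_3d"
    perturbation: PerturbationSpec = field(
        default_factory=lambda: PerturbationSpec.from_preset("wild_type")
    )
    t_end: float = 3600.0
    dt: float = 0.5
    window: tuple = (3200.0, 3600.0)
    n_cells: int = 400
    n_iterations: int = 100
    geometry_seed: int = 0
    uniform_neighbors: int | None = None  # use k-nearest equal-neighbor graph
    initial_noise: float = 0.0
    noise_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.window[0] < self.window[1] <= self.t_end):
            raise ValueError("analysis window must lie inside [0, t_end]")

    def with_perturbation(self, pert) -> "RunConfig":
        if isinstance(pert, str):
            pert = PerturbationSpec.from_preset(pert)
        return replace(self, perturbation=pert)

    def parameters(self) -> ParameterSet:
        return apply_perturbation(ParameterSet.from_preset(self.preset), self.perturbation)


@dataclass
class TrajectorySet:
    """Trajectories of the evolving (epithelial) cells plus their context.

    ``cell_ids[i]`` is the graph node index of trajectory row ``i``.
    """

    trajectory: Trajectory
    cell_ids: np.ndarray
    graph: TissueGraph | None
    config: RunConfig
    params: ParameterSet

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def var(self, name: str) -> np.ndarray:
        """Time series matrix (n_times, n_cells) of one variable."""
        from notchsim.model import VAR_INDEX

        idx = 5 if name == "NICD" else VAR_INDEX[name]
        return self.trajectory.y[:, :, idx]

    @property
    def t(self) -> np.ndarray:
        return self.trajectory.t


@dataclass
class SweepResult:
    """Per-value fate tables and Hes1 amplitudes for a parameter sweep."""

    parameter: str
    values: list
    fate_tables: list  # one FateTable per value
    amplitudes: list  # one ndarray of per-cell Hes1 amplitudes per value

    def proportions(self, fate: str) -> np.ndarray:
        return np.array([ft.proportions[fate] for ft in self.fate_tables])


def default_tissue_graph(
    seed: int, n_cells: int = 400, n_iterations: int = 100
) -> TissueGraph:
    """The standard labeled tissue: relaxed packing, midpoint graph, hull
    plus hull-neighbor mesenchyme."""
    cloud = relax_packing(n_cells=n_cells, seed=seed, n_iterations=n_iterations)
    return label_mesenchyme(build_neighbor_graph(cloud))


def _neighbor_operator(graph: TissueGraph) -> sparse.csr_matrix:
    """Sparse operator mapping epithelial states to neighbor means.

    Row i (local epithelial index) averages over ALL neighbors of that
    cell: epithelial neighbors contribute their value, mesenchymal ones
    contribute zero but still enlarge the denominator.
    """
    epi = graph.epithelial_indices()
    local = {int(g): i for i, g in enumerate(epi)}
    rows, cols, vals = [], [], []
    for i, g in enumerate(epi):
        nb = graph.neighbors[g]
        if len(nb) == 0:
            raise ValueError(f"epithelial cell {g} has no neighbors")
        w = 1.0 / len(nb)
        for j in nb:
            if graph.cell_class[j] == EPITHELIAL:
                rows.append(i)
                cols.append(local[int(j)])
                vals.append(w)
    n = len(epi)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _make_rhs(W: sparse.csr_matrix, params: ParameterSet, pert: PerturbationSpec):
    """Vectorized tissue right-hand side with delay taps.

    State is (n_epi, 5) or (n_epi, 6) with the NICD variant.  Delayed
    states carry the same shape; the Hes1 auto-inhibition tap is at tau0
    and, when active, the Dll1 production tap at ``pert.dll1_delay``.
    """
    tau0 = params.tau0
    tau = pert.dll1_delay

    def rhs(t, y, delayed):
        D_t = W @ y[:, 1]
        J_t = W @ y[:, 2]
        N_t = W @ y[:, 3]
        delayed_H = delayed[tau0][:, 0]
        kw = {}
        if tau > 0:
            kw["delayed_H_tau"] = delayed[tau][:, 0]
            kw["delayed_P_tau"] = delayed[tau][:, 4]
        if pert.nicd_variant:
            kw["nicd"] = y[:, 5]
        return grn_rhs(
            np.clip(y[:, :5], 0.0, None),
            np.clip(delayed_H, 0.0, None),
            (D_t, J_t, N_t),
            params,
            pert,
            **kw,
        )

    return rhs


def _delays_for(params: ParameterSet, pert: PerturbationSpec, dt: float) -> list:
    delays = [params.tau0]
    if pert.dll1_delay > 0:
        delays.append(pert.dll1_delay)
    for tau in delays:
        if abs(tau / dt - round(tau / dt)) > 1e-9:
            raise ValueError(f"dt={dt} does not divide delay {tau}")
    return delays


def _two_cell_graph() -> TissueGraph:
    pos = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    nb = [np.array([1]), np.array([0])]
    cls = np.array([EPITHELIAL, EPITHELIAL])
    return TissueGraph(positions=pos, neighbors=nb, cell_class=cls)


def run_two_cell(config: RunConfig | None = None, **overrides) -> TrajectorySet:
    """Two mutually neighboring cells from the standard asymmetric start.

    Each cell's trans input is its partner's state.  Uses the two-cell
    parameter preset unless the config says otherwise.
    """
    if config is None:
        config = RunConfig(preset="table1_twocell", **overrides)
    params = config.parameters()
    pert = config.perturbation
    graph = _two_cell_graph()
    W = _neighbor_operator(graph)
    y0 = TWO_CELL_INITIAL.copy()
    if pert.nicd_variant:
        y0 = np.concatenate([y0, np.zeros((2, 1))], axis=1)
    delays = _delays_for(params, pert, config.dt)
    traj = integrate(_make_rhs(W, params, pert), y0, delays, config.t_end, config.dt)
    return TrajectorySet(
        trajectory=traj,
        cell_ids=np.array([0, 1]),
        graph=graph,
        config=config,
        params=params,
    )


def run_two_cell_delay_variant(tau: float, config: RunConfig | None = None) -> TrajectorySet:
    """Two-cell model with Jag1 removed and a Dll1 transcriptional delay.

    ``tau = 0`` reduces exactly to the Jag1-deficient two-cell model.  At
    delays near 10 min the coupled oscillators undergo oscillation death;
    larger delays restore oscillation with the two cells in phase.
    """
    if config is None:
        config = RunConfig(preset="table1_twocell")
    base = config.perturbation
    pert = replace(
        base,
        overrides={**base.overrides, "a_J": 0.0},
        dll1_delay=float(tau),
        name=f"jag1_removed_delay_{tau:g}",
    )
    return run_two_cell(config.with_perturbation(pert))


def run_tissue(
    config: RunConfig, graph: TissueGraph | None = None
) -> TrajectorySet:
    """Tissue run: epithelial cells evolve, mesenchymal cells stay silent.

    All epithelial cells start at the uniform low state 0.1 (optionally
    with small multiplicative noise).  Mesenchymal cells never enter the
    state vector; they only dilute neighbor means through the averaging
    operator's denominators.
    """
    if graph is None:
        if config.uniform_neighbors is not None:
            base = default_tissue_graph(
                config.geometry_seed, config.n_cells, config.n_iterations
            )
            epi_pos = base.positions[base.epithelial_indices()]
            graph = build_uniform_graph(epi_pos, k=config.uniform_neighbors)
        else:
            graph = default_tissue_graph(
                config.geometry_seed, config.n_cells, config.n_iterations
            )
    if not graph.is_labeled:
        raise ValueError("tissue graph must be labeled")
    params = config.parameters()
    pert = config.perturbation
    epi = graph.epithelial_indices()
    W = _neighbor_operator(graph)

    nvar = 6 if pert.nicd_variant else 5
    y0 = np.full((len(epi), 5), TISSUE_INITIAL_LEVEL)
    if config.initial_noise > 0:
        rng = np.random.default_rng(config.noise_seed)
        y0 = y0 * (1.0 + config.initial_noise * rng.uniform(-1, 1, size=y0.shape))
    if nvar == 6:
        y0 = np.concatenate([y0, np.zeros((len(epi), 1))], axis=1)

    delays = _delays_for(params, pert, config.dt)
    traj = integrate(_make_rhs(W, params, pert), y0, delays, config.t_end, config.dt)
    return TrajectorySet(
        trajectory=traj, cell_ids=epi, graph=graph, config=config, params=params
    )


_PERT_FIELDS = {"dll1_delay", "ptf1a_timescale"}


def sweep(
    config: RunConfig,
    parameter: str,
    values,
    graph: TissueGraph | None = None,
    thresholds=None,
) -> SweepResult:
    """One tissue run per parameter value on a shared geometry.

    ``parameter`` may name a rate/Hill constant (an override, e.g.
    ``gamma1``, ``a_J``, ``K2``, ``tau_n``) or a perturbation field
    (``dll1_delay``, ``ptf1a_timescale``).  Fate tables use the frozen
    default thresholds unless given.
    """
    values = list(values)
    if not values:
        raise ValueError("empty sweep value list")
    from notchsim.analysis import fate_proportions

    if graph is None and config.uniform_neighbors is None:
        graph = default_tissue_graph(
            config.geometry_seed, config.n_cells, config.n_iterations
        )
    tables, amps = [], []
    for v in values:
        base = config.perturbation
        if parameter in _PERT_FIELDS:
            pert = replace(base, **{parameter: v})
        else:
            pert = replace(base, overrides={**base.overrides, parameter: v})
        pert = replace(pert, name=f"{base.name}+{parameter}={v:g}")
        ts = run_tissue(config.with_perturbation(pert), graph)
        ft = fate_proportions(ts, thresholds=thresholds)
        tables.append(ft)
        amps.append(ft.per_cell["hes1_amplitude"].to_numpy())
    return SweepResult(parameter=parameter, values=values, fate_tables=tables, amplitudes=amps)
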