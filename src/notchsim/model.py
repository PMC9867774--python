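"""Per-cell Notch/Hes1 regulatory dynamics and the perturbation algebra.

Each cell carries five species: Hes1 (H), Dll1 (D), Jag1 (J), Notch (N)
and Ptf1a (P), all in µM.  Hes1 is delay-auto-inhibited (delay tau0) and
activated by trans Notch signaling; Ptf1a is repressed by Hes1 and drives
both ligands; the ligands are consumed by cis-inhibition within a cell
(rate gamma1) and trans-interaction with neighbor means (rate gamma2).
Bound receptor-ligand complexes use the tight-binding approximation
``[XY] = XY / (X + Y)``, which never exceeds the scarcer species.

Two named parameter presets exist: ``table1_3d`` for the tissue model and
``table1_twocell`` for the two-cell model.  Genotypes and treatments are
declarative :class:`PerturbationSpec` objects: parameter overrides, term
masks for the four cis/trans channels, an optional transcriptional delay
on Dll1 production, a Ptf1a timescale factor delta, and an optional
explicit-NICD variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np

__all__ = [
    "ParameterSet",
    "PerturbationSpec",
    "CellState",
    "VARIABLES",
    "hill_act",
    "hill_rep",
    "bound_complex",
    "neighbor_means",
    "grn_rhs",
    "apply_perturbation",
    "PERTURBATION_PRESETS",
]

VARIABLES = ("H", "D", "J", "N", "P")
VAR_INDEX = {v: i for i, v in enumerate(VARIABLES)}


@dataclass(frozen=True)
class CellState:
    """Convenience container for one cell's concentrations (µM)."""

    H: float
    D: float
    J: float
    N: float
    P: float
    NICD: float | None = None

    def __post_init__(self):
        for v in VARIABLES:
            if getattr(self, v) < 0:
                raise ValueError(f"{v} must be >= 0")
        if self.NICD is not None and self.NICD < 0:
            raise ValueError("NICD must be >= 0")

    def to_array(self) -> np.ndarray:
        vals = [getattr(self, v) for v in VARIABLES]
        if self.NICD is not None:
            vals.append(self.NICD)
        return np.array(vals, dtype=float)

    @classmethod
    def from_array(cls, arr) -> "CellState":
        arr = np.asarray(arr, dtype=float)
        nicd = float(arr[5]) if arr.shape[-1] == 6 else None
        return cls(*(float(x) for x in arr[:5]), NICD=nicd)


@dataclass(frozen=True)
class ParameterSet:
    """Rate, delay, and Hill constants of the regulatory network.

    Production rates ``a_*`` are in µM/min, degradation times ``tau_*`` and
    the auto-inhibition delay ``tau0`` in min, Hill constants ``K1..K6`` in
    µM, and the interaction rates ``gamma1`` (cis) and ``gamma2`` (trans)
    are taken literally as tabulated.
    """

    a_H: float
    a_D: float
    a_w: float
    a_J: float
    a_N: float
    a_P: float
    tau0: float
    tau_h: float
    tau_d: float
    tau_j: float
    tau_n: float
    tau_p: float
    gamma1: float
    gamma2: float
    K1: float
    K2: float
    K3: float
    K4: float
    K5: float
    K6: float
    a_NICD: float = 1.0
    tau_NICD: float = 10.0

    def __post_init__(self):
        strictly_positive = (
            "a_H", "a_N", "a_P", "tau0", "tau_h", "tau_d", "tau_j", "tau_n",
            "tau_p", "K1", "K2", "K3", "K4", "K5", "K6", "a_NICD", "tau_NICD",
        )
        for name in strictly_positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")
        for name in ("a_D", "a_w", "a_J", "gamma1", "gamma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")

    @classmethod
    def from_preset(cls, name: str) -> "ParameterSet":
        try:
            return cls(**_PARAMETER_PRESETS[name])
        except KeyError:
            raise KeyError(
                f"unknown preset {name!r}; available: {sorted(_PARAMETER_PRESETS)}"
            ) from None

    def with_overrides(self, **overrides) -> "ParameterSet":
        for key in overrides:
            if key not in self.__dataclass_fields__:
                raise KeyError(f"unknown parameter {key!r}")
        return replace(self, **overrides)

    def as_dict(self) -> dict:
        return asdict(self)


_PARAMETER_PRESETS = {
    # 3D tissue model
    "table1_3d": dict(
        a_H=3.0, a_D=0.5, a_w=0.8, a_J=1.0, a_N=0.5, a_P=0.2,
        tau0=40.0, tau_h=20.0, tau_d=50.0, tau_j=120.0, tau_n=50.0, tau_p=120.0,
        gamma1=0.25, gamma2=0.02,
        K1=0.3, K2=0.06, K3=0.8, K4=4.0, K5=0.1, K6=4.0,
    ),
    # two-cell model (values in parentheses of the table)
    "table1_twocell": dict(
        a_H=5.0, a_D=0.5, a_w=1.0, a_J=1.0, a_N=0.5, a_P=0.1,
        tau0=40.0, tau_h=20.0, tau_d=50.0, tau_j=120.0, tau_n=50.0, tau_p=120.0,
        gamma1=0.25, gamma2=0.1,
        K1=0.5, K2=0.5, K3=1.0, K4=4.0, K5=0.2, K6=10.0,
    ),
}


@dataclass(frozen=True)
class PerturbationSpec:
    """Declarative genotype / treatment modification.

    ``overrides`` rewrites named parameters; the four boolean masks switch
    individual interaction channels off (cis/trans, per ligand);
    ``dll1_delay`` adds a transcriptional delay (min) to both Dll1
    production terms; ``ptf1a_timescale`` multiplies the whole Ptf1a
    right-hand side (delta), changing its speed but not its fixed point;
    ``nicd_variant`` tracks NICD as an explicit sixth variable.
    """

    overrides: dict = field(default_factory=dict)
    cis_D: bool = True
    cis_J: bool = True
    trans_D: bool = True
    trans_J: bool = True
    dll1_delay: float = 0.0
    ptf1a_timescale: float = 1.0
    nicd_variant: bool = False
    name: str = "custom"

    def __post_init__(self):
        if self.dll1_delay < 0:
            raise ValueError("dll1_delay must be >= 0")
        if self.ptf1a_timescale <= 0:
            raise ValueError("ptf1a_timescale must be > 0")

    @classmethod
    def from_preset(cls, name: str, **extra_overrides) -> "PerturbationSpec":
        try:
            spec = PERTURBATION_PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown perturbation {name!r}; available: {sorted(PERTURBATION_PRESETS)}"
            ) from None
        if extra_overrides:
            spec = replace(spec, overrides={**spec.overrides, **extra_overrides})
        return spec


PERTURBATION_PRESETS = {
    "wild_type": PerturbationSpec(name="wild_type"),
    # ligand knockouts
    "dll1_ko": PerturbationSpec(overrides={"a_D": 0.0, "a_w": 0.0}, name="dll1_ko"),
    "jag1_ko": PerturbationSpec(overrides={"a_J": 0.0}, name="jag1_ko"),
    # drug treatments act on the Notch->Hes1 response threshold K2
    "dmso": PerturbationSpec(overrides={"K2": 0.06}, name="dmso"),
    "dapt": PerturbationSpec(overrides={"K2": 0.3}, name="dapt"),
    "mln4924": PerturbationSpec(overrides={"K2": 0.01}, name="mln4924"),
    # Dll1 transcriptional-delay mutant
    "type2_dll1": PerturbationSpec(dll1_delay=6.0, name="type2_dll1"),
    # rescue of low cis-inhibition by Jag1 overexpression
    "jag1_rescue": PerturbationSpec(overrides={"gamma1": 0.2, "a_J": 4.0}, name="jag1_rescue"),
    # equal-neighbor tissue variant uses a slightly larger K2
    "equal_neighbor": PerturbationSpec(overrides={"K2": 0.08}, name="equal_neighbor"),
    # single-channel ablations
    "no_cis_dll1": PerturbationSpec(cis_D=False, name="no_cis_dll1"),
    "no_trans_dll1": PerturbationSpec(trans_D=False, name="no_trans_dll1"),
    "no_cis_jag1": PerturbationSpec(cis_J=False, name="no_cis_jag1"),
    "no_trans_jag1": PerturbationSpec(trans_J=False, name="no_trans_jag1"),
    "jag1_cis_only": PerturbationSpec(trans_J=False, name="jag1_cis_only"),
    "jag1_trans_only": PerturbationSpec(cis_J=False, name="jag1_trans_only"),
}


def hill_act(x, K):
    """Activating Hill function x^2 / (x^2 + K^2) in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be >= 0")
    if np.any(np.asarray(K) <= 0):
        raise ValueError("Hill constant must be > 0")
    x2 = x * x
    return x2 / (x2 + K * K)


def hill_rep(x, K):
    """Repressing Hill function K^2 / (K^2 + x^2) = 1 - hill_act(x, K)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be >= 0")
    if np.any(np.asarray(K) <= 0):
        raise ValueError("Hill constant must be > 0")
    K2 = K * K
    return K2 / (K2 + x * x)


def bound_complex(a, b):
    """Tight-binding complex level ab / (a + b); 0 when both vanish.

    Symmetric, bounded by min(a, b), and saturating at the scarcer species.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    s = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, a * b / np.where(s > 0, s, 1.0), 0.0)
    return out if out.ndim else float(out)


def neighbor_means(graph, states: np.ndarray, cell: int) -> tuple:
    """Mean (D_t, J_t, N_t) over all neighbors of ``cell``.

    Mesenchymal neighbors contribute zeros but still count in the
    denominator, so cells at the epithelial surface receive diluted ligand.
    ``states`` holds rows per cell in the order H, D, J, N, P (mesenchymal
    rows are ignored; any value may sit there).
    """
    if graph.cell_class is None:
        raise ValueError("graph must be labeled")
    nb = graph.neighbors[cell]
    if len(nb) == 0:
        raise ValueError(f"cell {cell} has no neighbors")
    from notchsim.geometry import EPITHELIAL

    epi = np.array([j for j in nb if graph.cell_class[j] == EPITHELIAL], dtype=int)
    n = len(nb)
    if epi.size == 0:
        return (0.0, 0.0, 0.0)
    D_t = float(states[epi, VAR_INDEX["D"]].sum() / n)
    J_t = float(states[epi, VAR_INDEX["J"]].sum() / n)
    N_t = float(states[epi, VAR_INDEX["N"]].sum() / n)
    return (D_t, J_t, N_t)


def apply_perturbation(base: ParameterSet, spec: PerturbationSpec) -> ParameterSet:
    """Effective parameters after applying the spec's overrides (pure)."""
    return base.with_overrides(**spec.overrides)


def grn_rhs(
    state: np.ndarray,
    delayed_H: np.ndarray,
    trans: tuple,
    params: ParameterSet,
    pert: PerturbationSpec | None = None,
    delayed_H_tau: np.ndarray | None = None,
    delayed_P_tau: np.ndarray | None = None,
    nicd: np.ndarray | None = None,
) -> np.ndarray:
    """Time derivative of one or many cell states.

    Parameters
    ----------
    state:
        Array ``(..., 5)`` of (H, D, J, N, P), all >= 0.
    delayed_H:
        Hes1 at ``t - tau0`` (auto-inhibition delay), shape ``(...)``.
    trans:
        Tuple of arrays ``(D_t, J_t, N_t)``: neighbor-mean ligand and
        receptor levels seen by each cell.
    pert:
        Term masks / delay / timescale spec.  Parameter overrides must
        already be folded in via :func:`apply_perturbation`.
    delayed_H_tau, delayed_P_tau:
        Hes1 and Ptf1a at ``t - tau`` for the delayed-Dll1 variant;
        required iff ``pert.dll1_delay > 0``.
    nicd:
        Current NICD level; required iff ``pert.nicd_variant``.  In that
        case the returned array has 6 columns (dNICD/dt last) and the Hes1
        activation reads the tracked NICD instead of the instantaneous
        trans signal.
    """
    pert = pert or PERTURBATION_PRESETS["wild_type"]
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("negative concentrations")
    H = state[..., 0]
    D = state[..., 1]
    J = state[..., 2]
    N = state[..., 3]
    P = state[..., 4]
    D_t, J_t, N_t = (np.asarray(x, dtype=float) for x in trans)
    delayed_H = np.asarray(delayed_H, dtype=float)

    p = params
    # cis and trans complexes per the tight-binding approximation
    ND_cis = bound_complex(N, D) if pert.cis_D else 0.0
    NJ_cis = bound_complex(N, J) if pert.cis_J else 0.0
    NDt = bound_complex(N, D_t) if pert.trans_D else 0.0
    NJt = bound_complex(N, J_t) if pert.trans_J else 0.0
    DNt = bound_complex(D, N_t) if pert.trans_D else 0.0
    JNt = bound_complex(J, N_t) if pert.trans_J else 0.0

    # Hes1: delayed auto-inhibition x Notch-signal activation - decay.
    # The activation input is the trans signal gamma2([NDt]+[NJt]), or the
    # tracked NICD rescaled by its quasi-steady-state gain in the explicit
    # variant (so the fast-NICD limit reproduces the simplified model).
    if pert.nicd_variant:
        if nicd is None:
            raise ValueError("nicd_variant requires the NICD level")
        signal = np.asarray(nicd, dtype=float) / (p.a_NICD * p.tau_NICD)
    else:
        signal = p.gamma2 * (NDt + NJt)
    act = signal * signal / (signal * signal + p.K2 * p.K2)
    dH = p.a_H * hill_rep(delayed_H, p.K1) * act - H / p.tau_h

    # Dll1: Hes1-repressed + Ptf1a-activated production (optionally with a
    # transcriptional delay tau), minus cis/trans consumption and decay
    if pert.dll1_delay > 0:
        if delayed_H_tau is None or delayed_P_tau is None:
            raise ValueError("dll1_delay > 0 requires delayed H and P values")
        H_prod = np.asarray(delayed_H_tau, dtype=float)
        P_prod = np.asarray(delayed_P_tau, dtype=float)
    else:
        H_prod, P_prod = H, P
    dD = (
        p.a_D * hill_rep(H_prod, p.K3)
        + p.a_w * hill_act(P_prod, p.K6)
        - p.gamma1 * ND_cis
        - p.gamma2 * DNt
        - D / p.tau_d
    )

    dJ = p.a_J * hill_act(P, p.K4) - p.gamma1 * NJ_cis - p.gamma2 * JNt - J / p.tau_j

    dN = (
        p.a_N
        - p.gamma1 * ND_cis
        - p.gamma1 * NJ_cis
        - p.gamma2 * NDt
        - p.gamma2 * NJt
        - N / p.tau_n
    )

    dP = (p.a_P * hill_rep(H, p.K5) - P / p.tau_p) * pert.ptf1a_timescale

    out = np.stack(np.broadcast_arrays(dH, dD, dJ, dN, dP), axis=-1)
    if pert.nicd_variant:
        dNICD = p.a_NICD * p.gamma2 * (NDt + NJt) - np.asarray(nicd, float) / p.tau_NICD
        out = np.concatenate(
            [out, np.broadcast_to(dNICD, out.shape[:-1])[..., None]], axis=-1
        )
    return out
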