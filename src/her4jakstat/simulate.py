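"""Time-course integration of the pathway ODEs.

The network is compiled once into vectorized numpy arrays (exponent
matrices for the mass-action products, a volume-scaled contribution
matrix), then integrated with a stiff solver (LSODA) and resampled onto a
uniform output grid.  Default tolerances rtol=1e-8 / atol=1e-10 nM resolve
peak times well below the output step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import (
    FIRST_ORDER_TRANSPORT,
    HILL_ACTIVATION,
    MASS_ACTION_REVERSIBLE,
    ReactionNetwork,
    effective_stoichiometry_matrix,
)

__all__ = [
    "DoseProtocol",
    "Trajectory",
    "IntegrationError",
    "CompiledModel",
    "run_timecourse",
    "run_dose_series",
    "run_ensemble",
    "trajectories_to_frame",
]

logger = logging.getLogger(__name__)

_CLIP_FLOOR = -1e-6  # gross negativity -> integration failure


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the offending parameters."""

    def __init__(self, message: str, params: dict | None = None):
        super().__init__(message)
        self.params = params or {}


@dataclass
class DoseProtocol:
    """NRG dose series: doses in nM, horizon and output step in hours."""

    nrg_doses: list[float] = field(default_factory=lambda: [0.0, 10.0, 20.0, 50.0])
    t_end: float = 48.0
    output_step: float = 0.01

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.nrg_doses):
            raise ValueError("doses must be non-negative")
        if sorted(self.nrg_doses) != list(self.nrg_doses):
            raise ValueError("doses must be sorted ascending")
        if self.t_end <= 0 or self.output_step <= 0:
            raise ValueError("t_end and output_step must be positive")


@dataclass
class Trajectory:
    """Uniform-grid solution of one simulation (concentrations in nM)."""

    times: np.ndarray
    conc: np.ndarray  # (n_species, n_times)
    species_ids: list[str]
    dose: float
    params_used: dict[str, float]

    def index(self, species_id: str) -> int:
        return self.species_ids.index(species_id)

    def get(self, species_id: str) -> np.ndarray:
        return self.conc[self.index(species_id)]

    def to_frame(self, member_id: int | None = None) -> pd.DataFrame:
        """Tidy table: time_h, species_id, conc_nM, dose_nM[, member_id]."""
        n_t = len(self.times)
        df = pd.DataFrame({
            "time_h": np.tile(self.times, len(self.species_ids)),
            "species_id": np.repeat(self.species_ids, n_t),
            "conc_nM": self.conc.ravel(),
            "dose_nM": self.dose,
        })
        if member_id is not None:
            df["member_id"] = member_id
        return df


class CompiledModel:
    """Vectorized rate/RHS evaluator for one network topology.

    Parameter values are passed per call, so one compiled model serves an
    entire parameter ensemble.
    """

    def __init__(self, net: ReactionNetwork):
        self.net = net
        self.species_ids = net.species_ids
        self.param_ids = sorted(net.parameters)
        self._pidx = {p: i for i, p in enumerate(self.param_ids)}
        n_sp, n_rxn = len(net.species), len(net.reactions)
        idx = net.species_index
        vol = {c.id: c.volume for c in net.compartments}

        self._fwd_exp = np.zeros((n_rxn, n_sp))
        self._rev_exp = np.zeros((n_rxn, n_sp))
        self._kf_idx = np.zeros(n_rxn, dtype=int)
        self._kr_idx = np.full(n_rxn, -1, dtype=int)
        self._hill_rows: list[tuple[int, int, int, int, int]] = []
        for j, r in enumerate(net.reactions):
            law = r.rate_law
            if law.kind == HILL_ACTIVATION:
                self._hill_rows.append((
                    j,
                    idx[r.modifiers[0]],
                    self._pidx[law.params["V_transc"]],
                    self._pidx[law.params["K_transc"]],
                    self._pidx[law.params["n_transc"]],
                ))
                continue
            for sid, st in r.reactants:
                self._fwd_exp[j, idx[sid]] += st
            if law.kind == MASS_ACTION_REVERSIBLE:
                for sid, st in r.products:
                    self._rev_exp[j, idx[sid]] += st
                self._kr_idx[j] = self._pidx[law.params["kr"]]
            key = "k_transport" if law.kind == FIRST_ORDER_TRANSPORT else "kf"
            self._kf_idx[j] = self._pidx[law.params[key]]

        self._rev_rows = np.where(self._kr_idx >= 0)[0]
        self._mass_rows = np.array(
            [j for j in range(n_rxn) if j not in {h[0] for h in self._hill_rows}],
            dtype=int,
        )
        v_loc = np.array([vol[net.reaction_compartment(r)] for r in net.reactions])
        v_sp = net.species_volumes()
        self.contribution = (
            effective_stoichiometry_matrix(net) * v_loc[None, :] / v_sp[:, None]
        )

    def param_vector(self, params: dict[str, float]) -> np.ndarray:
        return np.array([params[p] for p in self.param_ids], dtype=float)

    def rates(self, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)
        v = np.prod(yc[None, :] ** self._fwd_exp, axis=1) * p[self._kf_idx]
        if self._rev_rows.size:
            rev = np.prod(yc[None, :] ** self._rev_exp[self._rev_rows], axis=1)
            v[self._rev_rows] -= rev * p[self._kr_idx[self._rev_rows]]
        for j, mi, vi, ki, ni in self._hill_rows:
            m = yc[mi]
            if m > 0.0:
                mn = m ** p[ni]
                v[j] = p[vi] * mn / (p[ki] ** p[ni] + mn)
            else:
                v[j] = 0.0
        return v

    def rhs(self, t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        return self.contribution @ self.rates(y, p)


_COMPILE_CACHE: dict[int, CompiledModel] = {}


def compiled(net: ReactionNetwork) -> CompiledModel:
    model = _COMPILE_CACHE.get(id(net))
    if model is None or model.net is not net:
        model = CompiledModel(net)
        _COMPILE_CACHE[id(net)] = model
    return model


def run_timecourse(
    net: ReactionNetwork,
    dose: float,
    t_end: float = 48.0,
    output_step: float = 0.01,
    params: dict[str, float] | None = None,
    init_overrides: dict[str, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dose_species: str = "NRG",
) -> Trajectory:
    """Integrate the network from its initial amounts with an NRG bolus.

    ``params`` overrides rate constants; ``init_overrides`` overrides
    initial amounts (both leave the network object untouched).
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    model = compiled(net)
    p_map = dict(net.parameters)
    if params:
        unknown = set(params) - set(p_map)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        p_map.update(params)
    y0 = net.initial_state()
    if init_overrides:
        sidx = net.species_index
        for sid, val in init_overrides.items():
            y0[sidx[sid]] = val
    if dose > 0 or dose_species in model.species_ids:
        try:
            y0[model.species_ids.index(dose_species)] = dose
        except ValueError:
            raise KeyError(f"dose species {dose_species!r} not in network") from None

    p = model.param_vector(p_map)
    n_steps = int(round(t_end / output_step))
    t_eval = np.linspace(0.0, n_steps * output_step, n_steps + 1)
    sol = solve_ivp(
        model.rhs, (0.0, t_eval[-1]), y0, method="LSODA", t_eval=t_eval,
        args=(p,), rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}", p_map)
    conc = sol.y
    if not np.all(np.isfinite(conc)):
        raise IntegrationError("non-finite concentrations", p_map)
    if conc.min() < _CLIP_FLOOR:
        raise IntegrationError(
            f"negative concentration {conc.min():.3g} nM beyond tolerance", p_map
        )
    return Trajectory(sol.t, np.maximum(conc, 0.0), list(model.species_ids), dose, p_map)


def run_dose_series(net: ReactionNetwork, protocol: DoseProtocol, **kwargs) -> list[Trajectory]:
    """One trajectory per dose on identical time grids."""
    return [
        run_timecourse(net, d, protocol.t_end, protocol.output_step, **kwargs)
        for d in protocol.nrg_doses
    ]


def run_ensemble(
    net: ReactionNetwork,
    protocol: DoseProtocol,
    space,
    n_members: int,
    seed: int,
    max_dropout: float = 0.05,
    **kwargs,
) -> list[tuple[dict[str, float], list[Trajectory]]]:
    """Latin-Hypercube parameter ensemble of dose series.

    ``space`` is a :class:`her4jakstat.sampling.ParameterSpace` whose entry
    ids name either rate constants or species initial amounts.  Members
    whose integration fails are dropped (logged); if more than
    ``max_dropout`` of members fail, an error is raised.
    """
    from .sampling import latin_hypercube, scale_to_space, split_overrides

    if n_members < 2:
        raise ValueError("n_members must be >= 2")
    unit = latin_hypercube(n_members, space.k, seed)
    values = scale_to_space(unit, space)
    members: list[tuple[dict[str, float], list[Trajectory]]] = []
    failures = 0
    for row in values:
        draw = dict(zip(space.ids, row))
        p_over, i_over = split_overrides(net, draw)
        try:
            trajs = run_dose_series(
                net, protocol, params=p_over, init_overrides=i_over, **kwargs
            )
        except IntegrationError as err:
            failures += 1
            logger.warning("ensemble member dropped: %s", err)
            continue
        members.append((draw, trajs))
    if not members:
        raise IntegrationError("all ensemble members failed")
    frac = failures / n_members
    logger.info("ensemble dropout: %d/%d (%.1f%%)", failures, n_members, 100 * frac)
    if frac > max_dropout:
        raise IntegrationError(
            f"ensemble dropout {frac:.1%} exceeds {max_dropout:.0%}"
        )
    return members


def trajectories_to_frame(members) -> pd.DataFrame:
    """Tidy CSV-ready table for an ensemble (or plain list) of trajectories."""
    frames = []
    if members and isinstance(members[0], Trajectory):
        members = [(None, members)]
    for m, (_, trajs) in enumerate(members):
        for traj in trajs:
            frames.append(traj.to_frame(member_id=m))
    return pd.concat(frames, ignore_index=True)
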