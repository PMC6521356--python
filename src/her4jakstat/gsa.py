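"""Variance-based (Sobol') global sensitivity analysis.

First-order and total-effect indices are estimated with the Saltelli
product estimators over the A/B/A_B^i/B_A^i design:

    V_Xi (E(Y|Xi))   ~  (1/N) sum_j f(A)_j f(B_A^i)_j  -  f0^2
    V_X~i(E(Y|X~i))  ~  (1/N) sum_j f(A)_j f(A_B^i)_j  -  f0^2

    S_i  =  V_Xi / V(Y)          S_Ti  =  1 - V_X~i / V(Y)

with f0^2 estimated as mean(fA)·mean(fB) and V(Y) as the sample variance
of fA and fB pooled.  Negative estimates are reported raw (Monte Carlo
noise); clipping at zero is applied only when ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .readouts import compute_readouts
from .sampling import ParameterSpace, SaltelliDesign, scale_to_space, split_overrides
from .simulate import IntegrationError, run_timecourse

__all__ = [
    "EvaluationBundle",
    "SensitivityResult",
    "evaluate_design",
    "model_evaluator",
    "first_order_index",
    "total_effect_index",
    "analyze",
    "rank_top",
    "result_to_frame",
]

logger = logging.getLogger(__name__)

OUTPUT_NAMES = ("integrated_casein", "switch_ratio", "delay")


@dataclass
class EvaluationBundle:
    """Model outputs on every design row, with failed rows excluded pairwise."""

    fA: np.ndarray
    fB: np.ndarray
    fAB: list[np.ndarray]
    fBA: list[np.ndarray]
    failures: list[int] = field(default_factory=list)

    @property
    def N(self) -> int:
        return len(self.fA)

    @property
    def k(self) -> int:
        return len(self.fAB)


@dataclass
class SensitivityResult:
    output_name: str
    parameter_ids: list[str]
    S1: np.ndarray
    ST: np.ndarray
    f0: float
    VY: float
    N: int
    dose_nM: float = float("nan")


def first_order_index(
    fA: np.ndarray, fBA_i: np.ndarray, f0_sq: float, VY: float, N: int | None = None
) -> float:
    """S_i = [(1/N) sum_j fA_j * fBA_i_j - f0^2] / V(Y)."""
    if VY <= 0:
        raise ValueError("output has no variance")
    n = N if N is not None else len(fA)
    return (float(np.dot(fA, fBA_i)) / n - f0_sq) / VY


def total_effect_index(
    fA: np.ndarray, fAB_i: np.ndarray, f0_sq: float, VY: float, N: int | None = None
) -> float:
    """S_Ti = 1 - [(1/N) sum_j fA_j * fAB_i_j - f0^2] / V(Y)."""
    if VY <= 0:
        raise ValueError("output has no variance")
    n = N if N is not None else len(fA)
    return 1.0 - (float(np.dot(fA, fAB_i)) / n - f0_sq) / VY


def evaluate_design(
    design: SaltelliDesign,
    evaluator: Callable[[np.ndarray], float],
    space: ParameterSpace | None = None,
    max_failure_frac: float = 0.2,
) -> EvaluationBundle:
    """Evaluate a scalar model on every row of the Saltelli design.

    ``evaluator`` receives one row; with ``space`` given the row is first
    scaled from the unit hypercube to parameter values.  Rows where the
    evaluator raises (or returns non-finite) are recorded and excluded
    pairwise across all matrices.
    """
    mats = [design.A, design.B, *design.AB, *design.BA]

    def run(row: np.ndarray) -> float:
        if space is not None:
            row = scale_to_space(row[None, :], space)[0]
        try:
            val = float(evaluator(row))
        except (IntegrationError, ValueError, FloatingPointError) as err:
            logger.warning("design row failed: %s", err)
            return np.nan
        return val if np.isfinite(val) else np.nan

    columns = np.array([[run(M[j]) for M in mats] for j in range(design.N)])
    bad = ~np.all(np.isfinite(columns), axis=1)
    failures = list(np.where(bad)[0])
    if len(failures) > max_failure_frac * design.N:
        raise RuntimeError(
            f"{len(failures)}/{design.N} design rows failed; bounds likely pathological"
        )
    good = columns[~bad]
    k = design.k
    return EvaluationBundle(
        fA=good[:, 0],
        fB=good[:, 1],
        fAB=[good[:, 2 + i] for i in range(k)],
        fBA=[good[:, 2 + k + i] for i in range(k)],
        failures=failures,
    )


def model_evaluator(
    net,
    output: str,
    dose: float,
    space: ParameterSpace,
    t_end: float = 48.0,
    output_step: float = 0.05,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> Callable[[np.ndarray], float]:
    """Build a row evaluator that simulates the model and extracts a readout.

    The returned callable expects rows already scaled to parameter values
    in the order of ``space.ids``.  GSA runs use a coarser grid and looser
    tolerances than single trajectories; both are configurable.
    """
    if output not in OUTPUT_NAMES:
        raise ValueError(f"output must be one of {OUTPUT_NAMES}")

    def evaluate(row: np.ndarray) -> float:
        draw = dict(zip(space.ids, row))
        p_over, i_over = split_overrides(net, draw)
        traj = run_timecourse(
            net, dose, t_end=t_end, output_step=output_step,
            params=p_over, init_overrides=i_over, rtol=rtol, atol=atol,
        )
        rs = compute_readouts(traj, require_peak=(output == "delay"))
        return {
            "integrated_casein": rs.integral_total_0_48,
            "switch_ratio": rs.switch_ratio,
            "delay": rs.delay_h,
        }[output]

    return evaluate


def evaluate_design_outputs(
    design: SaltelliDesign,
    net,
    space: ParameterSpace,
    dose: float,
    outputs: Sequence[str] = OUTPUT_NAMES,
    max_failure_frac: float = 0.2,
    **sim_kwargs,
) -> dict[str, EvaluationBundle]:
    """Evaluate the ODE model once per design row, extracting several
    readouts from each trajectory (one bundle per requested output).

    Failure exclusion is pairwise per output: an integration failure drops
    the row everywhere, a missing peak drops it only for ``delay``.
    """
    bad_outputs = set(outputs) - set(OUTPUT_NAMES)
    if bad_outputs:
        raise ValueError(f"unknown outputs: {sorted(bad_outputs)}")
    mats = [design.A, design.B, *design.AB, *design.BA]
    sim_kwargs.setdefault("output_step", 0.05)
    sim_kwargs.setdefault("rtol", 1e-6)
    sim_kwargs.setdefault("atol", 1e-8)

    def run(row: np.ndarray) -> dict[str, float]:
        draw = dict(zip(space.ids, scale_to_space(row[None, :], space)[0]))
        p_over, i_over = split_overrides(net, draw)
        try:
            traj = run_timecourse(net, dose, params=p_over,
                                  init_overrides=i_over, **sim_kwargs)
            rs = compute_readouts(traj, require_peak=False)
        except (IntegrationError, ValueError) as err:
            logger.warning("design row failed: %s", err)
            return {o: np.nan for o in outputs}
        vals = {"integrated_casein": rs.integral_total_0_48,
                "switch_ratio": rs.switch_ratio, "delay": rs.delay_h}
        return {o: vals[o] for o in outputs}

    rows = [[run(M[j]) for M in mats] for j in range(design.N)]
    k = design.k
    bundles: dict[str, EvaluationBundle] = {}
    for o in outputs:
        cols = np.array([[cell[o] for cell in row] for row in rows])
        bad = ~np.all(np.isfinite(cols), axis=1)
        failures = list(np.where(bad)[0])
        if len(failures) > max_failure_frac * design.N:
            raise RuntimeError(
                f"{len(failures)}/{design.N} design rows failed for "
                f"output {o!r}; bounds likely pathological"
            )
        good = cols[~bad]
        bundles[o] = EvaluationBundle(
            fA=good[:, 0], fB=good[:, 1],
            fAB=[good[:, 2 + i] for i in range(k)],
            fBA=[good[:, 2 + k + i] for i in range(k)],
            failures=failures,
        )
    return bundles


def analyze(
    bundle: EvaluationBundle,
    design: SaltelliDesign,
    output_name: str = "output",
    dose_nM: float = float("nan"),
) -> SensitivityResult:
    """Assemble S1/ST for every parameter from an evaluation bundle."""
    if bundle.k != design.k:
        raise ValueError("bundle/design dimension mismatch")
    fA, fB = bundle.fA, bundle.fB
    n = bundle.N
    if n < 2:
        raise ValueError("too few surviving design rows")
    f0_sq = float(np.mean(fA) * np.mean(fB))
    VY = float(np.var(np.concatenate([fA, fB]), ddof=1))
    if VY <= 0:
        raise ValueError("output has no variance")
    S1 = np.array([
        first_order_index(fA, bundle.fBA[i], f0_sq, VY, n) for i in range(bundle.k)
    ])
    ST = np.array([
        total_effect_index(fA, bundle.fAB[i], f0_sq, VY, n) for i in range(bundle.k)
    ])
    return SensitivityResult(
        output_name=output_name,
        parameter_ids=list(design.parameter_ids) or [f"x{i+1}" for i in range(bundle.k)],
        S1=S1, ST=ST,
        f0=float(np.sqrt(max(f0_sq, 0.0))), VY=VY, N=n, dose_nM=dose_nM,
    )


def rank_top(result: SensitivityResult, n: int = 10) -> list[tuple[str, float, float]]:
    """Top-n parameters by total effect (ST clipped at 0 for sorting only;
    ties broken lexicographically by parameter id)."""
    rows = list(zip(result.parameter_ids, result.S1, result.ST))
    rows.sort(key=lambda r: (-max(r[2], 0.0), r[0]))
    return [(pid, float(s1), float(st)) for pid, s1, st in rows[:n]]


def result_to_frame(results: Sequence[SensitivityResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for pid, s1, st in zip(res.parameter_ids, res.S1, res.ST):
            rows.append({
                "parameter_id": pid, "S1": float(s1), "ST": float(st),
                "N": res.N, "output_name": res.output_name, "dose_nM": res.dose_nM,
            })
    return pd.DataFrame(rows)
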