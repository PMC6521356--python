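"""Self-contained benchmarks and oracles.

Everything needed to validate the estimators and the integrator without
external data: analytic test functions with closed-form Sobol' indices, a
two-step decay network with a closed-form solution, a brute-force
double-loop Monte Carlo sensitivity oracle, and a generator of pseudo-
experimental fold-change tables mimicking RT-PCR readouts of beta-casein
under an NRG dose series.

The closed forms here are implemented independently of the Saltelli
estimators and of the ODE integrator they validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .network import Compartment, RateLaw, Reaction, ReactionNetwork, Species
from .readouts import INTERVALS, ReadoutSet, normalize_to_control

__all__ = [
    "AnalyticTestFunction",
    "PseudoExperiment",
    "ishigami",
    "ishigami_function",
    "ishigami_closed_form_indices",
    "additive_linear",
    "toy_decay_network",
    "toy_decay_closed_form",
    "double_loop_sobol",
    "generate_pseudo_experiment",
]


@dataclass
class AnalyticTestFunction:
    """A unit-hypercube test function with known Sobol' indices."""

    name: str
    k: int
    evaluator: Callable[[np.ndarray], float]
    closed_form_S1: np.ndarray
    closed_form_ST: np.ndarray

    def __post_init__(self) -> None:
        s1, st = np.asarray(self.closed_form_S1), np.asarray(self.closed_form_ST)
        if np.any(s1 < -1e-12) or np.any(st > 1 + 1e-12):
            raise ValueError("closed-form indices must lie in [0, 1]")
        if s1.sum() > 1 + 1e-12:
            raise ValueError("sum of first-order indices cannot exceed 1")


ISHIGAMI_A = 7.0
ISHIGAMI_B = 0.1


def ishigami(x: np.ndarray, a: float = ISHIGAMI_A, b: float = ISHIGAMI_B) -> float:
    """Ishigami function on the unit cube (mapped internally to [-pi, pi]^3)."""
    x = np.asarray(x, dtype=float)
    z = -np.pi + 2 * np.pi * x
    return float(np.sin(z[0]) + a * np.sin(z[1]) ** 2 + b * z[2] ** 4 * np.sin(z[0]))


def ishigami_closed_form_indices(
    a: float = ISHIGAMI_A, b: float = ISHIGAMI_B
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic S1 and ST of the Ishigami function.

    V(Y)  = a^2/8 + b pi^4/5 + b^2 pi^8/18 + 1/2
    V1    = (1 + b pi^4/5)^2 / 2          (x3 enters only via x1 interaction)
    V2    = a^2/8,   V3 = 0
    VT1   = V1 + 8 b^2 pi^8 / 225 = VT3 + V1,   VT2 = V2
    """
    pi = np.pi
    V = a**2 / 8 + b * pi**4 / 5 + b**2 * pi**8 / 18 + 0.5
    V1 = 0.5 * (1 + b * pi**4 / 5) ** 2
    V2 = a**2 / 8
    V13 = 8 * b**2 * pi**8 / 225
    S1 = np.array([V1 / V, V2 / V, 0.0])
    ST = np.array([(V1 + V13) / V, V2 / V, V13 / V])
    return S1, ST


def ishigami_function(a: float = ISHIGAMI_A, b: float = ISHIGAMI_B) -> AnalyticTestFunction:
    S1, ST = ishigami_closed_form_indices(a, b)
    return AnalyticTestFunction(
        "ishigami", 3, lambda x: ishigami(x, a, b), S1, ST
    )


def additive_linear(k: int) -> AnalyticTestFunction:
    """Y = sum_i X_i with X_i iid uniform: S1_i = ST_i = 1/k exactly."""
    if k < 1:
        raise ValueError("k must be >= 1")
    w = np.full(k, 1.0 / k)
    return AnalyticTestFunction(
        f"additive_linear_{k}", k,
        lambda x: float(np.sum(np.asarray(x, dtype=float))),
        w.copy(), w.copy(),
    )


# ---------------------------------------------------------------------------
# Integrator oracle
# ---------------------------------------------------------------------------

def toy_decay_network(k1: float = 1.0, k2: float = 2.0, a0: float = 1.0) -> ReactionNetwork:
    """Two-step decay A -> B -> 0 with a closed-form solution."""
    return ReactionNetwork(
        compartments=[Compartment("cyt", "cytoplasm", 1.0)],
        species=[
            Species("A", "species A", "cyt", a0, "protein"),
            Species("B", "species B", "cyt", 0.0, "protein"),
        ],
        reactions=[
            Reaction("T1", "A decay to B", [("A", 1)], [("B", 1)],
                     RateLaw("mass_action_irreversible", {"kf": "k1"})),
            Reaction("T2", "B degradation", [("B", 1)], [],
                     RateLaw("mass_action_irreversible", {"kf": "k2"})),
        ],
        parameters={"k1": k1, "k2": k2},
    )


def toy_decay_closed_form(
    t: np.ndarray, k1: float = 1.0, k2: float = 2.0, a0: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """A(t) = A0 e^{-k1 t};  B(t) = A0 k1 (e^{-k1 t} - e^{-k2 t})/(k2 - k1),
    degenerating to A0 k1 t e^{-k1 t} when k1 = k2."""
    t = np.asarray(t, dtype=float)
    A = a0 * np.exp(-k1 * t)
    if np.isclose(k1, k2):
        B = a0 * k1 * t * np.exp(-k1 * t)
    else:
        B = a0 * k1 * (np.exp(-k1 * t) - np.exp(-k2 * t)) / (k2 - k1)
    return A, B


# ---------------------------------------------------------------------------
# Brute-force sensitivity oracle
# ---------------------------------------------------------------------------

def double_loop_sobol(
    f: Callable[[np.ndarray], float],
    k: int,
    i: int,
    n_outer: int = 256,
    n_inner: int = 256,
    seed: int = 0,
    total: bool = False,
) -> float:
    """Nested-loop Monte Carlo estimate of S_i (or S_Ti with ``total``).

    Directly evaluates V(E(Y|X_i))/V(Y) by conditioning: the outer loop
    fixes X_i (or X_~i for the total effect), the inner loop averages over
    the complement.  Independent of the Saltelli machinery; intended as an
    oracle at small k.
    """
    rng = np.random.default_rng(seed)

    def batch_eval(X: np.ndarray) -> np.ndarray:
        return np.array([f(x) for x in X])

    X_var = batch_eval(rng.random((4096, k)))
    VY = X_var.var(ddof=1)
    means = np.empty(n_outer)
    for j in range(n_outer):
        X = rng.random((n_inner, k))
        if total:
            fixed = rng.random(k)
            X[:, [c for c in range(k) if c != i]] = fixed[
                [c for c in range(k) if c != i]
            ]
        else:
            X[:, i] = rng.random()
        means[j] = batch_eval(X).mean()
    V_cond = means.var(ddof=1) - VY / n_inner  # debias inner-loop noise
    if total:
        return 1.0 - V_cond / VY
    return V_cond / VY


# ---------------------------------------------------------------------------
# Pseudo-experimental fold-change tables
# ---------------------------------------------------------------------------

@dataclass
class PseudoExperiment:
    """RT-PCR-style fold-change table (doses x intervals) with noise."""

    doses: list[float]
    intervals: tuple = INTERVALS
    fold_change: np.ndarray = field(default=None)  # (n_doses, 3)
    noise_sigma: float = 0.0
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d, row in zip(self.doses, self.fold_change):
            for (t0, t1), v in zip(self.intervals, row):
                rows.append({
                    "dose_nM": d, "interval": f"{t0:g}-{t1:g}h", "fold_change": v,
                })
        return pd.DataFrame(rows)


def generate_pseudo_experiment(
    readouts_per_dose: list[ReadoutSet],
    noise_sigma: float,
    seed: int,
) -> PseudoExperiment:
    """Turn model readouts into a noisy fold-change table vs the 0-dose control.

    Interval integrals are normalized by the zero-NRG (control) row and
    multiplied by lognormal(0, sigma) noise; the control row itself is
    fixed at 1 (fold changes are defined relative to it).
    """
    doses = [r.dose for r in readouts_per_dose]
    if 0.0 not in doses:
        raise ValueError("readouts must include the zero-NRG control dose")
    control = readouts_per_dose[doses.index(0.0)]
    ctrl = np.array([control.integral_0_12, control.integral_12_24,
                     control.integral_24_48])
    if np.any(ctrl <= 0):
        raise ValueError("control integrals must be positive")
    rng = np.random.default_rng(seed)
    fold = np.empty((len(doses), 3))
    for i, r in enumerate(readouts_per_dose):
        vals = np.array([r.integral_0_12, r.integral_12_24, r.integral_24_48])
        row = np.array([normalize_to_control(v, c) for v, c in zip(vals, ctrl)])
        if r.dose == 0.0:
            fold[i] = 1.0
        else:
            noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=3) if noise_sigma > 0 else 1.0
            fold[i] = row * noise
    return PseudoExperiment(
        doses=doses, fold_change=fold, noise_sigma=noise_sigma, seed=seed
    )
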