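"""Sampling designs: Latin hypercube, Sobol' sequences, Saltelli matrices.

Latin-hypercube draws and the Sobol' low-discrepancy sequence come from
``scipy.stats.qmc`` (Joe–Kuo direction numbers).  The Saltelli
A/B/A_B^i/B_A^i construction — two blocks of a 2k-dimensional Sobol'
sequence with column swaps, N(2k+2) model evaluations in total — is built
here, as required by the product-form index estimators in
:mod:`her4jakstat.gsa`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import qmc

__all__ = [
    "ParameterSpace",
    "SaltelliDesign",
    "latin_hypercube",
    "sobol_sequence",
    "scale_to_space",
    "saltelli_design",
    "default_parameter_space",
    "split_overrides",
]

_SOBOL_MAX_DIM = 21201  # scipy's Joe-Kuo table


@dataclass
class ParameterSpace:
    """Ordered box bounds over model inputs (rate constants and/or
    species initial amounts), each sampled on a linear or log10 scale."""

    entries: list[tuple[str, float, float, str]]

    def __post_init__(self) -> None:
        seen = set()
        for pid, lo, hi, scale in self.entries:
            if pid in seen:
                raise ValueError(f"duplicate entry {pid!r}")
            seen.add(pid)
            if not lo < hi:
                raise ValueError(f"{pid!r}: lower bound must be < upper bound")
            if scale not in ("linear", "log10"):
                raise ValueError(f"{pid!r}: scale must be 'linear' or 'log10'")
            if scale == "log10" and lo <= 0:
                raise ValueError(f"{pid!r}: log10 scale requires lower > 0")

    @property
    def k(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]


@dataclass
class SaltelliDesign:
    """The A, B, A_B^i, B_A^i unit-hypercube sample matrices."""

    A: np.ndarray
    B: np.ndarray
    AB: list[np.ndarray]
    BA: list[np.ndarray]
    N: int
    skip: int
    parameter_ids: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.A.shape[1]

    @property
    def n_evaluations(self) -> int:
        return self.N * (2 * self.k + 2)

    def validate(self) -> None:
        k = self.k
        assert self.A.shape == self.B.shape == (self.N, k)
        for mats, base, other in ((self.AB, self.A, self.B), (self.BA, self.B, self.A)):
            assert len(mats) == k
            for i, M in enumerate(mats):
                cols = [j for j in range(k) if j != i]
                if not (np.array_equal(M[:, cols], base[:, cols])
                        and np.array_equal(M[:, i], other[:, i])):
                    raise ValueError(f"column-swap invariant violated at column {i}")
        for M in [self.A, self.B, *self.AB, *self.BA]:
            if M.min() < 0 or M.max() >= 1:
                raise ValueError("design entries must lie in [0, 1)")

    def save(self, path: str | Path) -> None:
        """CSV matrices with a JSON sidecar describing the design."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "A.csv", self.A, delimiter=",")
        np.savetxt(path / "B.csv", self.B, delimiter=",")
        for i in range(self.k):
            np.savetxt(path / f"AB_{i}.csv", self.AB[i], delimiter=",")
            np.savetxt(path / f"BA_{i}.csv", self.BA[i], delimiter=",")
        meta = {"N": self.N, "k": self.k, "skip": self.skip,
                "parameter_ids": self.parameter_ids}
        (path / "design.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SaltelliDesign":
        path = Path(path)
        meta = json.loads((path / "design.json").read_text())
        k = meta["k"]
        load = lambda name: np.loadtxt(path / name, delimiter=",").reshape(meta["N"], k)
        design = cls(
            A=load("A.csv"), B=load("B.csv"),
            AB=[load(f"AB_{i}.csv") for i in range(k)],
            BA=[load(f"BA_{i}.csv") for i in range(k)],
            N=meta["N"], skip=meta["skip"], parameter_ids=meta["parameter_ids"],
        )
        design.validate()
        return design


def latin_hypercube(n: int, k: int, seed: int) -> np.ndarray:
    """n stratified samples in [0,1)^k: one point per marginal stratum."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    return qmc.LatinHypercube(d=k, seed=seed).random(n)


def sobol_sequence(n: int, k: int, skip: int = 0) -> np.ndarray:
    """First ``n`` points of the (unscrambled) Sobol' sequence after
    skipping ``skip``; for n = 2^m every 1-D projection is dyadically
    equidistributed."""
    if k < 1 or k > _SOBOL_MAX_DIM:
        raise ValueError(f"dimension k must be in [1, {_SOBOL_MAX_DIM}]")
    if n == 0:
        return np.empty((0, k))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        gen = qmc.Sobol(d=k, scramble=False)
        if skip:
            gen.fast_forward(skip)
        return gen.random(n)


def scale_to_space(unit: np.ndarray, space: ParameterSpace) -> np.ndarray:
    """Map unit-hypercube samples onto the parameter box."""
    unit = np.asarray(unit, dtype=float)
    if unit.ndim != 2 or unit.shape[1] != space.k:
        raise ValueError("column count must equal the space dimension")
    if unit.min() < 0 or unit.max() > 1:
        raise ValueError("unit samples must lie in [0, 1]")
    out = np.empty_like(unit)
    for j, (_, lo, hi, scale) in enumerate(space.entries):
        u = unit[:, j]
        if scale == "linear":
            out[:, j] = lo + u * (hi - lo)
        else:
            out[:, j] = 10.0 ** (np.log10(lo) + u * (np.log10(hi) - np.log10(lo)))
    return out


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def saltelli_design(
    space: ParameterSpace, N: int, skip: int | None = None
) -> SaltelliDesign:
    """Build the N(2k+2)-evaluation Saltelli design over ``space``.

    A and B are disjoint column blocks of one 2k-dimensional Sobol'
    sequence; A_B^i is A with column i replaced by B's column i (and
    symmetrically B_A^i).  ``skip`` defaults to the next power of two
    >= N (burn-in).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    k = space.k
    if skip is None:
        skip = _next_pow2(N)
    base = sobol_sequence(N, 2 * k, skip=skip)
    A, B = base[:, :k].copy(), base[:, k:].copy()
    AB, BA = [], []
    for i in range(k):
        m = A.copy()
        m[:, i] = B[:, i]
        AB.append(m)
        m = B.copy()
        m[:, i] = A[:, i]
        BA.append(m)
    design = SaltelliDesign(A, B, AB, BA, N, skip, parameter_ids=list(space.ids))
    design.validate()
    return design


def default_parameter_space(
    net,
    ids: list[str] | None = None,
    rate_fold: float = 10.0,
    init_fold: float = 2.0,
) -> ParameterSpace:
    """Default bounds around the baseline: rate constants log10-scaled over
    [baseline/rate_fold, baseline*rate_fold], initial amounts linear over
    [baseline/init_fold, baseline*init_fold].

    ``ids`` may mix rate-constant ids and species ids (initial amounts);
    by default all positive rate constants are used.
    """
    entries: list[tuple[str, float, float, str]] = []
    if ids is None:
        ids = [p for p, v in net.parameters.items() if v > 0]
    species_ids = set(net.species_ids)
    for pid in ids:
        if pid in net.parameters:
            v = net.parameters[pid]
            if v <= 0:
                raise ValueError(f"cannot bound non-positive baseline {pid!r}")
            entries.append((pid, v / rate_fold, v * rate_fold, "log10"))
        elif pid in species_ids:
            v = net.species_by_id(pid).initial_amount
            if v <= 0:
                raise ValueError(f"species {pid!r} has zero baseline amount")
            entries.append((pid, v / init_fold, v * init_fold, "linear"))
        else:
            raise KeyError(f"{pid!r} is neither a parameter nor a species")
    return ParameterSpace(entries)


def split_overrides(net, draw: dict[str, float]):
    """Split a sampled point into rate-constant and initial-amount overrides."""
    species_ids = set(net.species_ids)
    params = {k: v for k, v in draw.items() if k in net.parameters}
    inits = {k: v for k, v in draw.items() if k in species_ids and k not in params}
    leftover = set(draw) - set(params) - set(inits)
    if leftover:
        raise KeyError(f"unknown sampled ids: {sorted(leftover)}")
    return params, inits
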