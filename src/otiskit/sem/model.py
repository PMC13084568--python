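"""Observed-variable SEM specification and a lavaan-like model grammar.

A model is a pair of p x p matrices over the ordered observed variables:
``B`` (directed regression paths, zero diagonal) and ``Psi`` (symmetric
residual/exogenous (co)variances), with a list of free cells.  The implied
covariance is ``Sigma = (I - B)^-1 Psi (I - B)^-T``; exogenous variances and
covariances live in ``Psi`` like any other parameter.

Grammar (one statement per line, ``#`` comments)::

    y ~ x1 + x2     # regressions (free B cells)
    a ~~ b          # free (co)variance in Psi

Every variable's own variance is free by default; with
``saturated_exogenous=True`` (the default) all covariances among exogenous
variables (those never on the left of ``~``) are free as well, which is the
standard path-analysis treatment of correlated covariates.
"""

from __future__ import annotations

import graphlib
import re
from dataclasses import dataclass, field

import numpy as np

from ..errors import CycleDetected, DuplicatePath, UnknownVariable

__all__ = ["SEMSpec", "parse_model"]


@dataclass
class SEMSpec:
    variables: list[str]
    free_b: list[tuple[int, int]] = field(default_factory=list)   # (child, parent)
    free_psi: list[tuple[int, int]] = field(default_factory=list)  # i <= j
    b_fixed: np.ndarray | None = None
    psi_fixed: np.ndarray | None = None

    def __post_init__(self):
        p = len(self.variables)
        if self.b_fixed is None:
            self.b_fixed = np.zeros((p, p))
        if self.psi_fixed is None:
            self.psi_fixed = np.zeros((p, p))
        if not np.allclose(self.psi_fixed, self.psi_fixed.T):
            raise ValueError("fixed Psi must be symmetric")
        seen = set()
        for cell in [("B", ij) for ij in self.free_b] + [("P", ij) for ij in self.free_psi]:
            if cell in seen:
                raise DuplicatePath(f"free parameter listed twice: {cell}")
            seen.add(cell)

    # ------------------------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def n_free(self) -> int:
        return len(self.free_b) + len(self.free_psi)

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.n_free

    def index(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise UnknownVariable(name) from None

    def param_names(self) -> list[str]:
        v = self.variables
        return [f"{v[i]} ~ {v[j]}" for i, j in self.free_b] + [
            f"{v[i]} ~~ {v[j]}" for i, j in self.free_psi
        ]

    def endogenous(self) -> list[str]:
        kids = {i for i, _ in self.free_b} | {
            i for i in range(self.p) if np.any(self.b_fixed[i] != 0)
        }
        return [self.variables[i] for i in sorted(kids)]

    def exogenous(self) -> list[str]:
        endo = set(self.endogenous())
        return [v for v in self.variables if v not in endo]

    def parents(self, name: str) -> list[str]:
        i = self.index(name)
        idx = {j for (c, j) in self.free_b if c == i} | set(np.nonzero(self.b_fixed[i])[0])
        return [self.variables[j] for j in sorted(idx)]

    def check_acyclic(self) -> None:
        ts = graphlib.TopologicalSorter()
        for child, parent in self.free_b:
            if child == parent:
                raise CycleDetected(f"self-loop on {self.variables[child]}")
            ts.add(child, parent)
        for child, parent in zip(*np.nonzero(self.b_fixed)):
            ts.add(int(child), int(parent))
        try:
            ts.prepare()
        except graphlib.CycleError as exc:
            raise CycleDetected(str(exc)) from exc


_STMT = re.compile(r"^\s*([\w.]+)\s*(~~|~)\s*(.+?)\s*$")


def parse_model(
    text: str,
    variables: list[str] | None = None,
    saturated_exogenous: bool = True,
    require_recursive: bool = True,
) -> SEMSpec:
    """Parse model text into an :class:`SEMSpec`.  See module docstring."""
    regressions: list[tuple[str, str]] = []
    covariances: list[tuple[str, str]] = []
    order: list[str] = []

    def note(name: str):
        if variables is not None and name not in variables:
            raise UnknownVariable(name)
        if name not in order:
            order.append(name)

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _STMT.match(line)
        if not m:
            raise ValueError(f"cannot parse model line: {raw!r}")
        lhs, op, rhs = m.groups()
        note(lhs)
        for term in (t.strip() for t in rhs.split("+")):
            if not term:
                raise ValueError(f"empty term in: {raw!r}")
            note(term)
            if op == "~":
                if lhs == term:
                    raise CycleDetected(f"self-regression {lhs} ~ {term}")
                pair = (lhs, term)
                if pair in regressions:
                    raise DuplicatePath(f"{lhs} ~ {term}")
                regressions.append(pair)
            else:
                pair = tuple(sorted((lhs, term)))
                if pair in covariances:
                    raise DuplicatePath(f"{lhs} ~~ {term}")
                covariances.append(pair)

    names = list(variables) if variables is not None else order
    idx = {v: k for k, v in enumerate(names)}

    free_b = [(idx[child], idx[parent]) for child, parent in regressions]
    lhs_vars = {child for child, _ in regressions}
    free_cov = {(min(idx[a], idx[b]), max(idx[a], idx[b])) for a, b in covariances if a != b}
    if saturated_exogenous:
        exo = [v for v in names if v not in lhs_vars]
        for k, a in enumerate(exo):
            for b in exo[k + 1:]:
                free_cov.add((min(idx[a], idx[b]), max(idx[a], idx[b])))
    # every variance free (explicit `a ~~ a` mentions are redundant)
    free_psi = [(i, i) for i in range(len(names))] + sorted(free_cov)
    spec = SEMSpec(variables=names, free_b=free_b, free_psi=free_psi)

    if require_recursive:
        spec.check_acyclic()
    return spec
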