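"""Behavioral rule sets for the two competing hypotheses.

Both hypotheses share the movement/attachment machinery (attachment threshold
``N_crit`` on a 0-100 scale, substrate deposit ``c_amount``) and differ only in
how engrafted cells draw their lifespan ``T_life`` and proliferation delay
``T_prol``:

* **Hypothesis 1** (matched to mesenchymal stem cells): shorter-lived cells
  that proliferate preferentially where substrate is high.  Initial engrafters
  draw ``T_life ~ U[0, 36]`` and ``T_prol ~ U[33, 87]``; offspring draw
  ``T_life ~ U[0, 18]`` and ``T_prol = (33 - c_patch/c_envfactor) + n`` with
  ``n ~ U[0, 54]``.
* **Hypothesis 2** (matched to C10 alveolar epithelial cells): longer-lived
  cells that survive preferentially where substrate is high.  Initial
  engrafters draw ``T_life ~ U[0, 45]`` and ``T_prol ~ U[41, 103]``; offspring
  draw ``T_life = (c_patch/c_envfactor) + n`` with ``n ~ U[0, 45]`` and
  ``T_prol ~ U[41, 103]``.

``c_envfactor`` defaults to 1.9.  Draws are integer-valued (counters advance in
whole time steps) and the environment-coupled formulas are rounded to the
nearest integer and floored at 1, so that the equality-style counters can
always fire.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "UniformSpec",
    "EnvCoupledSpec",
    "RuleSet",
    "hypothesis1",
    "hypothesis2",
    "draw_engraftment_params",
]


@dataclass(frozen=True)
class UniformSpec:
    """Integer uniform draw on the inclusive interval [lo, hi]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ValueError(f"invalid interval [{self.lo}, {self.hi}]")

    def draw(self, rng: np.random.Generator, c_patch: float = 0.0,
             c_envfactor: float = 1.9) -> int:
        lo = int(np.ceil(self.lo))
        hi = int(np.floor(self.hi))
        return int(rng.integers(lo, hi + 1))

    def scaled(self, factor: float) -> "UniformSpec":
        return UniformSpec(self.lo * factor, self.hi * factor)


@dataclass(frozen=True)
class EnvCoupledSpec:
    """Environment-coupled draw: ``base + sign * c_patch/c_envfactor + n``.

    ``n`` is an integer uniform draw on [n_lo, n_hi]; the total is rounded to
    the nearest integer and floored at 1.
    """

    base: float
    sign: int  # +1: value grows with substrate; -1: value shrinks
    n_lo: float
    n_hi: float

    def draw(self, rng: np.random.Generator, c_patch: float = 0.0,
             c_envfactor: float = 1.9) -> int:
        n = int(rng.integers(int(np.ceil(self.n_lo)), int(np.floor(self.n_hi)) + 1))
        value = self.base + self.sign * (c_patch / c_envfactor) + n
        return max(1, int(round(value)))

    def scaled(self, factor: float) -> "EnvCoupledSpec":
        return EnvCoupledSpec(self.base * factor, self.sign,
                              self.n_lo * factor, self.n_hi * factor)


@dataclass(frozen=True)
class RuleSet:
    """Every parameter distinguishing the two behavioral hypotheses."""

    name: str
    N_crit: float = 5.0
    c_envfactor: float = 1.9
    c_amount: float = 1.0
    initial_T_life: UniformSpec = UniformSpec(0, 36)
    initial_T_prol: UniformSpec = UniformSpec(33, 87)
    offspring_T_life: UniformSpec | EnvCoupledSpec = UniformSpec(0, 18)
    offspring_T_prol: UniformSpec | EnvCoupledSpec = EnvCoupledSpec(33, -1, 0, 54)
    max_target_neighbors: int = 6

    def __post_init__(self) -> None:
        n_env = sum(
            isinstance(s, EnvCoupledSpec)
            for s in (self.offspring_T_life, self.offspring_T_prol)
        )
        if n_env != 1:
            raise ValueError(
                "exactly one of offspring_T_life / offspring_T_prol must be "
                "environment-coupled"
            )

    # convenience views used by tests and the sensitivity protocol
    @property
    def initial_T_life_interval(self) -> tuple[float, float]:
        return (self.initial_T_life.lo, self.initial_T_life.hi)

    @property
    def initial_T_prol_interval(self) -> tuple[float, float]:
        return (self.initial_T_prol.lo, self.initial_T_prol.hi)

    def replace(self, **kwargs) -> "RuleSet":
        return dataclasses.replace(self, **kwargs)

    def perturbed(self, parameter: str, factor: float) -> "RuleSet":
        """Return a copy with one named parameter scaled by ``factor``.

        ``parameter`` is one of ``N_crit``, ``c_amount``, ``c_envfactor``,
        ``T_life``, ``T_prol``.  For the interval-valued lifespan and
        proliferation parameters, every defining endpoint (and the additive
        base of an environment-coupled formula) is scaled.
        """
        if parameter in ("N_crit", "c_amount", "c_envfactor"):
            return self.replace(**{parameter: getattr(self, parameter) * factor})
        if parameter == "T_life":
            return self.replace(
                initial_T_life=self.initial_T_life.scaled(factor),
                offspring_T_life=self.offspring_T_life.scaled(factor),
            )
        if parameter == "T_prol":
            return self.replace(
                initial_T_prol=self.initial_T_prol.scaled(factor),
                offspring_T_prol=self.offspring_T_prol.scaled(factor),
            )
        raise ValueError(f"unknown parameter {parameter!r}")


def hypothesis1() -> RuleSet:
    """Rule set for Hypothesis 1: shorter-lived cells, substrate-favored
    proliferation (offspring ``T_prol`` decreases with local substrate)."""
    return RuleSet(
        name="hypothesis1",
        initial_T_life=UniformSpec(0, 36),
        initial_T_prol=UniformSpec(33, 87),
        offspring_T_life=UniformSpec(0, 18),
        offspring_T_prol=EnvCoupledSpec(base=33, sign=-1, n_lo=0, n_hi=54),
    )


def hypothesis2() -> RuleSet:
    """Rule set for Hypothesis 2: longer-lived cells, substrate-favored
    survival (offspring ``T_life`` increases with local substrate)."""
    return RuleSet(
        name="hypothesis2",
        initial_T_life=UniformSpec(0, 45),
        initial_T_prol=UniformSpec(41, 103),
        offspring_T_life=EnvCoupledSpec(base=0, sign=+1, n_lo=0, n_hi=45),
        offspring_T_prol=UniformSpec(41, 103),
    )


def draw_engraftment_params(
    rules: RuleSet,
    c_patch: float,
    is_offspring: bool,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw ``(T_life, T_prol)`` for a newly engrafted cell.

    Initial engrafters draw both values from their uniform intervals;
    offspring use the hypothesis's environment-coupled formula for one of the
    two, evaluated at the local substrate concentration ``c_patch``.
    """
    if c_patch < 0:
        raise ValueError("c_patch must be non-negative")
    if is_offspring:
        t_life = rules.offspring_T_life.draw(rng, c_patch, rules.c_envfactor)
        t_prol = rules.offspring_T_prol.draw(rng, c_patch, rules.c_envfactor)
    else:
        t_life = rules.initial_T_life.draw(rng, c_patch, rules.c_envfactor)
        t_prol = rules.initial_T_prol.draw(rng, c_patch, rules.c_envfactor)
    return t_life, t_prol
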