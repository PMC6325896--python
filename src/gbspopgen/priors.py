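"""Prior distributions with bounds and inter-parameter constraints.

Supports Uniform(min, max) and Normal(mean, sd) truncated to
[min, max] by rejection, plus order constraints between parameters
expressed as strings like ``"t3 > t2"`` or ``"t2 >= t1"``.  Joint draws
violating a constraint are rejected and redrawn.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Uniform:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("Uniform requires lo < hi")

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lo, self.hi)


@dataclass
class Normal:
    """Normal(mean, sd), truncated to [lo, hi] by rejection.

    Infinite bounds give the untruncated normal.
    """

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("Normal requires sd > 0")
        if not self.lo < self.hi:
            raise ValueError("Normal requires lo < hi")

    def draw(self, rng: np.random.Generator) -> float:
        for _ in range(100000):
            x = float(rng.normal(self.mean, self.sd))
            if self.lo <= x <= self.hi:
                return x
        raise RuntimeError("truncated normal rejection failed")

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lo, self.hi)


_CONSTRAINT_RE = re.compile(
    r"^\s*(\w+)\s*(>=|<=|>|<)\s*(\w+)\s*$"
)

_OPS = {
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
}


@dataclass
class PriorSet:
    """Named per-parameter priors plus order constraints."""

    params: dict[str, Uniform | Normal]
    constraints: list[str] = field(default_factory=list)
    max_rejections: int = 10000

    def __post_init__(self) -> None:
        for c in self.constraints:
            a, _, b = self._parse(c)
            for name in (a, b):
                if name not in self.params:
                    raise ValueError(
                        f"constraint {c!r} references unknown parameter "
                        f"{name!r}"
                    )

    @staticmethod
    def _parse(constraint: str) -> tuple[str, str, str]:
        m = _CONSTRAINT_RE.match(constraint)
        if not m:
            raise ValueError(f"cannot parse constraint {constraint!r}")
        return m.group(1), m.group(2), m.group(3)

    def satisfied(self, draw: dict[str, float]) -> bool:
        for c in self.constraints:
            a, op, b = self._parse(c)
            if not _OPS[op](draw[a], draw[b]):
                return False
        return True

    def sample(self, rng: np.random.Generator | int) -> dict[str, float]:
        """One joint draw satisfying every constraint (rejection)."""
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        for _ in range(self.max_rejections):
            draw = {k: d.draw(rng) for k, d in self.params.items()}
            if self.satisfied(draw):
                return draw
        raise RuntimeError(
            f"constraints unsatisfied after {self.max_rejections} draws"
        )

    def sample_many(self, n: int,
                    rng: np.random.Generator | int) -> list[dict[str, float]]:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        return [self.sample(rng) for _ in range(n)]

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {k: d.bounds for k, d in self.params.items()}
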