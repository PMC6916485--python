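"""Raw-scale linear equations exported from latent-factor fits.

A :class:`LinearEquation` is the portable, human-readable form of a fitted
model: an intercept, continuous terms applied on a centered/scaled axis
(``coef * (x - center) / scale``), and effect-coded categorical factors
whose per-level offsets sum to (approximately) zero.  It is the exchange
format between the regression engine, the synthetic-data generator and the
Monte Carlo profiler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = ["ContinuousTerm", "CategoricalTerm", "LinearEquation"]


@dataclass(frozen=True)
class ContinuousTerm:
    """One continuous predictor: contributes ``coefficient * (x - center) / scale``."""

    name: str
    coefficient: float
    center: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale == 0:
            raise ValueError(f"term {self.name!r}: scale must be nonzero")


@dataclass(frozen=True)
class CategoricalTerm:
    """One effect-coded factor: contributes the offset of the active level.

    Offsets are expected to sum to ~0 across levels; published equations
    carry rounded coefficients so a loose tolerance is applied and the
    discrepancy is retained verbatim rather than silently recentered.
    """

    name: str
    offsets: Mapping[str, float]
    _SUM_TOL = 1.0  # printed-coefficient rounding can leave a residual

    def __post_init__(self) -> None:
        if not self.offsets:
            raise ValueError(f"factor {self.name!r}: no levels")
        total = float(sum(self.offsets.values()))
        if abs(total) > self._SUM_TOL:
            raise ValueError(
                f"factor {self.name!r}: level offsets sum to {total:.3f}, "
                "expected ~0 under effect coding"
            )

    def offset_for(self, level: Any) -> float:
        key = str(level)
        if key not in self.offsets:
            raise KeyError(
                f"factor {self.name!r}: unknown level {key!r} "
                f"(known: {sorted(self.offsets)})"
            )
        return float(self.offsets[key])


@dataclass
class LinearEquation:
    """Affine model of one response on raw-scale inputs.

    Evaluation::

        intercept
        + sum_j coef_j * (x_j - center_j) / scale_j        (continuous terms)
        + sum_F offset_F[level of F]                        (categorical terms)
    """

    response: str
    intercept: float
    continuous: list[ContinuousTerm] = field(default_factory=list)
    categorical: list[CategoricalTerm] = field(default_factory=list)

    @property
    def input_names(self) -> list[str]:
        return [t.name for t in self.continuous] + [t.name for t in self.categorical]

    def evaluate(self, inputs: Mapping[str, Any]):
        """Evaluate at a mapping of input name -> scalar or array.

        Scalars and equal-length arrays may be mixed; a missing input or an
        unknown categorical level raises.
        """
        total = np.asarray(self.intercept, dtype=float)
        for term in self.continuous:
            if term.name not in inputs:
                raise KeyError(f"missing input {term.name!r} for {self.response}")
            x = np.asarray(inputs[term.name], dtype=float)
            total = total + term.coefficient * (x - term.center) / term.scale
        for term in self.categorical:
            if term.name not in inputs:
                raise KeyError(f"missing input {term.name!r} for {self.response}")
            levels = np.asarray(inputs[term.name])
            if levels.ndim == 0:
                total = total + term.offset_for(levels.item())
            else:
                offs = np.array([term.offset_for(v) for v in levels])
                total = total + offs
        if total.ndim == 0:
            return float(total)
        return total

    def __call__(self, inputs: Mapping[str, Any]):
        return self.evaluate(inputs)

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "intercept": self.intercept,
            "continuous": [
                {
                    "name": t.name,
                    "coefficient": t.coefficient,
                    "center": t.center,
                    "scale": t.scale,
                }
                for t in self.continuous
            ],
            "categorical": [
                {"name": t.name, "offsets": dict(t.offsets)} for t in self.categorical
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "LinearEquation":
        return cls(
            response=d["response"],
            intercept=float(d["intercept"]),
            continuous=[
                ContinuousTerm(
                    t["name"],
                    float(t["coefficient"]),
                    float(t.get("center", 0.0)),
                    float(t.get("scale", 1.0)),
                )
                for t in d.get("continuous", [])
            ],
            categorical=[
                CategoricalTerm(t["name"], {k: float(v) for k, v in t["offsets"].items()})
                for t in d.get("categorical", [])
            ],
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "LinearEquation":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
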