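"""Sequencing-budget model and coverage-versus-sample-size optimization.

Total cost of an eQTL experiment with N samples at target coverage b
(million reads/sample):

    B = N*e + N*g + N*a + N*b*c/d + f

with a = library prep $/sample, c = $/lane, d = million reads/lane,
e = extraction $/sample, g = genotyping $/sample, f = fixed costs. Under a
fixed budget the affordable N falls as b rises; the effective sample size
Neff = R2adj(b * m) * N (m = mapping rate) trades measurement accuracy
against cohort size and is maximized over a coverage grid.

Money arithmetic is exact (rational) internally; displayed dollars are
floored.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .power import effective_n
from .quantify import CoverageResponseCurve


def _frac(x) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(str(x))


@dataclasses.dataclass(frozen=True)
class CostModel:
    """Per-sample, per-lane and fixed costs plus the total budget, in dollars."""

    library_prep: float = 87.0   # a
    lane_cost: float = 1790.0    # c
    reads_per_lane: float = 300.0  # d, million reads
    extraction: float = 0.0      # e
    genotyping: float = 53.0     # g_cost
    fixed: float = 0.0           # f
    budget: float = 300_000.0    # B

    def __post_init__(self) -> None:
        for name in ("library_prep", "lane_cost", "reads_per_lane", "extraction",
                     "genotyping", "fixed", "budget"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.reads_per_lane == 0:
            raise ParameterError("reads_per_lane must be positive")

    def per_sample_cost(self, b: float) -> Fraction:
        """e + g + a + b*c/d, exact."""
        return (
            _frac(self.extraction)
            + _frac(self.genotyping)
            + _frac(self.library_prep)
            + _frac(b) * _frac(self.lane_cost) / _frac(self.reads_per_lane)
        )


@dataclasses.dataclass(frozen=True)
class MappingModel:
    """Fraction of purchased reads expected to map to genes."""

    mapping_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mapping_rate <= 1.0:
            raise ParameterError("mapping rate must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class DesignPoint:
    """One (coverage, N) evaluation on the budget frontier."""

    b: float
    n: int
    expected_coverage: float
    r2_adj: float
    n_eff: float
    total_cost: float


def total_cost(cost: CostModel, n: int, b: float) -> float:
    """Exact experiment cost in dollars for N samples at target coverage b."""
    if n < 0 or b < 0:
        raise ParameterError("N and coverage must be non-negative")
    return float(_frac(n) * cost.per_sample_cost(b) + _frac(cost.fixed))


def floor_dollars(x: float) -> int:
    return int(math.floor(x + 1e-9))


def samples_affordable(cost: CostModel, b: float) -> int:
    """N = floor((B - f) / (e + g + a + b*c/d)); 0 with a warning if B < f."""
    if b < 0:
        raise ParameterError("coverage must be non-negative")
    per = cost.per_sample_cost(b)
    if per <= 0:
        raise ParameterError("per-sample cost must be positive")
    budget = _frac(cost.budget) - _frac(cost.fixed)
    if budget < 0:
        warnings.warn("budget is below fixed costs; no samples affordable", stacklevel=2)
        return 0
    return int(budget / per)  # Fraction // is exact floor for non-negative values


def effective_curve(
    cost: CostModel,
    curve: CoverageResponseCurve,
    mapping: MappingModel | float = 1.0,
    b_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Budget frontier: for each target coverage, N affordable, R2adj and Neff.

    R2adj is the coverage-response curve evaluated at the expected coverage
    b * mapping_rate, clamped to [0, 1].
    """
    m = mapping.mapping_rate if isinstance(mapping, MappingModel) else float(mapping)
    if not 0.0 < m <= 1.0:
        raise ParameterError("mapping rate must lie in (0, 1]")
    if b_grid is None:
        b_grid = default_grid()
    b_grid = np.asarray(list(b_grid), dtype=float)
    if b_grid.size == 0:
        raise ParameterError("coverage grid must be non-empty")
    if np.any(b_grid <= 0) or np.any(np.diff(b_grid) <= 0):
        raise ParameterError("coverage grid must be positive and strictly ascending")
    rows = []
    for b in b_grid:
        n = samples_affordable(cost, b)
        r2 = float(curve.predict(b * m))
        rows.append(
            {
                "b": float(b),
                "n": n,
                "expected_coverage": float(b * m),
                "r2_adj": r2,
                "n_eff": effective_n(n, r2),
                "total_cost": total_cost(cost, n, b),
            }
        )
    return pd.DataFrame(rows)


def default_grid() -> np.ndarray:
    """Target coverages from 1 to 60 million reads/sample in 0.5 steps."""
    return np.round(np.arange(1.0, 60.0 + 0.25, 0.5), 3)


def optimize_coverage(points: pd.DataFrame) -> DesignPoint:
    """Argmax of Neff over the frontier; ties break toward lower coverage."""
    if len(points) == 0:
        raise ParameterError("no design points to optimize over")
    p = points.sort_values("b", kind="stable").reset_index(drop=True)
    row = p.iloc[int(np.argmax(p["n_eff"].to_numpy()))]
    return DesignPoint(
        b=float(row["b"]),
        n=int(row["n"]),
        expected_coverage=float(row["expected_coverage"]),
        r2_adj=float(row["r2_adj"]),
        n_eff=float(row["n_eff"]),
        total_cost=float(row["total_cost"]),
    )


def cost_to_match(
    n_eff_target: float,
    cost: CostModel,
    b_ref: float,
    r2_ref: float = 1.0,
    comparison_budget: float | None = None,
) -> dict:
    """Cost of reaching a given effective sample size at a reference coverage.

    N_ref = ceil(n_eff_target / r2_ref); returns the exact cost of sequencing
    N_ref samples at b_ref and, when a comparison budget is given, that
    budget as a fraction of the matched cost.
    """
    if r2_ref <= 0:
        raise ParameterError("r2_ref must be positive")
    n_ref = int(math.ceil(n_eff_target / r2_ref - 1e-9))
    c = total_cost(cost, n_ref, b_ref)
    out = {"n_ref": n_ref, "cost": c}
    if comparison_budget is not None:
        out["cost_ratio"] = comparison_budget / c
    return out


def plot_design_curves(
    frontiers: dict[str, pd.DataFrame],
    path: str,
    title: str = "Effective sample size under a fixed budget",
) -> None:
    """Neff vs target coverage for one or more cost/mapping scenarios (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, df in frontiers.items():
        ax.plot(df["b"], df["n_eff"], label=label)
    ax.set_xlabel("target coverage (million reads/sample)")
    ax.set_ylabel("effective sample size")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
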