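"""Synthetic feature tables with known PE structure.

Each policy pins the metric value by construction, so generated tables
serve as exact test inputs for everything downstream:

* ``proportional`` — p_i = C·a_i: corrected PE_p = 1;
* ``fixed`` — p_i = C_p: corrected PE_f = 1 (requires C_p <= min a_i);
* ``perfectly_unequal`` — one feature holds all protection: corrected
  PE_p = PE_f = 0;
* ``random`` — p_i = a_i·U_i with U_i ~ Uniform(0, 1): PE strictly between
  0 and 1 almost surely.

Areas come from the same gamma/lognormal generator the simulations use.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field

from .core import FeatureTable
from .simulate import AreaDistribution, generate_areas

__all__ = ["PolicySpec", "make_table", "write_fixture"]

Policy = Literal["proportional", "fixed", "perfectly_unequal", "random"]


class PolicySpec(BaseModel):
    """Recipe for one synthetic table: policy, size, area distribution, seed."""

    policy: Policy
    n: int = Field(default=10, ge=2)
    mean_area: float = Field(default=1000.0, gt=0)
    cv: float = Field(default=0.5, ge=0)
    proportion: float = Field(default=0.10, gt=0, le=1, description="C for the proportional policy")
    amount: float = Field(default=100.0, gt=0, description="C_p for the fixed policy")
    seed: int = 0
    distribution: AreaDistribution = "gamma"
    clamp: bool = False


def make_table(spec: PolicySpec) -> FeatureTable:
    """Generate a feature table whose PE is pinned by the chosen policy."""
    rng = np.random.default_rng(spec.seed)
    areas = generate_areas(spec.n, spec.mean_area, spec.cv, rng, spec.distribution)
    if spec.policy == "proportional":
        protected = spec.proportion * areas
    elif spec.policy == "fixed":
        if spec.amount > areas.min() and not spec.clamp:
            raise ValueError(
                f"fixed amount {spec.amount:g} exceeds the smallest area "
                f"{areas.min():g}; enable clamp or lower the amount"
            )
        protected = np.minimum(np.full_like(areas, spec.amount), areas)
    elif spec.policy == "perfectly_unequal":
        protected = np.zeros_like(areas)
        protected[0] = 0.5 * areas[0]
    elif spec.policy == "random":
        protected = areas * rng.uniform(0.0, 1.0, size=spec.n)
    else:  # pragma: no cover - pydantic rejects unknown policies
        raise ValueError(f"unknown policy {spec.policy!r}")
    return FeatureTable.from_arrays(areas, protected)


def write_fixture(spec: PolicySpec, path: str | Path) -> Path:
    """Write a generated table as CSV in the dialect ``read_feature_table`` reads."""
    from .report import write_feature_table

    path = Path(path)
    write_feature_table(make_table(spec), path)
    return path
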