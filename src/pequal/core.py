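"""Protection Equality (PE) metrics.

PE measures how evenly protection is spread across a set of conservation
features (ecoregions, habitats, species ranges).  Each feature *i* has a
total area ``a_i`` inside the region of interest and a protected area
``p_i``.  Protection levels — either the absolute amounts ``p_i``
(fixed-area variant, PE_f) or the fractions ``p_i / a_i`` (proportional
variant, PE_p) — are ranked ascending and accumulated into a Lorenz-style
curve; PE is the area under that curve divided by the area under the
perfect-equality chord, so PE = 1 means every feature is protected equally
and PE = 1 - G where G is the Gini coefficient of the protection levels.

Because the discrete Lorenz curve of a maximally unequal allocation still
encloses a triangle of area 1/(2N), raw PE is bounded below by 1/N rather
than 0.  The small-N correction ``PE_c = (PE - 1/N) * N/(N-1)`` rescales it
so that perfect inequality maps to 0 for every N >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Feature",
    "FeatureTable",
    "LorenzCurve",
    "PEResult",
    "PEDomainError",
    "ValidationError",
    "ranked_values",
    "lorenz_curve",
    "pe_fixed",
    "pe_proportional",
    "correct_pe",
    "pe_from_curve",
]

Variant = Literal["proportional", "fixed"]


class PEDomainError(ValueError):
    """The requested PE quantity is mathematically undefined for this input."""


class ValidationError(ValueError):
    """A feature table violates the a_i/p_i constraints."""


@dataclass(frozen=True)
class Feature:
    """One conservation feature: identifier, total area a_i, protected area p_i.

    Areas are in whatever consistent unit the caller chose (km², ha, ...);
    PE itself is dimensionless.
    """

    id: str
    area: float
    protected: float


@dataclass(frozen=True)
class PEResult:
    """A single PE evaluation.

    ``raw`` is U/(U+V) from the Lorenz construction, in [1/n, 1];
    ``corrected`` is the small-N rescaling (raw - 1/n) * n/(n-1), in [0, 1].
    """

    variant: Variant
    raw: float
    corrected: float
    n: int


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative-protection curve: points (i/N, y_i) for i = 1..N.

    ``y`` accumulates the ascending-ranked protection values (absolute
    areas for the fixed variant, fractions for proportional).  The curve is
    implicitly anchored at the origin; the perfect-equality chord runs from
    (0, 0) to (1, y_N).
    """

    x: np.ndarray
    y: np.ndarray
    variant: Variant

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1 or x.size == 0:
            raise ValueError("x and y must be equal-length 1-D sequences")
        if np.any(np.diff(y) < 0):
            raise ValueError("cumulative protection y must be non-decreasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    def standardized(self) -> np.ndarray:
        """y rescaled so the curve ends at (1, 1) — the scale used for plotting."""
        total = self.y[-1]
        if total <= 0:
            raise PEDomainError("cannot standardize a curve with zero total protection")
        return self.y / total


class FeatureTable:
    """An ordered collection of conservation features; the input to all metrics.

    Parameters
    ----------
    features
        Iterable of :class:`Feature`, or (id, area, protected) triples.
    clamp
        How to treat ``protected > area`` (a common GIS-overlap artifact):
        ``False`` (default) rejects with :class:`ValidationError`; ``True``
        sets p_i := a_i and records the affected ids in ``clamped_ids``.

    Negative areas or protection are always rejected; ``protected == 0`` is
    allowed (real networks contain entirely unprotected features).
    """

    def __init__(self, features: Iterable[Feature | tuple], *, clamp: bool = False):
        feats: list[Feature] = []
        clamped: list[str] = []
        for f in features:
            if not isinstance(f, Feature):
                f = Feature(str(f[0]), float(f[1]), float(f[2]))
            if f.area < 0:
                raise ValidationError(f"feature {f.id!r}: negative area {f.area}")
            if f.protected < 0:
                raise ValidationError(
                    f"feature {f.id!r}: negative protected area {f.protected}"
                )
            if f.protected > f.area:
                if clamp:
                    clamped.append(f.id)
                    f = Feature(f.id, f.area, f.area)
                else:
                    raise ValidationError(
                        f"feature {f.id!r}: protected {f.protected} exceeds area "
                        f"{f.area} (pass clamp=True to truncate)"
                    )
            feats.append(f)
        if not feats:
            raise ValidationError("a feature table needs at least one feature")
        self.features: tuple[Feature, ...] = tuple(feats)
        self.clamped_ids: tuple[str, ...] = tuple(clamped)

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def areas(self) -> np.ndarray:
        return np.array([f.area for f in self.features], dtype=float)

    @property
    def protected(self) -> np.ndarray:
        return np.array([f.protected for f in self.features], dtype=float)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.features)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def total_protected(self) -> float:
        return float(self.protected.sum())

    @classmethod
    def from_arrays(
        cls,
        areas: Sequence[float],
        protected: Sequence[float],
        ids: Sequence[str] | None = None,
        *,
        clamp: bool = False,
    ) -> "FeatureTable":
        areas = np.asarray(areas, dtype=float)
        prot = np.asarray(protected, dtype=float)
        if areas.shape != prot.shape:
            raise ValidationError("areas and protected must have the same length")
        if ids is None:
            ids = [f"f{i + 1}" for i in range(areas.size)]
        return cls(zip(ids, areas, prot), clamp=clamp)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return (
            f"FeatureTable(n={self.n}, total_area={self.total_area:g}, "
            f"total_protected={self.total_protected:g})"
        )


def ranked_values(table: FeatureTable, variant: Variant) -> np.ndarray:
    """Protection values of ``table`` under ``variant``, sorted ascending.

    Fixed variant: the absolute protected areas p_i.  Proportional variant:
    the protected fractions p_i / a_i (every area must be positive).  The
    sort is stable, so ties keep their input order — PE depends only on the
    sorted multiset, but the curve output is reproducible.
    """
    if variant == "fixed":
        values = table.protected
    elif variant == "proportional":
        areas = table.areas
        zero = np.nonzero(areas == 0)[0]
        if zero.size:
            bad = table.ids[zero[0]]
            raise PEDomainError(
                f"feature {bad!r} has zero area; proportional PE is undefined"
            )
        values = table.protected / areas
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return values[np.argsort(values, kind="stable")]


def lorenz_curve(table: FeatureTable, variant: Variant) -> LorenzCurve:
    """Cumulative-protection (Lorenz-style) curve of ``table``.

    x_i = i/N and y_i = sum of the i smallest protection values.
    """
    values = ranked_values(table, variant)
    n = values.size
    return LorenzCurve(
        x=np.arange(1, n + 1) / n, y=np.cumsum(values), variant=variant
    )


def _pe_raw(values: np.ndarray) -> float:
    """Closed-form raw PE on ascending-ranked protection values.

    PE = U/(U+V) with U the trapezoid area under the cumulative curve
    anchored at the origin and U+V = y_N / 2 the triangle under the
    equality chord; algebraically

        PE = [ (1/N) * ( Σv/2 + Σ_{i=1}^{N-1} v_(i) (N-i) ) ] / ( Σv/2 ).
    """
    n = values.size
    total = float(values.sum())
    if total <= 0:
        raise PEDomainError("no protection in table: PE is undefined (0/0)")
    weights = n - np.arange(1, n + 1, dtype=float)  # N-i, last weight 0
    # single division keeps the perfect-inequality floor exactly at 1/N
    return (0.5 * total + float(values @ weights)) / (n * 0.5 * total)


def correct_pe(raw: float, n: int) -> float:
    """Small-N correction PE_c = (PE - 1/N) * N/(N-1).

    Maps the perfect-inequality floor 1/N to 0 while leaving PE = 1 fixed;
    converges to the raw value as N grows.  Undefined at n < 2.
    """
    if n < 2:
        raise PEDomainError("corrected PE requires at least 2 features")
    corrected = (raw - 1.0 / n) * (n / (n - 1.0))
    # raw >= 1/N for any valid table, so no clamping is ever needed
    assert corrected >= -1e-9, f"corrected PE {corrected} below 0: raw < 1/N?"
    return corrected


def _evaluate(table: FeatureTable, variant: Variant) -> PEResult:
    values = ranked_values(table, variant)
    raw = _pe_raw(values)
    if table.n < 2:
        raise PEDomainError(
            "corrected PE is undefined for a single feature (division by N-1=0)"
        )
    return PEResult(
        variant=variant, raw=raw, corrected=correct_pe(raw, table.n), n=table.n
    )


def pe_fixed(table: FeatureTable) -> PEResult:
    """Fixed-area Protection Equality: equality of the absolute amounts p_i."""
    return _evaluate(table, "fixed")


def pe_proportional(table: FeatureTable) -> PEResult:
    """Proportional Protection Equality: equality of the fractions p_i/a_i."""
    return _evaluate(table, "proportional")


def pe_from_curve(curve: LorenzCurve) -> float:
    """Raw PE by trapezoid geometry on a cumulative-protection curve.

    Integrates the curve (anchored at the origin) with the trapezoid rule
    and divides by the triangle area under the equality chord.  Agrees with
    the closed forms to ~1e-12 relative — the geometric cross-check of the
    algebra.
    """
    y_n = float(curve.y[-1])
    if y_n <= 0:
        raise PEDomainError("no protection in curve: PE is undefined (0/0)")
    x = np.concatenate(([0.0], curve.x))
    y = np.concatenate(([0.0], curve.y))
    u = float(np.trapezoid(y, x))
    u_plus_v = 0.5 * float(curve.x[-1]) * y_n
    return u / u_plus_v
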