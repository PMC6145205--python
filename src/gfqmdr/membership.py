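"""Ordinal discretization of a quantitative trait and fuzzy membership functions.

A quantitative trait is divided into ``J`` ordered levels (for ``J=3``:
low / average / high).  Two linear membership families are defined on the
level midpoints ``P_1..P_J``:

* the *traditional* family maps a trait value to a degree of belonging in
  ``[0, 1]`` (triangular around each midpoint, clamped to 1 beyond the
  outermost midpoints);
* the *extended* family widens the range to ``[-1, 1]`` so that trait
  values far from a level count *against* that level.  This is the
  ingredient that lets a multifactor classifier distinguish two candidate
  marker sets whose traditional fuzzy accuracies coincide.

For three levels with midpoints ``P_1 < P_2 < P_3`` the extended low-level
function is 1 below ``P_1``, falls linearly through 0 at ``P_2`` and -1 at
``P_3``, and stays at -1 above; the high level mirrors it; the middle level
is the unclamped tent ``(x-P_1)/(P_2-P_1)`` for ``x <= P_2`` and
``(P_3-x)/(P_3-P_2)`` above.  The middle level is deliberately not clamped:
with equal-width intervals its infimum on the observed trait range is -0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "IntervalScheme",
    "build_equal_length_scheme",
    "build_deviation_scheme",
    "mu_traditional",
    "mu_extended",
    "membership_matrix",
    "assign_crisp_category",
]


@dataclass(frozen=True)
class IntervalScheme:
    """Partition of a trait range into ``J`` ordered intervals.

    Attributes
    ----------
    J : int
        Number of ordinal levels (>= 2).
    borders : ndarray, shape (J+1,)
        Strictly increasing interval borders; ``borders[0]`` and
        ``borders[J]`` are the observed trait minimum and maximum.
    midpoints : ndarray, shape (J,)
        Midpoint ``P_j`` of each interval,
        ``P_j = (borders[j-1] + borders[j]) / 2``.
    """

    J: int
    borders: NDArray[np.float64]
    midpoints: NDArray[np.float64] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        borders = np.asarray(self.borders, dtype=float)
        if self.J < 2:
            raise ValueError(f"need at least 2 levels, got J={self.J}")
        if borders.shape != (self.J + 1,):
            raise ValueError("borders must have length J+1")
        if not np.all(np.diff(borders) > 0):
            raise ValueError("borders must be strictly increasing")
        mids = (borders[:-1] + borders[1:]) / 2.0
        if self.midpoints is not None:
            given = np.asarray(self.midpoints, dtype=float)
            if not np.allclose(given, mids):
                raise ValueError("midpoints inconsistent with borders")
        object.__setattr__(self, "borders", borders)
        object.__setattr__(self, "midpoints", mids)

    def to_dict(self) -> dict:
        """JSON-serializable summary for run logs."""
        return {
            "J": int(self.J),
            "borders": [float(b) for b in self.borders],
            "midpoints": [float(p) for p in self.midpoints],
        }


def build_equal_length_scheme(trait: ArrayLike, J: int = 3) -> IntervalScheme:
    """Divide the observed trait range into ``J`` equal-length intervals.

    Raises
    ------
    ValueError
        If the trait is constant (degenerate range) or ``J < 2``.
    """
    x = np.asarray(trait, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if not hi > lo:
        raise ValueError("trait range is degenerate (constant trait)")
    borders = np.linspace(lo, hi, J + 1)
    return IntervalScheme(J=J, borders=borders)


def build_deviation_scheme(trait: ArrayLike) -> IntervalScheme:
    """Three-level scheme with interior borders at mean +/- sd/2.

    Values below ``mean - sd/2`` fall in the low level, values above
    ``mean + sd/2`` in the high level.  Outer borders sit at the observed
    minimum and maximum.

    Raises
    ------
    ValueError
        If the sd is zero, or an interior border falls outside the observed
        range (which would leave an empty outer category).
    """
    x = np.asarray(trait, dtype=float)
    mu, sd = float(np.mean(x)), float(np.std(x))
    if sd == 0.0:
        raise ValueError("trait standard deviation is zero")
    b1, b2 = mu - sd / 2.0, mu + sd / 2.0
    lo, hi = float(np.min(x)), float(np.max(x))
    if b1 <= lo or b2 >= hi:
        raise ValueError(
            "mean +/- sd/2 borders fall outside the observed trait range; "
            "an outer category would be empty"
        )
    return IntervalScheme(J=3, borders=np.array([lo, b1, b2, hi]))


def _level_arrays(scheme: IntervalScheme, j: int):
    """Midpoint of level ``j`` (1-based) and the slopes to its neighbours."""
    if not 1 <= j <= scheme.J:
        raise ValueError(f"level index {j} outside 1..{scheme.J}")
    P = scheme.midpoints
    left = P[j - 2] if j >= 2 else None
    right = P[j] if j <= scheme.J - 1 else None
    return P[j - 1], left, right


def mu_traditional(scheme: IntervalScheme, j: int, x: ArrayLike) -> NDArray[np.float64]:
    """Traditional membership of trait value(s) ``x`` in level ``j``, in [0, 1].

    Interior levels are triangular with vertices at the adjacent midpoints;
    the lowest (highest) level clamps to 1 below (above) its own midpoint.
    """
    Pj, left, right = _level_arrays(scheme, j)
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if left is None:
        out = np.where(x <= Pj, 1.0, out)
    else:
        ramp = (x - left) / (Pj - left)
        out = np.where((x > left) & (x <= Pj), ramp, out)
    if right is None:
        out = np.where(x > Pj, 1.0, out)
    else:
        ramp = (right - x) / (right - Pj)
        out = np.where((x > Pj) & (x < right), ramp, out)
    return out


def mu_extended(scheme: IntervalScheme, j: int, x: ArrayLike) -> NDArray[np.float64]:
    """Extended membership of ``x`` in level ``j``, range [-1, 1] for edge levels.

    Edge levels continue the traditional linear slope past the adjacent
    midpoint and clamp at -1 one further midpoint away; interior levels keep
    the two unclamped linear pieces meeting at 1 on their own midpoint.
    """
    Pj, left, right = _level_arrays(scheme, j)
    x = np.asarray(x, dtype=float)
    if left is None:
        # lowest level: 1 below P_1, slope down to -1 at the midpoint after next
        slope_den = right - Pj  # equals P_2 - P_1
        lin = (right - x) / slope_den
        far = scheme.midpoints[min(j + 1, scheme.J - 1)]
        out = np.where(x <= Pj, 1.0, np.where(x <= far, lin, -1.0))
        return out
    if right is None:
        # highest level: mirror of the lowest
        slope_den = Pj - left
        lin = (x - left) / slope_den
        far = scheme.midpoints[max(j - 3, 0)]
        out = np.where(x > Pj, 1.0, np.where(x > far, lin, -1.0))
        return out
    # interior level: unclamped tent
    up = (x - left) / (Pj - left)
    down = (right - x) / (right - Pj)
    return np.where(x <= Pj, up, down)


def membership_matrix(
    scheme: IntervalScheme, x: ArrayLike, family: str = "traditional"
) -> NDArray[np.float64]:
    """Stack memberships of all ``J`` levels into an (n, J) matrix.

    ``family`` is ``"traditional"`` or ``"extended"``.
    """
    fn = {"traditional": mu_traditional, "extended": mu_extended}[family]
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return np.column_stack([fn(scheme, j, x) for j in range(1, scheme.J + 1)])


def assign_crisp_category(scheme: IntervalScheme, x: ArrayLike) -> NDArray[np.int64]:
    """Hard level assignment, 1-based.

    Intervals are half-open with the upper end closed at the trait maximum;
    a value exactly on an interior border goes to the lower level.  Values
    outside the scheme's range clamp to the outermost levels.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    interior = scheme.borders[1:-1]
    return np.searchsorted(interior, x, side="left").astype(np.int64) + 1
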