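"""Desirability transforms for gene-level omics variables.

A desirability function maps a raw study variable Y (P-value, fold change,
odds ratio, ...) onto the unit interval, where 1 marks the most desirable
evidence for a gene as a disease candidate.  Four shapes are supported:

``low``
    Small values are desirable (P-values).  1 below the low cut A, 0 above
    the high cut B, power-interpolated in between::

        d_low(Y) = 1                       Y < A
                 = [(Y - B)/(A - B)]^s     A <= Y <= B
                 = 0                       Y > B

``high``
    Large values are desirable (odds ratios); the mirror image of ``low``.

``extreme``
    Values in either tail are desirable (fold changes).  A four-cut valley
    B_lo < A_lo <= A_hi < B_hi: 1 at or beyond the outer cuts, 0 on the
    inner plateau [A_lo, A_hi], with a ``low``-shaped descent on
    (B_lo, A_lo) and a ``high``-shaped ascent on (A_hi, B_hi).

``target``
    An intermediate value is desirable; peak-shaped with cuts A < C < B,
    reaching 1 at C and 0 outside [A, B].

The exponent ``s`` (scale) bends the interpolating branch; s = 1 is linear.
Cut points may be given numerically or as percentiles of the observed data
(resolved by :func:`resolve_percentile_cuts`).  Missing / non-finite values
propagate as missing — they are never coerced to zero desirability, which
would silently penalise a gene during downstream averaging.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidSpecError",
    "DegenerateVariableError",
    "DesirabilityFunctionSpec",
    "d_low",
    "d_high",
    "d_extreme",
    "d_target",
    "resolve_percentile_cuts",
    "transform_variable",
]


class InvalidSpecError(ValueError):
    """A desirability-function specification violates its invariants."""


class DegenerateVariableError(ValueError):
    """A variable has too few distinct values to resolve percentile cuts."""


_KIND_NCUTS = {"low": 2, "high": 2, "extreme": 4, "target": 3}


@dataclass(frozen=True)
class DesirabilityFunctionSpec:
    """Which transform a variable gets, and its parameterisation.

    Parameters
    ----------
    kind
        One of ``"low"``, ``"high"``, ``"extreme"``, ``"target"``.
    cuts
        Ordered cut points.  ``low``/``high`` take (A, B); ``extreme`` takes
        (B_lo, A_lo, A_hi, B_hi); ``target`` takes (A, C, B).  In percentile
        mode, ``extreme`` also accepts three cuts (p_tail_lo, mid_width,
        p_tail_hi) where ``mid_width`` names the central band mapped to 0
        (e.g. 50 for "the middle 50%").
    scale
        Positive exponent on the interpolating branch; 1 is linear.
    weight
        Non-negative weight used when variables are averaged within a study.
    d_min, d_max
        Output bounds; transformed scores are affinely rescaled into
        [d_min, d_max] (defaults 0 and 1).
    cut_mode
        ``"numeric"`` or ``"percentile"``; percentile cuts lie in [0, 100]
        and are resolved against the variable's non-missing values.
    """

    kind: str
    cuts: tuple[float, ...]
    scale: float = 1.0
    weight: float = 1.0
    d_min: float = 0.0
    d_max: float = 1.0
    cut_mode: str = "numeric"

    def __post_init__(self) -> None:
        if self.kind not in _KIND_NCUTS:
            raise InvalidSpecError(f"unknown desirability kind {self.kind!r}")
        if self.cut_mode not in ("numeric", "percentile"):
            raise InvalidSpecError(f"unknown cut_mode {self.cut_mode!r}")
        object.__setattr__(self, "cuts", tuple(float(c) for c in self.cuts))
        n = len(self.cuts)
        n_expected = _KIND_NCUTS[self.kind]
        three_cut_extreme = (
            self.kind == "extreme" and self.cut_mode == "percentile" and n == 3
        )
        if n != n_expected and not three_cut_extreme:
            raise InvalidSpecError(
                f"kind {self.kind!r} needs {n_expected} cut points, got {n}"
            )
        if not self.scale > 0:
            raise InvalidSpecError(f"scale must be positive, got {self.scale}")
        if self.weight < 0:
            raise InvalidSpecError(f"weight must be non-negative, got {self.weight}")
        if not (0.0 <= self.d_min < self.d_max <= 1.0):
            raise InvalidSpecError(
                f"need 0 <= d_min < d_max <= 1, got ({self.d_min}, {self.d_max})"
            )
        if self.cut_mode == "percentile":
            if any(not (0.0 <= c <= 100.0) for c in self.cuts):
                raise InvalidSpecError(f"percentile cuts must lie in [0, 100]: {self.cuts}")
        else:
            self._check_cut_order(self.cuts)

    def _check_cut_order(self, cuts: Sequence[float]) -> None:
        """Strict ordering as the kind requires; equal adjacent cuts would
        divide by zero in the interpolating branches (extreme's two inner
        cuts may coincide — they bound the zero plateau, not a branch)."""
        k = self.kind
        if k in ("low", "high"):
            a, b = cuts
            if not a < b:
                raise InvalidSpecError(f"{k}: need A < B, got {cuts}")
        elif k == "extreme":
            b_lo, a_lo, a_hi, b_hi = cuts
            if not (b_lo < a_lo <= a_hi < b_hi):
                raise InvalidSpecError(
                    f"extreme: need B_lo < A_lo <= A_hi < B_hi, got {cuts}"
                )
        elif k == "target":
            a, c, b = cuts
            if not (a < c < b):
                raise InvalidSpecError(f"target: need A < C < B, got {cuts}")

    @property
    def is_numeric(self) -> bool:
        return self.cut_mode == "numeric"


def _as_float_array(y) -> np.ndarray:
    return np.asarray(y, dtype=float)


def d_low(y, a: float, b: float, s: float = 1.0) -> np.ndarray | float:
    """Desirability when small values of Y are best (e.g. P-values).

    Returns 1 for Y < A, 0 for Y > B and ``[(Y-B)/(A-B)]**s`` in between.
    Non-finite Y propagates as NaN (missing).
    """
    if not a < b:
        raise InvalidSpecError(f"d_low: need A < B, got A={a}, B={b}")
    if not s > 0:
        raise InvalidSpecError(f"d_low: need s > 0, got {s}")
    yv = _as_float_array(y)
    with np.errstate(invalid="ignore"):
        mid = np.power(np.clip((yv - b) / (a - b), 0.0, 1.0), s)
        out = np.where(yv < a, 1.0, np.where(yv > b, 0.0, mid))
    out = np.where(np.isfinite(yv), out, np.nan)
    return out if out.ndim else float(out) if np.isfinite(out) else float("nan")


def d_high(y, a: float, b: float, s: float = 1.0) -> np.ndarray | float:
    """Desirability when large values of Y are best (e.g. odds ratios).

    Returns 0 for Y < A, 1 for Y > B and ``[(Y-A)/(B-A)]**s`` in between.
    """
    if not a < b:
        raise InvalidSpecError(f"d_high: need A < B, got A={a}, B={b}")
    if not s > 0:
        raise InvalidSpecError(f"d_high: need s > 0, got {s}")
    yv = _as_float_array(y)
    with np.errstate(invalid="ignore"):
        mid = np.power(np.clip((yv - a) / (b - a), 0.0, 1.0), s)
        out = np.where(yv < a, 0.0, np.where(yv > b, 1.0, mid))
    out = np.where(np.isfinite(yv), out, np.nan)
    return out if out.ndim else float(out) if np.isfinite(out) else float("nan")


def d_extreme(
    y, b_lo: float, a_lo: float, a_hi: float, b_hi: float, s: float = 1.0
) -> np.ndarray | float:
    """Valley desirability: values in either tail of Y are best (fold changes).

    1 at or beyond the outer cuts (Y <= B_lo or Y >= B_hi), 0 on the central
    plateau [A_lo, A_hi]; the flanks interpolate as ``d_low(Y; B_lo, A_lo)``
    on the left and ``d_high(Y; A_hi, B_hi)`` on the right.
    """
    if not (b_lo < a_lo <= a_hi < b_hi):
        raise InvalidSpecError(
            f"d_extreme: need B_lo < A_lo <= A_hi < B_hi, got "
            f"({b_lo}, {a_lo}, {a_hi}, {b_hi})"
        )
    if not s > 0:
        raise InvalidSpecError(f"d_extreme: need s > 0, got {s}")
    yv = _as_float_array(y)
    with np.errstate(invalid="ignore"):
        left = np.power(np.clip((yv - a_lo) / (b_lo - a_lo), 0.0, 1.0), s)
        right = np.power(np.clip((yv - a_hi) / (b_hi - a_hi), 0.0, 1.0), s)
        out = np.where(yv < a_lo, left, np.where(yv > a_hi, right, 0.0))
    out = np.where(np.isfinite(yv), out, np.nan)
    return out if out.ndim else float(out) if np.isfinite(out) else float("nan")


def d_target(y, a: float, c: float, b: float, s: float = 1.0) -> np.ndarray | float:
    """Peak desirability: an intermediate value C of Y is best.

    ``[(Y-A)/(C-A)]**s`` on [A, C], ``[(Y-B)/(C-B)]**s`` on [C, B], 0
    elsewhere; the maximum 1 is attained at Y = C.
    """
    if not (a < c < b):
        raise InvalidSpecError(f"d_target: need A < C < B, got ({a}, {c}, {b})")
    if not s > 0:
        raise InvalidSpecError(f"d_target: need s > 0, got {s}")
    yv = _as_float_array(y)
    with np.errstate(invalid="ignore"):
        up = np.power(np.clip((yv - a) / (c - a), 0.0, 1.0), s)
        down = np.power(np.clip((yv - b) / (c - b), 0.0, 1.0), s)
        out = np.where(yv <= c, up, down)
        out = np.where((yv < a) | (yv > b), 0.0, out)
    out = np.where(np.isfinite(yv), out, np.nan)
    return out if out.ndim else float(out) if np.isfinite(out) else float("nan")


def resolve_percentile_cuts(
    spec: DesirabilityFunctionSpec, values
) -> DesirabilityFunctionSpec:
    """Replace percentile-coded cuts with empirical quantiles of ``values``.

    Quantiles use linear interpolation (numpy's default).  For ``low``
    variables the desirable tail is the smallest-value end, so the cuts
    (5, 95) place the "top 5%" saturation at the 5th quantile.  A
    three-cut percentile ``extreme`` spec (p_lo, mid_width, p_hi) expands
    the middle cut into the central band of that width: (5, 50, 95)
    becomes valley cuts at the 5th, 25th, 75th and 95th quantiles, so the
    middle 50% of values maps to 0.

    Raises
    ------
    DegenerateVariableError
        If fewer than two distinct non-missing values are available, or if
        the resolved cuts collapse (ties in the quantiles).
    """
    if spec.cut_mode != "percentile":
        return spec
    vals = _as_float_array(values)
    vals = vals[np.isfinite(vals)]
    if np.unique(vals).size < 2:
        raise DegenerateVariableError(
            "percentile cuts need at least 2 distinct non-missing values"
        )
    pcts = list(spec.cuts)
    if spec.kind == "extreme" and len(pcts) == 3:
        p_lo, width, p_hi = pcts
        pcts = [p_lo, 50.0 - width / 2.0, 50.0 + width / 2.0, p_hi]
    numeric = tuple(float(q) for q in np.percentile(vals, pcts))
    resolved = dataclasses.replace(spec, cuts=numeric, cut_mode="numeric")
    try:
        resolved._check_cut_order(numeric)
    except InvalidSpecError as exc:
        raise DegenerateVariableError(
            f"percentile cuts {spec.cuts} collapse to {numeric} on these values"
        ) from exc
    return resolved


_DISPATCH = {
    "low": lambda y, cuts, s: d_low(y, *cuts, s),
    "high": lambda y, cuts, s: d_high(y, *cuts, s),
    "extreme": lambda y, cuts, s: d_extreme(y, *cuts, s),
    "target": lambda y, cuts, s: d_target(y, *cuts, s),
}


def transform_variable(values, spec: DesirabilityFunctionSpec) -> np.ndarray:
    """Map raw variable values through ``spec``'s desirability function.

    ``values`` may be any array-like (a pandas Series keeps its index
    semantics upstream; here only the numeric content matters).  Percentile
    specs are resolved against the same values.  Outputs are rescaled into
    [d_min, d_max]; missing values stay missing.
    """
    spec = resolve_percentile_cuts(spec, values)
    d = _DISPATCH[spec.kind](_as_float_array(values), spec.cuts, spec.scale)
    d = np.asarray(d, dtype=float)
    if spec.d_min != 0.0 or spec.d_max != 1.0:
        d = spec.d_min + d * (spec.d_max - spec.d_min)
    return d
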