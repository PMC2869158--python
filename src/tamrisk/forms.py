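"""Risk-function forms for continuous predictors.

A *form* describes how a raw covariate (typically an immunohistochemistry
histoscore on the 0-300 scale) enters the log-hazard of a Cox model:

``linear``
    the raw value itself;
``fp1`` / ``fp2``
    one or two fractional-polynomial power transforms with powers drawn
    from the conventional set {-2, -1, 0, 0.5, 1, 2, 3}, where power 0
    denotes the natural log and a repeated power (p, p) expands to
    ``x^p`` and ``x^p * ln(x)``;
``threshold``
    a 0/1 indicator of expression at or above a cutpoint;
``non_ordinal``
    a 0/1 indicator of membership in a quartile-defined interior range of
    the distribution (e.g. between the 2nd and 3rd quartile) versus the
    remaining patients.

Fractional-polynomial transforms require strictly positive inputs, so each
form carries a pre-scaling ``(shift, scale)`` applied as ``(x + shift) /
scale`` before any power is taken.  The default scaling shifts a variable
whose minimum is <= 0 by ``1 - min`` and divides by a power of ten chosen so
the transformed values are of order one (a 0-300 histoscore is divided by
100, matching the usual reporting convention for cubic-transformed scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

#: fractional-polynomial power set; 0 denotes the natural logarithm
FP_POWERS: tuple[float, ...] = (-2.0, -1.0, 0.0, 0.5, 1.0, 2.0, 3.0)

#: quartile-range patterns probed by the non-ordinal scan (R1..R4 are the
#: four quartile ranges; "R2R3" = middle two ranges vs the rest, etc.)
NON_ORDINAL_PATTERNS: tuple[str, ...] = ("R2", "R3", "R2R3", "R1R3")

FORM_KINDS = ("linear", "fp1", "fp2", "threshold", "non_ordinal")


@dataclass(frozen=True)
class Form:
    """Tagged description of how one covariate enters the model."""

    kind: str
    powers: tuple[float, ...] = ()
    cut: float | None = None
    pattern: str | None = None
    shift: float = 0.0
    scale: float = 1.0
    #: frozen quartiles (q1, q2, q3) for non_ordinal forms
    quartiles: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in FORM_KINDS:
            raise ValueError(f"unknown form kind {self.kind!r}")
        if self.kind == "fp1":
            if len(self.powers) != 1 or self.powers[0] not in FP_POWERS:
                raise ValueError(f"fp1 needs one power from {FP_POWERS}")
        elif self.kind == "fp2":
            if len(self.powers) != 2 or any(p not in FP_POWERS for p in self.powers):
                raise ValueError(f"fp2 needs two powers from {FP_POWERS}")
            if self.powers[0] > self.powers[1]:
                raise ValueError("fp2 powers must satisfy p1 <= p2")
        elif self.powers:
            raise ValueError(f"{self.kind} form takes no powers")
        if self.kind == "threshold" and self.cut is None:
            raise ValueError("threshold form needs a cutpoint")
        if self.kind == "non_ordinal":
            if self.pattern not in NON_ORDINAL_PATTERNS:
                raise ValueError(f"pattern must be one of {NON_ORDINAL_PATTERNS}")
        if not (math.isfinite(self.shift) and math.isfinite(self.scale)) or self.scale <= 0:
            raise ValueError("scaling must be finite with scale > 0")

    @property
    def n_columns(self) -> int:
        return 2 if self.kind == "fp2" else 1

    @property
    def degree_class(self) -> str:
        """Coarse class used for form-stability bookkeeping."""
        if self.kind in ("linear", "fp1", "fp2"):
            return self.kind
        return "special"

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.powers:
            d["powers"] = list(self.powers)
        if self.cut is not None:
            d["cut"] = self.cut
        if self.pattern is not None:
            d["pattern"] = self.pattern
        if self.shift != 0.0 or self.scale != 1.0:
            d["shift"], d["scale"] = self.shift, self.scale
        if self.quartiles is not None:
            d["quartiles"] = list(self.quartiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Form":
        return cls(
            kind=d["kind"],
            powers=tuple(d.get("powers", ())),
            cut=d.get("cut"),
            pattern=d.get("pattern"),
            shift=d.get("shift", 0.0),
            scale=d.get("scale", 1.0),
            quartiles=tuple(d["quartiles"]) if d.get("quartiles") else None,
        )


def linear() -> Form:
    return Form("linear")


def fp1(p: float, shift: float = 0.0, scale: float = 1.0) -> Form:
    return Form("fp1", powers=(float(p),), shift=shift, scale=scale)


def fp2(p1: float, p2: float, shift: float = 0.0, scale: float = 1.0) -> Form:
    lo, hi = sorted((float(p1), float(p2)))
    return Form("fp2", powers=(lo, hi), shift=shift, scale=scale)


def threshold(cut: float) -> Form:
    return Form("threshold", cut=float(cut))


def non_ordinal(pattern: str, quartiles=None) -> Form:
    return Form(
        "non_ordinal",
        pattern=pattern,
        quartiles=tuple(float(q) for q in quartiles) if quartiles is not None else None,
    )


def default_scaling(x: np.ndarray) -> tuple[float, float]:
    """Shift/scale making a variable usable with log and negative powers.

    Shift is ``1 - min(x)`` when the minimum is non-positive (standard
    fractional-polynomial practice), and the scale is the largest power of
    ten not exceeding the shifted maximum, so transformed values are O(1).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("scaling needs finite, non-empty data")
    mn = float(x.min())
    shift = 0.0 if mn > 0 else 1.0 - mn
    mx = float(x.max()) + shift
    scale = 10.0 ** max(0, math.floor(math.log10(mx))) if mx > 0 else 1.0
    return shift, scale


def _power_col(z: np.ndarray, p: float) -> np.ndarray:
    return np.log(z) if p == 0.0 else z ** p


def fp_transform(x: np.ndarray, form: Form) -> np.ndarray:
    """Expand a linear/fp1/fp2 form into its design column(s).

    Returns an (n, 1) or (n, 2) array.  Raises if a log or negative power
    would be applied to non-positive values and no adequate shift was set.
    """
    if form.kind not in ("linear", "fp1", "fp2"):
        raise ValueError(f"fp_transform does not apply to {form.kind!r} forms")
    x = np.asarray(x, dtype=float)
    if form.kind == "linear":
        return ((x + form.shift) / form.scale)[:, None]
    z = (x + form.shift) / form.scale
    needs_positive = any(p <= 0 for p in form.powers)
    if needs_positive and np.any(z <= 0):
        raise ValueError(
            "non-positive values under log/negative power; set an explicit shift"
        )
    if form.kind == "fp1":
        return _power_col(z, form.powers[0])[:, None]
    p1, p2 = form.powers
    c1 = _power_col(z, p1)
    # repeated-power convention: second column is x^p * ln(x)
    c2 = c1 * np.log(z) if p1 == p2 else _power_col(z, p2)
    return np.column_stack([c1, c2])


def quartile_ranges(x: np.ndarray, quartiles=None) -> np.ndarray:
    """Assign each value to a quartile range 1..4 (ties go to the lower range)."""
    x = np.asarray(x, dtype=float)
    if quartiles is None:
        quartiles = np.quantile(x, [0.25, 0.5, 0.75])
    q = np.asarray(quartiles, dtype=float)
    return 1 + (x > q[0]).astype(int) + (x > q[1]).astype(int) + (x > q[2]).astype(int)


_PATTERN_RANGES = {"R2": {2}, "R3": {3}, "R2R3": {2, 3}, "R1R3": {1, 3}}


def pattern_indicator(x: np.ndarray, pattern: str, quartiles=None) -> np.ndarray:
    """0/1 indicator of membership in the quartile ranges named by *pattern*."""
    ranges = _PATTERN_RANGES[pattern]
    r = quartile_ranges(x, quartiles)
    return np.isin(r, list(ranges)).astype(float)


def form_columns(x: np.ndarray, form: Form) -> np.ndarray:
    """Design column(s) for any form kind, as an (n, k) float array."""
    x = np.asarray(x, dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError("form_columns requires complete data")
    if form.kind in ("linear", "fp1", "fp2"):
        return fp_transform(x, form)
    if form.kind == "threshold":
        return (x >= form.cut).astype(float)[:, None]
    if form.kind == "non_ordinal":
        return pattern_indicator(x, form.pattern, form.quartiles)[:, None]
    raise ValueError(f"unknown form kind {form.kind!r}")


def column_names(variable: str, form: Form) -> list[str]:
    """Stable design-matrix column names for a variable under a form."""
    if form.kind == "linear":
        return [variable]
    if form.kind == "fp1":
        return [f"{variable}__fp({form.powers[0]:g})"]
    if form.kind == "fp2":
        p1, p2 = form.powers
        second = f"{p2:g}" if p1 != p2 else f"{p1:g}.log"
        return [f"{variable}__fp({p1:g})", f"{variable}__fp({second})"]
    if form.kind == "threshold":
        return [f"{variable}__ge{form.cut:g}"]
    return [f"{variable}__{form.pattern}"]


def resolve_form(x: np.ndarray, form: Form) -> Form:
    """Fill data-dependent slots (fp scaling, non-ordinal quartiles) from *x*."""
    x = np.asarray(x, dtype=float)
    if form.kind in ("fp1", "fp2") and form.shift == 0.0 and form.scale == 1.0:
        shift, scale = default_scaling(x)
        return replace(form, shift=shift, scale=scale)
    if form.kind == "non_ordinal" and form.quartiles is None:
        q = np.quantile(x, [0.25, 0.5, 0.75])
        return replace(form, quartiles=tuple(float(v) for v in q))
    return form
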