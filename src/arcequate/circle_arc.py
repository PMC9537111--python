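"""Circle-arc observed-score equating.

The circle-arc method links two bounded integer score scales from three
anchor points: the nadir ``(x1, y1)``, a midpoint ``(x2, y2)`` and the
zenith ``(x3, y3)``.  The conversion decomposes into

* a linear component ``L(x)`` — the chord through the nadir and zenith —
  and
* a circular-arc correction through the deviation-transformed midpoint:
  after subtracting ``L``, the endpoints map to ``(x1, 0)`` and
  ``(x3, 0)`` and the midpoint to ``(x2, y2*)`` with
  ``y2* = y2 - L(x2)``.  The unique circle through those three points has
  the closed-form center and radius

  .. code-block:: text

     xc = (x3^2 - x1^2) / (2 (x3 - x1))
     yc = [x1^2 (x3 - x2) - (x2^2 + y2*^2)(x3 - x1) + x3^2 (x2 - x1)]
          / (2 y2* (x1 - x3))
     r  = sqrt((xc - x1)^2 + yc^2)

The converted score is ``L(x) + Y*(x)`` where
``Y*(x) = yc + sign(y2*) * sqrt(r^2 - (x - xc)^2)``: the branch bends the
arc toward the midpoint anchor, which is the only choice that passes
through ``(x2, y2*)``.  Collinear anchors (``y2* = 0``) degenerate to the
straight line ``L``.

The method assumes a *minor* arc: the circle center lies on the opposite
side of the baseline from the midpoint bulge (``sign(yc) != sign(y2*)``,
equivalently ``y2*^2 < (xc-x1)^2 - (x2-xc)^2``), so that all three
transformed points lie on one function branch.  Score crosswalks, which
deviate only mildly from linearity, sit comfortably in this regime; with
a larger sag the endpoints fall on the other branch and the arc no
longer interpolates them.

The method is designed for small samples: three anchor points determine
the whole 0-30 integer conversion table, which is the form clinicians use.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (AnchorError, ConversionLookupError, DegenerateAnchorError,
                     InsufficientDataError, OutOfArcDomainError)
from .score_data import SCORE_MAX, SCORE_MIN, Cohort

#: |y2*| below this is treated as collinear anchors (degenerate linear model)
_DEGENERATE_TOL = 1e-12
#: slack for sqrt arguments at the arc-domain boundary
_DOMAIN_TOL = 1e-9


def round_half_away(x):
    """Round to nearest integer, ties away from zero (0.5 -> 1, -0.5 -> -1)."""
    arr = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if np.isscalar(x):
        return int(arr)
    return arr.astype(int)


@dataclass(frozen=True)
class AnchorTriplet:
    """Nadir, midpoint and zenith anchor points in score units."""

    x1: float
    y1: float
    x2: float
    y2: float
    x3: float
    y3: float

    def __post_init__(self) -> None:
        if self.x1 == self.x3:
            raise DegenerateAnchorError(f"nadir and zenith share x = {self.x1}")
        if not self.x1 < self.x2 < self.x3:
            raise AnchorError(
                f"anchor x-values must be strictly increasing, got "
                f"({self.x1}, {self.x2}, {self.x3})")
        for name in ("x1", "y1", "x2", "y2", "x3", "y3"):
            v = getattr(self, name)
            if not SCORE_MIN <= v <= SCORE_MAX:
                raise AnchorError(f"anchor {name}={v} outside [0, 30]")

    def as_points(self) -> list[tuple[float, float]]:
        return [(self.x1, self.y1), (self.x2, self.y2), (self.x3, self.y3)]


def linear_component(anchors: "AnchorTriplet | CircleArcModel", x) -> float:
    """Chord through the nadir and zenith: L(x) = y1 + (y3-y1)/(x3-x1) (x-x1)."""
    a = anchors.anchors if isinstance(anchors, CircleArcModel) else anchors
    return a.y1 + (a.y3 - a.y1) / (a.x3 - a.x1) * (np.asarray(x, dtype=float) - a.x1)


@dataclass(frozen=True)
class CircleArcModel:
    """A fitted circle-arc conversion: linear chord plus arc correction.

    ``branch`` is +1 when the midpoint lies above the chord, -1 below, and
    0 for the degenerate collinear case where the model is the chord itself.
    """

    anchors: AnchorTriplet
    slope: float
    intercept: float
    y2_star: float
    xc: float
    yc: float
    r: float
    branch: int

    @property
    def degenerate(self) -> bool:
        return self.branch == 0

    def domain(self) -> tuple[float, float]:
        """x-interval on which the arc formula is defined."""
        if self.degenerate:
            return (-math.inf, math.inf)
        return (self.xc - self.r, self.xc + self.r)


def fit_circle_arc(anchors: AnchorTriplet) -> CircleArcModel:
    """Fit the circle-arc model to three anchor points by the closed forms.

    Computes the midpoint deviation ``y2* = y2 - L(x2)``; if it vanishes
    the anchors are collinear and the degenerate linear model is returned,
    otherwise the circle center ``(xc, yc)`` and radius ``r`` through
    ``(x1, 0), (x2, y2*), (x3, 0)`` are evaluated in closed form.
    """
    x1, y1, x2, y2, x3, y3 = (anchors.x1, anchors.y1, anchors.x2,
                              anchors.y2, anchors.x3, anchors.y3)
    slope = (y3 - y1) / (x3 - x1)
    intercept = y1 - slope * x1
    y2_star = y2 - (slope * x2 + intercept)
    if abs(y2_star) < _DEGENERATE_TOL:
        return CircleArcModel(anchors=anchors, slope=slope, intercept=intercept,
                              y2_star=0.0, xc=math.nan, yc=math.nan,
                              r=math.nan, branch=0)
    xc = (x3**2 - x1**2) / (2.0 * (x3 - x1))
    yc = (x1**2 * (x3 - x2) - (x2**2 + y2_star**2) * (x3 - x1)
          + x3**2 * (x2 - x1)) / (2.0 * y2_star * (x1 - x3))
    r = math.hypot(xc - x1, yc)
    return CircleArcModel(anchors=anchors, slope=slope, intercept=intercept,
                          y2_star=y2_star, xc=xc, yc=yc, r=r,
                          branch=1 if y2_star > 0 else -1)


def convert_score(model: CircleArcModel, x: float) -> float:
    """Convert one source score to the (real-valued) target scale.

    Degenerate models return the chord value ``L(x)``.  Otherwise the arc
    correction is added: ``L(x) + yc + branch * sqrt(r^2 - (x - xc)^2)``.
    The result interpolates the three anchors exactly.  Evaluating outside
    the arc's x-domain raises :class:`OutOfArcDomainError`; the caller
    decides the fallback (the table builder falls back to ``L``).
    """
    lin = float(linear_component(model.anchors, x))
    if model.degenerate:
        return lin
    disc = model.r**2 - (x - model.xc) ** 2
    if disc < -_DOMAIN_TOL:
        raise OutOfArcDomainError(
            f"x={x} outside arc domain [{model.xc - model.r:.3f}, "
            f"{model.xc + model.r:.3f}]")
    return lin + model.yc + model.branch * math.sqrt(max(disc, 0.0))


def extract_anchors(paired: "Cohort | Iterable[tuple[int, int]]",
                    mode: str = "auto",
                    explicit: AnchorTriplet | None = None) -> AnchorTriplet:
    """Choose the three anchor points from paired (source, target) scores.

    Auto mode sets the midpoint to the rounded sample means, the nadir to
    the minimal source score and the zenith to the maximal one; the target
    value at each extreme is the rounded median target score among records
    sharing that extreme source score (a deterministic tie rule).  Explicit
    mode returns user-supplied anchors after validation, for fidelity to an
    externally published anchor set.
    """
    if mode == "explicit":
        if explicit is None:
            raise ValueError("explicit mode requires an AnchorTriplet")
        return explicit
    if mode != "auto":
        raise ValueError(f"unknown anchor mode {mode!r}")
    pairs = paired.pairs() if isinstance(paired, Cohort) else list(paired)
    if len({x for x, _ in pairs}) < 3:
        raise InsufficientDataError(
            "need at least 3 distinct source scores to place anchors")
    xs = np.array([p[0] for p in pairs], dtype=float)
    ys = np.array([p[1] for p in pairs], dtype=float)
    x1 = xs.min()
    x3 = xs.max()
    y1 = round_half_away(float(np.median(ys[xs == x1])))
    y3 = round_half_away(float(np.median(ys[xs == x3])))
    x2 = round_half_away(float(xs.mean()))
    y2 = round_half_away(float(ys.mean()))
    try:
        return AnchorTriplet(x1=x1, y1=y1, x2=x2, y2=y2, x3=x3, y3=y3)
    except AnchorError as err:
        raise AnchorError(
            f"extracted anchors invalid (x1={x1}, x2={x2}, x3={x3}): {err}"
        ) from err


@dataclass
class ConversionTable:
    """Integer lookup table: source score -> equated target score."""

    entries: Mapping[int, int]
    model: CircleArcModel | None = None
    label: str = ""

    def __getitem__(self, source: int) -> int:
        try:
            return self.entries[int(source)]
        except KeyError:
            raise ConversionLookupError(
                f"source score {source} outside table range") from None

    def scores(self) -> list[int]:
        return sorted(self.entries)

    def as_array(self) -> np.ndarray:
        return np.array([self.entries[s] for s in self.scores()], dtype=int)

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV with a header comment recording the fit."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self._provenance_comment())
            fh.write("source,converted\n")
            for s in self.scores():
                fh.write(f"{s},{self.entries[s]}\n")

    def _provenance_comment(self) -> str:
        if self.model is None:
            return f"# label={self.label} anchors=none\n"
        a = self.model.anchors
        return (f"# label={self.label} "
                f"anchors=({a.x1},{a.y1});({a.x2},{a.y2});({a.x3},{a.y3}) "
                f"xc={self.model.xc!r} yc={self.model.yc!r} "
                f"r={self.model.r!r} branch={self.model.branch}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConversionTable":
        label = ""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        body: list[str] = []
        for line in lines:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("label="):
                        label = tok[len("label="):]
            else:
                body.append(line)
        import csv

        reader = csv.DictReader(io.StringIO("\n".join(body)))
        entries = {int(row["source"]): int(row["converted"]) for row in reader}
        return cls(entries=entries, model=None, label=label)


def build_conversion_table(model: CircleArcModel,
                           scores: Sequence[int] = range(SCORE_MIN, SCORE_MAX + 1),
                           label: str = "") -> ConversionTable:
    """Tabulate the conversion at every integer source score.

    Inside the arc's x-domain the arc formula is used (also beyond the
    zenith, where the published tables keep following the arc); outside it
    the chord ``L(s)`` is the fallback.  Values are rounded half away from
    zero and clamped to [0, 30].
    """
    entries: dict[int, int] = {}
    for s in scores:
        try:
            val = convert_score(model, float(s))
        except OutOfArcDomainError:
            val = float(linear_component(model.anchors, s))
        entries[int(s)] = int(np.clip(round_half_away(val), SCORE_MIN, SCORE_MAX))
    return ConversionTable(entries=entries, model=model, label=label)


def apply_conversion(table: ConversionTable, cohort: Cohort) -> np.ndarray:
    """Convert every subject's source score through the table, in order."""
    out = np.empty(len(cohort), dtype=int)
    for i, rec in enumerate(cohort):
        try:
            out[i] = table[rec.mmse]
        except ConversionLookupError as err:
            raise ConversionLookupError(
                f"subject {rec.subject_id}: {err}") from None
    return out
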