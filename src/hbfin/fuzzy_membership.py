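"""Fuzzy membership functions mapping a symptom value to a grade in [0, 1].

A membership function (MF) expresses how compatible a symptom value is
with a specific diagnosis.  Three parametric families are supported:

- ``polynomial``      f(s) = λ0 + λ1·s + … + λt·s^t, clipped to [0, 1]
- ``s_type``          f(s) = 1 / (1 + exp(−a·(s − b)))   (logistic)
- ``quasi_gaussian``  f(s) = exp(−((s − a) / (2d))²)

"Quasi" Gaussian because evaluation is restricted to a finite support:
outside ``[lo, hi]`` the boundary value is returned (constant
extrapolation), so the curve never extends to ±infinity.

MFs are fitted from labeled cohorts the way a frequency plot is read off:
histogram the whole cohort, histogram the records carrying the diagnosis,
and take the labeled fraction per occupied bin as the empirical grade at
the bin center.  The chosen family is then least-squares fitted to those
(center, grade) pairs.  When no family is prescribed, all three are fitted
and the lowest residual sum of squares wins (ties broken in the order
polynomial < s_type < quasi_gaussian).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import curve_fit
from scipy.special import expit

from .errors import ConfigError, FitError

__all__ = [
    "MembershipFunction",
    "MembershipSet",
    "eval_mf",
    "fit_mf",
    "select_kind",
    "bin_grades",
]

KINDS = ("polynomial", "s_type", "quasi_gaussian")

#: fewest labeled samples accepted by :func:`fit_mf`
MIN_FIT_COUNT = 20


@dataclass(frozen=True)
class MembershipFunction:
    """One fitted grade curve for a (symptom, hypothesis) pair."""

    kind: str
    symptom: str
    hypothesis: str
    params: dict
    support: tuple[float, float]

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"unknown membership-function kind {self.kind!r}")
        lo, hi = self.support
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
            raise ConfigError(f"invalid support {self.support!r}")
        if self.kind == "s_type" and float(self.params["a"]) == 0.0:
            raise ConfigError("s_type membership function needs a nonzero slope")
        if self.kind == "quasi_gaussian" and float(self.params["d"]) <= 0.0:
            raise ConfigError("quasi_gaussian membership function needs d > 0")

    def __call__(self, s: float) -> float:
        return eval_mf(self, s)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "symptom": self.symptom,
            "hypothesis": self.hypothesis,
            "params": {k: (list(v) if isinstance(v, (list, tuple, np.ndarray)) else float(v))
                       for k, v in self.params.items()},
            "support": [float(self.support[0]), float(self.support[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MembershipFunction":
        try:
            return cls(
                kind=d["kind"],
                symptom=d["symptom"],
                hypothesis=d["hypothesis"],
                params=dict(d["params"]),
                support=(float(d["support"][0]), float(d["support"][1])),
            )
        except (KeyError, TypeError, IndexError) as exc:
            raise ConfigError(f"malformed membership-function entry: {exc}") from exc


def _raw_eval(kind: str, params: dict, s: np.ndarray) -> np.ndarray:
    if kind == "polynomial":
        coeffs = np.asarray(params["coeffs"], dtype=float)
        return np.polynomial.polynomial.polyval(s, coeffs)
    if kind == "s_type":
        return expit(float(params["a"]) * (s - float(params["b"])))
    if kind == "quasi_gaussian":
        a, d = float(params["a"]), float(params["d"])
        return np.exp(-(((s - a) / (2.0 * d)) ** 2))
    raise ConfigError(f"unknown membership-function kind {kind!r}")


def eval_mf(mf: MembershipFunction, s: float):
    """Membership grade at *s*, always in [0, 1].

    Values outside the support are clamped to the nearest boundary before
    evaluation, and polynomial output is clipped to [0, 1].
    """
    arr = np.clip(np.asarray(s, dtype=float), mf.support[0], mf.support[1])
    out = np.clip(_raw_eval(mf.kind, mf.params, arr), 0.0, 1.0)
    return float(out) if np.isscalar(s) or np.ndim(s) == 0 else out


def bin_grades(values: Sequence[float], all_values: Sequence[float], bins: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Empirical grade curve: labeled fraction per occupied histogram bin.

    Bin edges come from the cohort-wide sample (Sturges' rule when *bins*
    is None); a bin's grade is (labeled count) / (cohort count) and bins
    with no cohort mass are dropped.  Returns (bin centers, grades).
    """
    all_values = np.asarray(all_values, dtype=float)
    values = np.asarray(values, dtype=float)
    if bins is None:
        bins = max(5, int(math.ceil(math.log2(len(all_values)))) + 1)
    if bins < 5:
        raise FitError(f"need at least 5 bins, got {bins}")
    counts_all, edges = np.histogram(all_values, bins=bins)
    counts_lab, _ = np.histogram(values, bins=edges)
    occupied = counts_all > 0
    if occupied.sum() < 2:
        raise FitError("fewer than 2 occupied histogram bins")
    if counts_lab[occupied].sum() == 0:
        raise FitError("labeled values fall in no occupied bin of the cohort histogram")
    centers = 0.5 * (edges[:-1] + edges[1:])
    grades = counts_lab[occupied] / counts_all[occupied]
    return centers[occupied], np.clip(grades, 0.0, 1.0)


def _fit_polynomial(centers: np.ndarray, grades: np.ndarray, order: int) -> tuple[dict, float]:
    deg = max(1, min(order, len(centers) - 1))
    poly = np.polynomial.Polynomial.fit(centers, grades, deg).convert()
    params = {"coeffs": [float(c) for c in poly.coef]}
    pred = np.clip(np.polynomial.polynomial.polyval(centers, poly.coef), 0.0, 1.0)
    return params, float(np.sum((pred - grades) ** 2))


def _fit_s_type(centers: np.ndarray, grades: np.ndarray) -> tuple[dict, float]:
    span = centers.max() - centers.min()
    if span == 0:
        raise FitError("degenerate bin centers for s_type fit")
    # initial turning point: where the grade crosses 0.5; slope sign from trend
    b0 = centers[int(np.argmin(np.abs(grades - 0.5)))]
    trend = np.polyfit(centers, grades, 1)[0]
    a0 = math.copysign(4.0 / span, trend if trend != 0 else 1.0)
    try:
        popt, _ = curve_fit(
            lambda s, a, b: expit(a * (s - b)),
            centers, grades, p0=[a0, b0], maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"s_type fit failed: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    if a == 0.0:
        raise FitError("s_type fit degenerated to zero slope")
    pred = expit(a * (centers - b))
    return {"a": a, "b": b}, float(np.sum((pred - grades) ** 2))


def _fit_quasi_gaussian(centers: np.ndarray, grades: np.ndarray) -> tuple[dict, float]:
    span = centers.max() - centers.min()
    if span == 0:
        raise FitError("degenerate bin centers for quasi_gaussian fit")
    a0 = centers[int(np.argmax(grades))]
    d0 = span / 4.0
    try:
        popt, _ = curve_fit(
            lambda s, a, d: np.exp(-(((s - a) / (2.0 * d)) ** 2)),
            centers, grades, p0=[a0, d0],
            bounds=([centers.min() - span, 1e-9], [centers.max() + span, 10 * span + 1e-9]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"quasi_gaussian fit failed: {exc}") from exc
    a, d = float(popt[0]), float(popt[1])
    pred = np.exp(-(((centers - a) / (2.0 * d)) ** 2))
    return {"a": a, "d": d}, float(np.sum((pred - grades) ** 2))


_FITTERS = {
    "polynomial": lambda c, g, order: _fit_polynomial(c, g, order),
    "s_type": lambda c, g, order: _fit_s_type(c, g),
    "quasi_gaussian": lambda c, g, order: _fit_quasi_gaussian(c, g),
}


def select_kind(centers: Sequence[float], grades: Sequence[float], order: int = 3) -> str:
    """Family with the lowest residual sum of squares on the grade curve.

    Ties (and near-ties within 1e-12) resolve in the order polynomial <
    s_type < quasi_gaussian.  Raises :class:`FitError` if every family
    fails to fit.
    """
    centers = np.asarray(centers, dtype=float)
    grades = np.asarray(grades, dtype=float)
    if len(centers) < 5:
        raise FitError(f"need at least 5 occupied bins to select a family, got {len(centers)}")
    best: tuple[float, int, str] | None = None
    failures = []
    for rank, kind in enumerate(KINDS):
        try:
            _, rss = _FITTERS[kind](centers, grades, order)
        except FitError as exc:
            failures.append(f"{kind}: {exc}")
            continue
        if best is None or rss < best[0] - 1e-12:
            best = (rss, rank, kind)
    if best is None:
        raise FitError("all membership-function families failed to fit: " + "; ".join(failures))
    return best[2]


def fit_mf(
    values: Sequence[float],
    all_values: Sequence[float],
    kind: str | None = None,
    bins: int | None = None,
    *,
    symptom: str = "",
    hypothesis: str = "",
    order: int = 3,
    min_fit_count: int = MIN_FIT_COUNT,
) -> MembershipFunction:
    """Fit one membership function from labeled and cohort-wide samples.

    *values* are the symptom values among records labeled with the
    hypothesis; *all_values* the cohort-wide sample.  With ``kind=None``
    the family is chosen by :func:`select_kind`.
    """
    values = np.asarray(values, dtype=float)
    all_values = np.asarray(all_values, dtype=float)
    if len(values) < min_fit_count:
        raise FitError(
            f"too few labeled samples to fit a membership function: "
            f"{len(values)} < {min_fit_count}"
        )
    if np.ptp(all_values) == 0 or np.ptp(values) == 0:
        raise FitError("degenerate sample: all values equal")
    centers, grades = bin_grades(values, all_values, bins)
    if kind is None:
        kind = select_kind(centers, grades, order)
    if kind not in KINDS:
        raise ConfigError(f"unknown membership-function kind {kind!r}")
    params, _ = _FITTERS[kind](centers, grades, order)
    support = (float(all_values.min()), float(all_values.max()))
    return MembershipFunction(kind=kind, symptom=symptom, hypothesis=hypothesis,
                              params=params, support=support)


class MembershipSet:
    """Collection of membership functions keyed by (symptom, hypothesis)."""

    def __init__(self, mfs: Sequence[MembershipFunction] = ()):
        self._mfs: dict[tuple[str, str], MembershipFunction] = {}
        for mf in mfs:
            self.add(mf)

    def add(self, mf: MembershipFunction) -> None:
        self._mfs[(mf.symptom, mf.hypothesis)] = mf

    def get(self, symptom: str, hypothesis: str) -> MembershipFunction | None:
        return self._mfs.get((symptom, hypothesis))

    def __len__(self) -> int:
        return len(self._mfs)

    def __iter__(self):
        return iter(sorted(self._mfs.values(), key=lambda m: (m.symptom, m.hypothesis)))

    def to_yaml(self) -> str:
        return yaml.safe_dump([mf.to_dict() for mf in self], sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "MembershipSet":
        entries = yaml.safe_load(text)
        if entries is None:
            return cls()
        if not isinstance(entries, list):
            raise ConfigError("membership-function config must be a YAML list")
        return cls([MembershipFunction.from_dict(e) for e in entries])
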