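"""Hemodynamic parameters from sphygmogram (SPG) morphology.

The arterial pulse waveform is summarized by a handful of point and area
features per beat: systolic pressure ``Ps``, diastolic pressure ``Pd``,
mean pressure over the period ``P̄``, the areas under the systolic and
diastolic portions of the curve ``As``/``Ad``, and the cardiac period
``T``.  Under elastic-cavity (two-element windkessel) theory these solve
for several clinically useful hemodynamic parameters (HDPs):

- auxiliary blood pressure index  k = (P̄ − Pd) / (Ps − Pd)
- stroke volume                   SV = 0.28 · k² · T · (Ps − Pd)
- auxiliary sphygmogram index     η = 1 + As / Ad
- arterial compliance             AC = SV / (η · (Ps − Pd))
- peripheral resistance           R = (P̄ − Pv) / (SV · T)
- body-size factor                Q = 0.0061·L + 0.0128·Wt − 0.1592

Units are documented, not enforced: pressures in mmHg, areas in mmHg·s,
period in s, height in cm, weight in kg.  The constant 0.28 in the stroke
volume formula absorbs unit conversion.  Venous pressure ``Pv`` defaults
to 0, the usual approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError

__all__ = [
    "SPGFeatures",
    "HDPRecord",
    "compute_k",
    "compute_sv",
    "compute_eta",
    "compute_ac",
    "compute_r",
    "compute_q",
    "derive_hdps",
    "derive_frame",
    "read_features",
    "write_hdps",
]

FEATURE_COLUMNS = ["ps", "pd", "pbar", "a_s", "a_d", "period_T", "pv", "height_cm", "weight_kg"]
HDP_COLUMNS = ["k", "sv", "eta", "ac", "r", "q"]


@dataclass(frozen=True)
class SPGFeatures:
    """One beat's morphological features of the sphygmogram.

    Invariants are checked on construction: ``ps > pd``, ``period_T > 0``,
    nonnegative areas, and ``pd ≤ pbar ≤ ps``.
    """

    ps: float
    pd: float
    pbar: float
    a_s: float
    a_d: float
    period_T: float
    pv: float = 0.0

    def __post_init__(self):
        for name in ("ps", "pd", "pbar", "a_s", "a_d", "period_T", "pv"):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"SPG feature {name!r} must be finite")
        if self.ps <= self.pd:
            raise DomainError(f"systolic pressure ps={self.ps} must exceed diastolic pd={self.pd}")
        if self.period_T <= 0:
            raise DomainError(f"cardiac period period_T={self.period_T} must be positive")
        if self.a_s < 0 or self.a_d < 0:
            raise DomainError("SPG areas a_s and a_d must be nonnegative")
        if not (self.pd <= self.pbar <= self.ps):
            raise DomainError(
                f"mean pressure pbar={self.pbar} must lie within [pd={self.pd}, ps={self.ps}]"
            )


@dataclass(frozen=True)
class HDPRecord:
    """Derived hemodynamic parameters for one beat plus body-size factor."""

    k: float
    sv: float
    eta: float
    ac: float
    r: float
    q: float

    def __post_init__(self):
        for name in ("k", "sv", "eta", "ac", "r", "q"):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"HDP {name!r} is not finite")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in HDP_COLUMNS}


def compute_k(f: SPGFeatures) -> float:
    """Auxiliary blood pressure index k = (P̄ − Pd)/(Ps − Pd) ∈ [0, 1]."""
    if f.ps == f.pd:
        raise DomainError("ps equals pd: pulse pressure is zero, k undefined")
    return (f.pbar - f.pd) / (f.ps - f.pd)


def compute_sv(k: float, period_T: float, ps: float, pd: float) -> float:
    """Stroke volume SV = 0.28·k²·T·(Ps − Pd), mL per stroke."""
    if period_T <= 0:
        raise DomainError(f"period_T={period_T} must be positive")
    if ps <= pd:
        raise DomainError(f"ps={ps} must exceed pd={pd}")
    return 0.28 * k * k * period_T * (ps - pd)


def compute_eta(a_s: float, a_d: float) -> float:
    """Auxiliary sphygmogram index η = 1 + As/Ad ≥ 1."""
    if a_d == 0:
        raise DomainError("a_d is zero: auxiliary sphygmogram index undefined")
    return 1.0 + a_s / a_d


def compute_ac(sv: float, eta: float, ps: float, pd: float) -> float:
    """Arterial compliance AC = SV / (η·(Ps − Pd))."""
    if ps == pd:
        raise DomainError("ps equals pd: pulse pressure is zero, AC undefined")
    if eta == 0:
        raise DomainError("eta is zero: AC undefined")
    return sv / (eta * (ps - pd))


def compute_r(pbar: float, sv: float, period_T: float, pv: float = 0.0) -> float:
    """Peripheral resistance R = (P̄ − Pv)/(SV·T).

    With the default ``pv=0`` this is the printed approximation R ≈ P̄/(SV·T).
    """
    if sv == 0:
        raise DomainError("sv is zero: peripheral resistance undefined")
    if period_T == 0:
        raise DomainError("period_T is zero: peripheral resistance undefined")
    return (pbar - pv) / (sv * period_T)


def compute_q(height_cm: float, weight_kg: float) -> float:
    """Body-size factor Q = 0.0061·L + 0.0128·Wt − 0.1592 (L in cm, Wt in kg)."""
    if height_cm <= 0:
        raise DomainError(f"height_cm={height_cm} must be positive")
    if weight_kg <= 0:
        raise DomainError(f"weight_kg={weight_kg} must be positive")
    return 0.0061 * height_cm + 0.0128 * weight_kg - 0.1592


def derive_hdps(f: SPGFeatures, height_cm: float, weight_kg: float) -> HDPRecord:
    """Chain the scalar formulas into a full HDP record (deterministic)."""
    k = compute_k(f)
    sv = compute_sv(k, f.period_T, f.ps, f.pd)
    eta = compute_eta(f.a_s, f.a_d)
    ac = compute_ac(sv, eta, f.ps, f.pd)
    r = compute_r(f.pbar, sv, f.period_T, f.pv)
    q = compute_q(height_cm, weight_kg)
    return HDPRecord(k=k, sv=sv, eta=eta, ac=ac, r=r, q=q)


def derive_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Append HDP columns to a feature DataFrame (one row per beat).

    Expects the columns of :data:`FEATURE_COLUMNS`; a missing or empty
    ``pv`` column is read as 0.  Row-level failures name the offending row.
    """
    out = df.copy()
    if "pv" not in out.columns:
        out["pv"] = 0.0
    out["pv"] = out["pv"].fillna(0.0)
    derived: list[dict[str, float]] = []
    for idx, row in out.iterrows():
        try:
            feats = SPGFeatures(
                ps=float(row["ps"]),
                pd=float(row["pd"]),
                pbar=float(row["pbar"]),
                a_s=float(row["a_s"]),
                a_d=float(row["a_d"]),
                period_T=float(row["period_T"]),
                pv=float(row["pv"]),
            )
            rec = derive_hdps(feats, float(row["height_cm"]), float(row["weight_kg"]))
        except (KeyError, ValueError, DomainError) as exc:
            raise DomainError(f"row {idx}: {exc}") from exc
        derived.append(rec.as_dict())
    for col in HDP_COLUMNS:
        out[col] = [d[col] for d in derived]
    return out


def read_features(path) -> pd.DataFrame:
    """Read a feature CSV (header per :data:`FEATURE_COLUMNS`; ``#`` comments)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns and c != "pv"]
    if missing:
        raise DomainError(f"feature CSV missing columns: {', '.join(missing)}")
    return df


def write_hdps(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)
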