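"""SOD activity quantification from NBT-inhibition readings.

Superoxide generated by riboflavin photoreduction reduces nitro blue
tetrazolium (NBT); SOD in the extract inhibits that reduction. One unit
of SOD activity is the amount of enzyme giving 50% inhibition, so the
activity of an extract is 1/x50 units per amount-unit, with x50 found
by piecewise-linear interpolation of the (amount, %inhibition) curve.
Specific activity normalises by total protein from a Lowry standard
curve (OLS line of absorbance on concentration, inverted at the sample
absorbance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "InhibitionCurve",
    "ActivityResult",
    "ProteinEstimate",
    "percent_inhibition",
    "units_at_50_inhibition",
    "lowry_protein_conc",
    "specific_activity",
    "activity_table",
]


@dataclass(frozen=True)
class InhibitionCurve:
    """Enzyme amount vs percent inhibition observations (amounts increasing)."""

    amounts: tuple[float, ...]
    inhibition_pct: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.amounts) != len(self.inhibition_pct):
            raise ValueError("amounts and inhibition vectors differ in length")
        if len(self.amounts) < 2:
            raise ValueError("an inhibition curve needs at least 2 points")
        if any(b <= a for a, b in zip(self.amounts, self.amounts[1:])):
            raise ValueError("amounts must be strictly increasing")


@dataclass(frozen=True)
class ActivityResult:
    """Units per volume, protein concentration and specific activity."""

    sample_id: str
    units_per_volume: float      # U per uL extract
    protein_mg_per_ml: float
    specific_activity: float     # U per mg protein
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProteinEstimate:
    mg_per_ml: float
    extrapolated: bool

    def __float__(self) -> float:
        return self.mg_per_ml


def percent_inhibition(a_blank: float, a_sample: float) -> tuple[float, bool]:
    """100*(A_blank - A_sample)/A_blank, clamped to [0, 100].

    Returns (percent, clamped_flag); a clamp indicates assay noise
    (negative apparent inhibition) or readings beyond full inhibition.
    """
    if a_blank <= 0:
        raise ValueError(f"blank absorbance must be > 0, got {a_blank}")
    pct = 100.0 * (a_blank - a_sample) / a_blank
    if pct < 0.0:
        return 0.0, True
    if pct > 100.0:
        return 100.0, True
    return pct, False


def _tie_average(curve: InhibitionCurve) -> tuple[np.ndarray, np.ndarray]:
    amounts = np.asarray(curve.amounts, dtype=float)
    inhib = np.asarray(curve.inhibition_pct, dtype=float)
    # amounts are strictly increasing by construction; nothing to merge,
    # but accept raw arrays through the public helper below.
    return amounts, inhib


def units_at_50_inhibition(
    curve: InhibitionCurve | None = None,
    amounts: Sequence[float] | None = None,
    inhibition_pct: Sequence[float] | None = None,
) -> tuple[float, float]:
    """(x50, activity): enzyme amount at 50% inhibition and 1/x50 U per
    amount-unit, by linear interpolation between the bracketing points.

    Duplicate amounts are tie-averaged first. The curve must be
    non-decreasing after averaging and must bracket 50%.
    """
    if curve is None:
        if amounts is None or inhibition_pct is None:
            raise ValueError("give either a curve or amounts + inhibition_pct")
        df = pd.DataFrame({"a": list(amounts), "i": list(inhibition_pct)})
        merged = df.groupby("a", sort=True)["i"].mean()
        curve = InhibitionCurve(tuple(merged.index), tuple(merged.to_numpy()))
    x, y = _tie_average(curve)

    drops = np.where(np.diff(y) < 0)[0]
    if drops.size:
        i = int(drops[0])
        raise ValueError(
            f"non-monotone inhibition curve: {y[i + 1]:.3g}% at amount "
            f"{x[i + 1]:.4g} follows {y[i]:.3g}% at amount {x[i]:.4g}"
        )
    if y.min() > 50.0 or y.max() < 50.0:
        raise ValueError(
            f"50% inhibition not bracketed (observed range "
            f"{y.min():.3g}-{y.max():.3g}%)"
        )
    exact = np.where(y == 50.0)[0]
    if exact.size:
        x50 = float(x[exact].mean())
    else:
        j = int(np.searchsorted(y, 50.0))
        x0, x1, y0, y1 = x[j - 1], x[j], y[j - 1], y[j]
        x50 = float(x0 + (50.0 - y0) * (x1 - x0) / (y1 - y0))
    return x50, 1.0 / x50


def lowry_protein_conc(
    standards: Sequence[tuple[float, float]], sample_abs: float
) -> ProteinEstimate:
    """Protein concentration (mg/mL) from a Lowry standard line.

    ``standards`` are (concentration, absorbance) pairs, at least 3,
    ideally including a blank. The OLS line of absorbance on
    concentration is inverted at ``sample_abs``; a sample outside the
    standard absorbance range is flagged as extrapolated.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 Lowry standards")
    conc = np.asarray([c for c, _ in standards], dtype=float)
    ab = np.asarray([a for _, a in standards], dtype=float)
    if np.allclose(ab, ab[0]):
        raise ValueError("all standards have equal absorbance: cannot fit a line")
    fit = sps.linregress(conc, ab)
    if fit.slope <= 0:
        raise ValueError(f"non-positive Lowry slope {fit.slope:.3g}")
    value = (sample_abs - fit.intercept) / fit.slope
    extrapolated = not (ab.min() <= sample_abs <= ab.max())
    return ProteinEstimate(mg_per_ml=float(value), extrapolated=extrapolated)


def specific_activity(units: float, protein_mg: float) -> float:
    """Units of SOD activity per mg total protein."""
    if protein_mg <= 0:
        raise ValueError(f"protein must be > 0 mg, got {protein_mg}")
    return units / protein_mg


def activity_table(assay: pd.DataFrame, lowry: pd.DataFrame) -> pd.DataFrame:
    """Per-sample activity results from raw assay + Lowry tables.

    ``assay`` columns: sample_id, amount (uL extract), a_blank,
    a_sample. ``lowry`` columns: kind (standard|sample), sample_id,
    conc, absorbance; standards define the line, sample rows carry each
    extract's absorbance.
    """
    for col in ("sample_id", "amount", "a_blank", "a_sample"):
        if col not in assay.columns:
            raise ValueError(f"assay table lacks column {col!r}")
    standards = [
        (float(r.conc), float(r.absorbance))
        for r in lowry[lowry["kind"] == "standard"].itertuples()
    ]
    sample_abs = {
        str(r.sample_id): float(r.absorbance)
        for r in lowry[lowry["kind"] == "sample"].itertuples()
    }
    rows = []
    for sample_id, grp in assay.groupby("sample_id", sort=True):
        flags: list[str] = []
        pct = []
        for r in grp.itertuples():
            p, clamped = percent_inhibition(float(r.a_blank), float(r.a_sample))
            if clamped:
                flags.append(f"inhibition_clamped_at_amount_{r.amount:g}")
            pct.append(p)
        x50, units_per_ul = units_at_50_inhibition(
            amounts=grp["amount"].tolist(), inhibition_pct=pct
        )
        if str(sample_id) not in sample_abs:
            raise ValueError(f"no Lowry sample absorbance for {sample_id!r}")
        est = lowry_protein_conc(standards, sample_abs[str(sample_id)])
        if est.extrapolated:
            flags.append("lowry_extrapolated")
        # U/uL over mg/uL: protein mg/mL / 1000 = mg per uL
        spec = specific_activity(units_per_ul, est.mg_per_ml / 1000.0)
        rows.append(
            {
                "sample_id": str(sample_id),
                "x50_ul": x50,
                "units_per_ul": units_per_ul,
                "protein_mg_per_ml": est.mg_per_ml,
                "specific_activity_u_per_mg": spec,
                "flags": ";".join(sorted(set(flags))),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
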