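"""Relative qPCR quantification by the 2^-ddCt (Livak) method.

Cycle thresholds come in long format (sample x treatment x gene x
biological replicate x technical replicate). Technical replicates are
averaged; per biological replicate r, dCt = Ct_target - Ct_reference,
ddCt subtracts the calibrator cell's dCt of the *same* replicate
(pairing the three independent experiments), and RQ = 2^-ddCt. The
reference gene defaults to the ribosomal housekeeping gene rp49 and the
calibrator cell to the untreated naive/naive group.

Primer amplification efficiency is a separate QC: a dilution standard
curve is fit by ordinary least squares of Ct on log10 quantity and
efficiency = 10^(-1/slope) (2.0 = perfect doubling); curves with
efficiency > 1.9 pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CT_COLUMNS",
    "CtRecord",
    "StandardCurve",
    "read_ct_table",
    "average_technical_reps",
    "collapse_technical",
    "relative_expression",
    "standard_curve_efficiency",
]

logger = logging.getLogger(__name__)

CT_COLUMNS = ["sample_id", "priming", "challenge", "gene", "bio_rep", "tech_rep", "ct"]

#: Technical replicates further apart than this (cycles) are flagged.
TECH_REP_TOLERANCE = 0.5


@dataclass(frozen=True)
class CtRecord:
    """A single raw cycle-threshold observation."""

    sample_id: str
    priming: str
    challenge: str
    gene: str
    bio_rep: int
    tech_rep: int
    ct: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"{self.sample_id}/{self.gene}: Ct must be finite and > 0")


@dataclass(frozen=True)
class StandardCurve:
    """A primer dilution series fit: Ct = slope * log10(quantity) + intercept."""

    log10_quantity: tuple[float, ...]
    ct: tuple[float, ...]
    slope: float
    intercept: float
    r2: float
    efficiency: float

    @property
    def qc_pass(self) -> bool:
        return self.efficiency > 1.9


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format Ct CSV."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table {path} lacks columns: {missing}")
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        raise ValueError(f"Ct table {path} contains non-finite or non-positive Ct")
    return df


def average_technical_reps(records: Sequence[CtRecord]) -> tuple[float, bool]:
    """Arithmetic-mean Ct of technical replicates of one sample x gene.

    The flag is True when the replicate spread exceeds
    :data:`TECH_REP_TOLERANCE` cycles. Replicates are never dropped.
    """
    if not records:
        raise ValueError("no technical replicates given")
    keys = {(r.sample_id, r.gene, r.bio_rep) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple sample/gene groups: {sorted(keys)}")
    cts = [r.ct for r in records]
    return float(np.mean(cts)), (max(cts) - min(cts)) > TECH_REP_TOLERANCE


def collapse_technical(ct: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates per (priming, challenge, gene, bio_rep).

    Returns a frame with columns priming/challenge/gene/bio_rep/ct/flagged.
    """
    grouped = ct.groupby(["priming", "challenge", "gene", "bio_rep"], sort=True)["ct"]
    out = grouped.agg(
        ct="mean", spread=lambda x: x.max() - x.min()
    ).reset_index()
    out["flagged"] = out.pop("spread") > TECH_REP_TOLERANCE
    return out


def relative_expression(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "rp49",
    calibrator: tuple[str, str] = ("naive", "naive"),
    per_replicate: bool = True,
) -> pd.DataFrame:
    """2^-ddCt relative expression of ``target_gene`` per treatment cell.

    Returns one row per (priming, challenge) with per-replicate RQ
    values, their mean and standard error (sd/sqrt(n), RQ scale). With
    ``per_replicate=False`` (pooled mode) every ddCt subtracts the
    calibrator's mean dCt instead of the matched replicate's.
    """
    tech = collapse_technical(ct)
    ref = tech[tech["gene"] == reference_gene].set_index(
        ["priming", "challenge", "bio_rep"]
    )["ct"]
    tgt = tech[tech["gene"] == target_gene]
    if tgt.empty:
        raise ValueError(f"no Ct rows for target gene {target_gene!r}")
    if ref.empty:
        raise ValueError(f"no Ct rows for reference gene {reference_gene!r}")

    idx = pd.MultiIndex.from_frame(tgt[["priming", "challenge", "bio_rep"]])
    ref_ct = ref.reindex(idx)
    if ref_ct.isna().any():
        missing = [tuple(k) for k in idx[ref_ct.isna().to_numpy()]]
        raise ValueError(
            f"missing reference ({reference_gene}) Ct for cells/replicates: {missing}"
        )
    dct = pd.Series(tgt["ct"].to_numpy() - ref_ct.to_numpy(), index=idx, name="dct")

    cal_p, cal_c = calibrator
    try:
        cal = dct.xs((cal_p, cal_c), level=("priming", "challenge"))
    except KeyError:
        raise ValueError(f"calibrator cell {calibrator} absent from Ct table")
    cal_by_rep = cal.groupby(level="bio_rep").mean()
    cal_mean = float(cal.mean())

    rows = []
    for (priming, challenge), cell in dct.groupby(level=("priming", "challenge"), sort=True):
        rqs = []
        for (_, _, rep), d in cell.items():
            if per_replicate:
                if rep in cal_by_rep.index:
                    base = float(cal_by_rep.loc[rep])
                else:
                    logger.warning(
                        "calibrator replicate %s missing for cell %s/%s; "
                        "falling back to calibrator mean dCt",
                        rep, priming, challenge,
                    )
                    base = cal_mean
            else:
                base = cal_mean
            rqs.append(2.0 ** -(d - base))
        rq = np.asarray(rqs, dtype=float)
        rows.append(
            {
                "gene": target_gene,
                "priming": priming,
                "challenge": challenge,
                "n": len(rq),
                "rq_mean": float(rq.mean()),
                "rq_se": float(rq.std(ddof=1) / np.sqrt(len(rq))) if len(rq) > 1 else 0.0,
                "rq_per_rep": tuple(float(x) for x in rq),
            }
        )
    return pd.DataFrame(rows)


def standard_curve_efficiency(
    log10_quantity: Sequence[float], ct: Sequence[float]
) -> StandardCurve:
    """Primer efficiency from a dilution series (OLS of Ct on log10 qty)."""
    x = np.asarray(log10_quantity, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size != y.size:
        raise ValueError("quantity and Ct vectors differ in length")
    if x.size < 3:
        raise ValueError("a standard curve needs at least 3 dilution points")
    d = np.diff(x)
    if not ((d > 0).all() or (d < 0).all()):
        raise ValueError("dilution quantities must be strictly ordered")
    fit = sps.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"non-amplifying standard curve: slope {fit.slope:.3f} >= 0"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope)
    return StandardCurve(
        log10_quantity=tuple(map(float, x)),
        ct=tuple(map(float, y)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        efficiency=float(efficiency),
    )
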