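"""Physicochemical phospholipidosis (DIPL) risk scoring.

Cationic amphiphilic drugs — a basic amine plus a hydrophobic ring system —
are the classic inducers of drug-induced phospholipidosis.  A widely used
screening heuristic scores a compound as ``pKa^2 + cLogP^2`` (pKa of the most
basic center): high scores flag DIPL propensity, low scores predict none,
and scores inside the band (75, 85) are not reliably predictive either way.
Only the band itself is encoded here (endpoints configurable); per-parameter
cutoffs from the wider literature, and computing pKa/cLogP from structure,
are out of scope — values are user supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import InvalidParameterError, SchemaError

__all__ = ["CompoundRecord", "RiskScore", "dipl_score", "score_table", "DEFAULT_BAND"]

#: inconclusive band: 75 < score < 85 is not reliably predictive
DEFAULT_BAND = (75.0, 85.0)

REQUIRED_COLUMNS = ("name", "pKa", "cLogP")


@dataclass(frozen=True)
class CompoundRecord:
    """A compound's name, basic-center pKa (0-14) and cLogP."""

    name: str
    pKa: float
    cLogP: float

    def __post_init__(self):
        if not (math.isfinite(self.pKa) and math.isfinite(self.cLogP)):
            raise InvalidParameterError(f"{self.name!r}: pKa and cLogP must be finite")
        if not 0.0 <= self.pKa <= 14.0:
            raise InvalidParameterError(f"{self.name!r}: pKa must lie in [0, 14], got {self.pKa}")


@dataclass(frozen=True)
class RiskScore:
    """The score pKa^2 + cLogP^2 and its zone relative to the inconclusive band.

    Zones: ``below_band`` (score <= lower endpoint, DIPL unlikely),
    ``above_band`` (score >= upper endpoint, DIPL-prone), ``inconclusive``
    in between.  The strict inequalities of the published band
    (85 > score > 75) put the endpoints themselves in the conclusive zones.
    """

    score: float
    zone: str
    band: tuple[float, float] = DEFAULT_BAND


def dipl_score(record: CompoundRecord, band: tuple[float, float] = DEFAULT_BAND) -> RiskScore:
    """Score one compound and classify it against the inconclusive band."""
    lo, hi = band
    if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
        raise InvalidParameterError(f"band must be finite with band[0] < band[1], got {band}")
    score = record.pKa ** 2 + record.cLogP ** 2
    if score >= hi:
        zone = "above_band"
    elif score <= lo:
        zone = "below_band"
    else:
        zone = "inconclusive"
    return RiskScore(score=float(score), zone=zone, band=(float(lo), float(hi)))


def score_table(
    table: pd.DataFrame | str,
    band: tuple[float, float] = DEFAULT_BAND,
    out_path: str | None = None,
) -> pd.DataFrame:
    """Annotate a compound table (DataFrame or CSV path) with score and zone.

    Requires columns ``name``, ``pKa``, ``cLogP``; all other columns and the
    row order are preserved.  Writes a CSV when ``out_path`` is given.
    """
    df = pd.read_csv(table) if isinstance(table, str) else table.copy()
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"compound table is missing required column {col!r}")
    scores, zones = [], []
    for _, row in df.iterrows():
        rs = dipl_score(CompoundRecord(str(row["name"]), float(row["pKa"]), float(row["cLogP"])), band)
        scores.append(rs.score)
        zones.append(rs.zone)
    df["dipl_score"] = scores
    df["dipl_zone"] = zones
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
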