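"""Risk-allele orientation.

Score construction requires every variant's effect to point in the direction
of disease risk.  A variant whose estimated OR is below 1 is flipped: alleles
swapped, OR and CI inverted together, per-group frequencies complemented.
The per-variant weight is ``ln`` of the risk-oriented OR, hence always >= 0.
An OR of exactly 1 is left unflipped with weight 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .datamodel import GenotypeMatrix

__all__ = ["RiskOrientedVariant", "orient_to_risk", "orient_panel", "dosage_flip"]


@dataclass(frozen=True)
class RiskOrientedVariant:
    """A variant re-expressed on its risk allele (OR >= 1)."""

    rsid: str
    risk_allele: str
    non_risk_allele: str
    or_risk: float
    ci_low: float
    ci_high: float
    raf_case: float
    raf_control: float
    weight: float
    flipped: bool


def orient_to_risk(
    rsid: str,
    effect_allele: str,
    other_allele: str,
    or_: float,
    ci_low: float,
    ci_high: float,
    eaf_case: float,
    eaf_control: float,
) -> RiskOrientedVariant:
    """Re-orient one association result so the effect allele is the risk allele.

    If ``or_ >= 1`` the record passes through unflipped.  If ``or_ < 1`` the
    alleles are swapped, OR -> 1/OR, CI -> (1/ci_high, 1/ci_low) and each
    frequency -> 1 - frequency.  Inverting the CI together with the OR keeps
    the invariant ``ci_low <= or_risk <= ci_high``.  Idempotent.
    """
    if not or_ > 0:
        raise ValueError(f"{rsid}: OR must be positive, got {or_}")
    if or_ >= 1.0:
        return RiskOrientedVariant(
            rsid=rsid,
            risk_allele=effect_allele,
            non_risk_allele=other_allele,
            or_risk=or_,
            ci_low=ci_low,
            ci_high=ci_high,
            raf_case=eaf_case,
            raf_control=eaf_control,
            weight=math.log(or_),
            flipped=False,
        )
    return RiskOrientedVariant(
        rsid=rsid,
        risk_allele=other_allele,
        non_risk_allele=effect_allele,
        or_risk=1.0 / or_,
        ci_low=1.0 / ci_high if ci_high > 0 else float("nan"),
        ci_high=1.0 / ci_low if ci_low > 0 else float("inf"),
        raf_case=1.0 - eaf_case,
        raf_control=1.0 - eaf_control,
        weight=-math.log(or_),
        flipped=True,
    )


ORIENTED_COLUMNS = [
    "rsid", "risk_allele", "non_risk_allele", "or_risk", "ci_low", "ci_high",
    "raf_case", "raf_control", "weight", "flipped",
]


def orient_panel(assoc: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`orient_to_risk` to every row of an association table.

    Monomorphic rows (OR fixed at 1) come through with weight 0.
    """
    oriented = [
        orient_to_risk(
            rsid=row.rsid,
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            or_=row.or_,
            ci_low=row.ci_low,
            ci_high=row.ci_high,
            eaf_case=row.eaf_case,
            eaf_control=row.eaf_control,
        )
        for row in assoc.itertuples()
    ]
    return pd.DataFrame([vars(v) for v in oriented], columns=ORIENTED_COLUMNS)


def write_oriented_panel(oriented: pd.DataFrame, path: str | Path) -> None:
    oriented.to_csv(path, sep="\t", index=False, na_rep="NA")


def dosage_flip(matrix: GenotypeMatrix, rsid: str) -> GenotypeMatrix:
    """Return a matrix with the named variant's dosage replaced by ``2 - g``.

    Missing entries stay missing (NaN arithmetic); the variant record's
    alleles are swapped so the dosage still counts the (new) effect allele.
    Applying the flip twice restores the original matrix.
    """
    j = matrix.variant_index(rsid)  # KeyError for unknown variants
    out = matrix.copy()
    out.dosages[:, j] = 2.0 - out.dosages[:, j]
    out.variants[j] = out.variants[j].swapped()
    return out
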