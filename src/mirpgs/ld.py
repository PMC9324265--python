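"""Pairwise linkage disequilibrium from dosages and greedy r² pruning.

LD is measured as the squared Pearson correlation of allele-dosage vectors
over pairwise-complete samples — the composite-LD estimator, which needs no
phase information.  Pruning is greedy: variants are scanned in a priority
order (by default ascending association p-value) and kept only if their r²
with every already-kept variant stays at or below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix
from .errors import UndefinedLdError

__all__ = ["dosage_r2", "ld_matrix", "LdMatrix", "greedy_prune", "PruneResult",
           "priority_by_pvalue"]


def dosage_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries (NaN) are dropped pairwise.  Requires at least two
    complete pairs and non-zero variance in both vectors on that subset.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = np.isfinite(g1) & np.isfinite(g2)
    x, y = g1[ok], g2[ok]
    if x.size < 2:
        raise UndefinedLdError(f"only {x.size} complete pairs; need >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedLdError("zero dosage variance on the pairwise-complete subset")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


@dataclass
class LdMatrix:
    """Symmetric r² matrix with pairwise-complete sample counts."""

    r2: pd.DataFrame     # rsid x rsid, diagonal exactly 1
    n_pairs: pd.DataFrame

    @property
    def rsids(self) -> list[str]:
        return list(self.r2.index)

    def to_tsv(self, path: str | Path) -> None:
        self.r2.to_csv(path, sep="\t", na_rep="NA")


def ld_matrix(matrix: GenotypeMatrix, subset: str = "all") -> LdMatrix:
    """All-pairs dosage r² over the given sample subset.

    Correlations use pairwise-complete observations (pandas ``corr``); a
    pair with undefined correlation (zero variance or < 2 complete pairs)
    gets NaN off the diagonal.  The diagonal is set to exactly 1.
    """
    mask = matrix.group_mask(subset)
    df = pd.DataFrame(matrix.dosages[mask], columns=matrix.rsids)
    r = df.corr(min_periods=2)
    r2 = (r * r).clip(upper=1.0)
    np.fill_diagonal(r2.values, 1.0)
    notna = df.notna().to_numpy().astype(float)
    n_pairs = pd.DataFrame(
        notna.T @ notna, index=matrix.rsids, columns=matrix.rsids
    ).astype(int)
    return LdMatrix(r2=r2, n_pairs=n_pairs)


def priority_by_pvalue(assoc: pd.DataFrame) -> list[str]:
    """Default prune priority: ascending p, ties by chromosome then position."""
    def chrom_key(c: str):
        return (0, int(c)) if str(c).isdigit() else (1, str(c))

    order = sorted(
        assoc.itertuples(),
        key=lambda row: (row.p, chrom_key(row.chrom), row.pos),
    )
    return [row.rsid for row in order]


@dataclass
class PruneResult:
    """Outcome of greedy LD pruning."""

    kept: list[str]
    log: pd.DataFrame  # rsid, kept, excluded_by, r2
    threshold: float

    @property
    def dropped(self) -> list[str]:
        return self.log.loc[~self.log["kept"], "rsid"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.log.to_csv(path, sep="\t", index=False, na_rep="NA")


def greedy_prune(
    ld: LdMatrix,
    priority: Sequence[str],
    threshold: float = 0.2,
) -> PruneResult:
    """Greedy pruning at an r² threshold.

    Variants are scanned in ``priority`` order; a variant is kept iff its r²
    with every already-kept variant is <= ``threshold`` (strict exclusion:
    r² must *exceed* the threshold to drop).  Each dropped variant records
    the kept partner that excluded it.  Deterministic given the priority,
    and invariant to the column order of the LD matrix.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if set(priority) != set(ld.rsids) or len(priority) != len(ld.rsids):
        raise ValueError("priority must be a total order over the LD matrix variants")
    kept: list[str] = []
    rows = []
    for rsid in priority:
        partner, worst = None, -1.0
        for k in kept:
            r2 = ld.r2.at[rsid, k]
            if np.isfinite(r2) and r2 > threshold and r2 > worst:
                partner, worst = k, float(r2)
        if partner is None:
            kept.append(rsid)
            rows.append({"rsid": rsid, "kept": True, "excluded_by": "", "r2": float("nan")})
        else:
            rows.append({"rsid": rsid, "kept": False, "excluded_by": partner, "r2": worst})
    log = pd.DataFrame(rows).set_index("rsid").loc[ld.rsids].reset_index()
    return PruneResult(kept=kept, log=log, threshold=threshold)
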