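"""Variant-level quality control: call rate and Hardy-Weinberg screening.

HWE is assessed with the 1-df chi-square goodness-of-fit test comparing the
observed genotype counts with the counts expected from the allele
frequencies.  Following standard case-control practice the test is run in
controls only by default, since true disease association distorts genotype
proportions among cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenotypeMatrix
from .errors import EmptyInputError

__all__ = ["call_rate", "hwe_test", "apply_qc", "QcReport"]


def call_rate(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-variant fraction of non-missing genotype calls."""
    if matrix.n_samples == 0:
        raise EmptyInputError("call rate undefined for a matrix with no samples")
    return np.isfinite(matrix.dosages).mean(axis=0)


def hwe_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> tuple[float, float]:
    """Chi-square (1 df) goodness-of-fit test for Hardy-Weinberg equilibrium.

    Parameters are observed genotype counts: effect-allele homozygotes,
    heterozygotes, other-allele homozygotes.  The expected counts are
    ``n*p^2, 2n*p*q, n*q^2`` with ``p`` the observed effect-allele
    frequency.  A monomorphic variant fits its (degenerate) expectation
    exactly and returns ``(0.0, 1.0)``.
    """
    counts = (n_hom_effect, n_het, n_hom_other)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        raise EmptyInputError("HWE test needs at least one genotype")
    p = (2 * n_hom_effect + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array(counts, dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class QcReport:
    """Per-variant QC statistics plus the overall mean call rate.

    ``table`` columns: rsid, call_rate, hwe_chi2, hwe_p, pass, reason
    (empty string for passing variants, else "call_rate", "hwe" or
    "call_rate,hwe").
    """

    table: pd.DataFrame
    mean_call_rate: float
    call_rate_min: float
    hwe_p_min: float
    hwe_subset: str

    @property
    def n_pass(self) -> int:
        return int(self.table["pass"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def apply_qc(
    matrix: GenotypeMatrix,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-3,
    hwe_subset: str = "control",
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop variants failing call-rate or HWE thresholds.

    Returns the filtered matrix (possibly with zero variants — the report
    flags that) and a :class:`QcReport` listing both statistics and the
    exclusion reason for every input variant.  Idempotent: the surviving
    variants pass both criteria by construction.
    """
    for name, thr in (("call_rate_min", call_rate_min), ("hwe_p_min", hwe_p_min)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")

    rates = call_rate(matrix)
    hwe_mask = matrix.group_mask(hwe_subset)
    rows = []
    for j, v in enumerate(matrix.variants):
        g = matrix.dosages[hwe_mask, j]
        g = g[np.isfinite(g)]
        if g.size == 0:
            chi2, p = 0.0, 1.0  # nothing to test against; call rate will catch it
        else:
            chi2, p = hwe_test(int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum()))
        reasons = []
        if rates[j] < call_rate_min:
            reasons.append("call_rate")
        if p < hwe_p_min:
            reasons.append("hwe")
        rows.append(
            {
                "rsid": v.rsid,
                "call_rate": float(rates[j]),
                "hwe_chi2": chi2,
                "hwe_p": p,
                "pass": not reasons,
                "reason": ",".join(reasons),
            }
        )
    table = pd.DataFrame(rows)
    report = QcReport(
        table=table,
        mean_call_rate=float(rates.mean()) if len(rates) else float("nan"),
        call_rate_min=call_rate_min,
        hwe_p_min=hwe_p_min,
        hwe_subset=hwe_subset,
    )
    kept = table.loc[table["pass"], "rsid"].tolist()
    return matrix.subset_variants(kept), report
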