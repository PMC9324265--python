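"""Polygenic score construction and score-level association.

A score model is an ordered set of (rsid, risk allele, weight) triples.  The
weighted model uses ``ln`` of the risk-oriented per-variant OR as weight; the
unweighted model sets every weight to 1, so the score is the plain
risk-allele count.  The per-sample raw score is the weighted sum of
risk-allele dosages; missing genotypes are imputed with the variant's mean
risk-allele dosage (or, in strict mode, the sample is dropped).  Scores are
standardised against the pooled (cases + controls) mean and SD, and the
score-level effect is reported as an odds ratio per standard deviation of
the score from a logistic regression on the standardised score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import Z_95, fit_logistic, _covariate_frame
from .datamodel import GenotypeMatrix
from .errors import AlleleMismatchError, DegenerateScoreError, MissingVariantError

__all__ = [
    "PGSModel",
    "ScoreResult",
    "build_weighted_model",
    "build_unweighted_model",
    "compute_pgs",
    "pgs_association",
    "PgsAssociation",
]


@dataclass
class PGSModel:
    """Ordered (rsid, risk_allele, weight) triples plus the model mode."""

    entries: pd.DataFrame  # columns rsid, risk_allele, weight
    mode: str              # "weighted" | "unweighted"

    def __post_init__(self) -> None:
        required = {"rsid", "risk_allele", "weight"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"model entries need columns {sorted(required)}")
        if self.mode not in ("weighted", "unweighted"):
            raise ValueError(f"mode must be 'weighted' or 'unweighted', got {self.mode!r}")
        if self.mode == "unweighted" and not (self.entries["weight"] == 1.0).all():
            raise ValueError("unweighted model must have every weight equal to 1")
        if self.mode == "weighted" and (self.entries["weight"] < 0).any():
            raise ValueError("weighted model weights must be >= 0 (risk-oriented)")

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, mode: str) -> "PGSModel":
        return cls(entries=pd.read_csv(path, sep="\t"), mode=mode)


def _restrict(oriented: pd.DataFrame, kept: Sequence[str] | None) -> pd.DataFrame:
    if kept is None:
        return oriented
    return oriented.set_index("rsid").loc[list(kept)].reset_index()


def build_weighted_model(
    oriented: pd.DataFrame,
    kept: Sequence[str] | None = None,
    weight_scale: str = "log_or",
) -> PGSModel:
    """Weighted score model from a risk-oriented panel (post-pruning).

    ``weight_scale="log_or"`` (default) uses ``ln`` of the oriented OR;
    ``"or"`` uses the OR itself, kept as a sensitivity switch.
    """
    panel = _restrict(oriented, kept)
    if weight_scale == "log_or":
        weights = panel["weight"].to_numpy(dtype=float)
    elif weight_scale == "or":
        weights = panel["or_risk"].to_numpy(dtype=float)
    else:
        raise ValueError(f"weight_scale must be 'log_or' or 'or', got {weight_scale!r}")
    entries = pd.DataFrame(
        {"rsid": panel["rsid"], "risk_allele": panel["risk_allele"], "weight": weights}
    )
    return PGSModel(entries=entries, mode="weighted")


def build_unweighted_model(
    oriented: pd.DataFrame, kept: Sequence[str] | None = None
) -> PGSModel:
    """Unweighted model: risk orientation retained, every weight 1."""
    panel = _restrict(oriented, kept)
    entries = pd.DataFrame(
        {"rsid": panel["rsid"], "risk_allele": panel["risk_allele"], "weight": 1.0}
    )
    return PGSModel(entries=entries, mode="unweighted")


@dataclass
class ScoreResult:
    """Per-sample raw and standardised scores.

    ``table`` columns: sample_id, raw, standardized, n_imputed.  The
    standardised score has mean 0 and SD 1 over the scored samples.
    """

    table: pd.DataFrame
    model_mode: str
    mean_raw: float
    sd_raw: float
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def raw(self) -> np.ndarray:
        return self.table["raw"].to_numpy()

    @property
    def standardized(self) -> np.ndarray:
        return self.table["standardized"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compute_pgs(
    matrix: GenotypeMatrix,
    model: PGSModel,
    missing: str = "mean",
) -> ScoreResult:
    """Per-sample polygenic score under ``model``.

    The model's risk allele is aligned to each matrix variant explicitly:
    when it equals the variant's effect allele the dosage is used as is;
    when it equals the other allele the dosage ``2 - g`` is used.  Missing
    genotypes are imputed with the variant's mean risk-allele dosage over
    non-missing samples (``missing="mean"``) or cause the sample to be
    dropped (``missing="strict"``); the per-sample imputation count is
    recorded either way.
    """
    if missing not in ("mean", "strict"):
        raise ValueError(f"missing must be 'mean' or 'strict', got {missing!r}")
    absent = [r for r in model.entries["rsid"] if r not in set(matrix.rsids)]
    if absent:
        raise MissingVariantError(f"model variants absent from matrix: {absent}")

    n = matrix.n_samples
    aligned = np.empty((n, len(model)), dtype=float)
    for k, entry in enumerate(model.entries.itertuples()):
        v = matrix.variant(entry.rsid)
        g = matrix.dosage_vector(entry.rsid)
        if entry.risk_allele == v.effect_allele:
            aligned[:, k] = g
        elif entry.risk_allele == v.other_allele:
            aligned[:, k] = 2.0 - g
        else:
            raise AlleleMismatchError(
                f"{entry.rsid}: model risk allele {entry.risk_allele!r} matches "
                f"neither {v.effect_allele!r} nor {v.other_allele!r}"
            )

    missing_mask = ~np.isfinite(aligned)
    n_imputed = missing_mask.sum(axis=1)
    weights = model.entries["weight"].to_numpy(dtype=float)

    dropped: list[str] = []
    if missing == "strict":
        keep = n_imputed == 0
        dropped = [sid for sid, k in zip(matrix.sample_ids, keep) if not k]
        aligned = aligned[keep]
        sample_ids = [sid for sid, k in zip(matrix.sample_ids, keep) if k]
        n_imputed = n_imputed[keep]
    else:
        col_means = np.nanmean(aligned, axis=0)
        aligned = np.where(missing_mask, col_means[np.newaxis, :], aligned)
        sample_ids = list(matrix.sample_ids)

    raw = aligned @ weights
    mean = float(raw.mean()) if raw.size else float("nan")
    sd = float(raw.std()) if raw.size else float("nan")
    standardized = (raw - mean) / sd if raw.size and sd > 0 else np.zeros_like(raw)
    table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "raw": raw,
            "standardized": standardized,
            "n_imputed": n_imputed.astype(int),
        }
    )
    return ScoreResult(
        table=table, model_mode=model.mode, mean_raw=mean, sd_raw=sd,
        dropped_samples=dropped,
    )


@dataclass(frozen=True)
class PgsAssociation:
    """Score-level logistic association: OR per 1 SD of the score."""

    or_per_sd: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    n: int
    covariates: tuple[str, ...]


def pgs_association(
    scores: ScoreResult,
    matrix: GenotypeMatrix,
    covariates: Sequence[str] = (),
) -> PgsAssociation:
    """Logistic regression of case status on the standardised score.

    Returns the odds ratio per standard deviation of the score with its
    Wald 95% CI and p-value.  Covariates (age/sex/ethnicity) are expanded
    exactly as in the per-variant models; rows with missing covariates are
    dropped complete-case.
    """
    matrix.require_status()
    by_id = {s: i for i, s in enumerate(matrix.sample_ids)}
    idx = np.array([by_id[s] for s in scores.table["sample_id"]])
    z = scores.standardized
    if np.ptp(z) == 0:
        raise DegenerateScoreError("score has zero variance; per-SD OR undefined")
    y = matrix.case_mask.astype(float)[idx]
    cov = _covariate_frame(matrix, covariates)
    if cov.empty:
        cov_values = np.empty((len(idx), 0))
        use = np.ones(len(idx), dtype=bool)
        names: list[str] = []
    else:
        cov_values = cov.to_numpy()[idx]
        use = ~np.isnan(cov_values).any(axis=1)
        names = list(cov.columns)
    X = np.column_stack([np.ones(use.sum()), z[use], cov_values[use]])
    beta, se, _ = fit_logistic(
        y[use], X, column_names=["intercept", "pgs", *names]
    )
    b, s = float(beta[1]), float(se[1])
    return PgsAssociation(
        or_per_sd=math.exp(b),
        ci_low=math.exp(b - Z_95 * s),
        ci_high=math.exp(b + Z_95 * s),
        p=float(2 * stats.norm.sf(abs(b / s))),
        beta=b,
        se=s,
        n=int(use.sum()),
        covariates=tuple(covariates),
    )
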