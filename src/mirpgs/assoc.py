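"""Per-variant case-control association under the log-additive model.

Each variant is tested by logistic regression of case status on effect-allele
dosage (0/1/2), optionally adjusted for age, sex and ethnicity, so one copy
of the effect allele multiplies the disease odds by ``exp(beta)``.  Wald 95%
confidence intervals and p-values match the OR-with-CI presentation used in
candidate-gene association tables; a closed-form allelic (2 x 2 allele count)
odds ratio with a Woolf CI is provided as an independent contrast.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .datamodel import GenotypeMatrix
from .errors import (
    BoundaryFrequencyError,
    CollinearityError,
    DegenerateOutcomeError,
    EmptyInputError,
)

__all__ = [
    "fit_logistic",
    "snp_association",
    "allelic_or",
    "bonferroni_threshold",
    "write_association_table",
]

#: Wald multiplier for a 95% confidence interval (fixed by convention).
Z_95 = 1.959963984540054

ASSOC_COLUMNS = [
    "rsid",
    "gene_label",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "n_used",
    "eaf_case",
    "eaf_control",
    "beta",
    "se",
    "or_",
    "ci_low",
    "ci_high",
    "p",
    "converged",
    "flag",
]


def _safe_exp(x: float) -> float:
    """exp() without OverflowError (separated fits can yield huge betas)."""
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


def _first_dependent_column(X: np.ndarray, names: Sequence[str]) -> str:
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            return names[j]
        rank = r
    return names[-1]


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    column_names: Sequence[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic fit.

    ``X`` must already contain the intercept column; rows with missing values
    must have been dropped by the caller.  Returns ``(beta, se, converged)``.
    Separation or non-convergence is reported through the flag — estimates
    from the final Newton iteration are still returned, but their standard
    errors are not trustworthy.

    Raises
    ------
    DegenerateOutcomeError
        If the outcome is constant.
    CollinearityError
        If the design is rank deficient; the message names the first column
        linearly dependent on its predecessors.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if column_names is None:
        column_names = [f"x{j}" for j in range(X.shape[1])]
    if y.size == 0:
        raise EmptyInputError("empty outcome vector")
    if np.all(y == y[0]):
        raise DegenerateOutcomeError("outcome is constant; logistic model undefined")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _first_dependent_column(X, column_names)
        raise CollinearityError(f"design matrix is rank deficient (column {bad!r})")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("error", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=max_iter, tol=tol, disp=0,
                warn_convergence=False,
            )
            converged = bool(res.mle_retvals.get("converged", True))
            beta = np.asarray(res.params, dtype=float)
            se = np.asarray(res.bse, dtype=float)
        except (PerfectSeparationError, PerfectSeparationWarning, ConvergenceWarning,
                np.linalg.LinAlgError):
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(
                    method="bfgs", maxiter=max_iter, disp=0, warn_convergence=False
                )
            beta = np.asarray(res.params, dtype=float)
            se = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(se)):
        converged = False
    return beta, se, converged


def _covariate_frame(matrix: GenotypeMatrix, covariates: Sequence[str]) -> pd.DataFrame:
    """Expand sample covariates into numeric design columns.

    Sex becomes an indicator for male; ethnicity becomes indicator columns
    against a reference category chosen as the most frequent category among
    controls (recorded in the column names that *are* included).
    """
    cols: dict[str, list] = {}
    if "age" in covariates:
        cols["age"] = [s.age for s in matrix.samples]
    if "sex" in covariates:
        cols["sex_male"] = [
            None if s.sex is None else float(s.sex == "male") for s in matrix.samples
        ]
    if "ethnicity" in covariates:
        eth = pd.Series([s.ethnicity for s in matrix.samples], dtype=object)
        controls = eth[matrix.control_mask]
        counts = controls.dropna().value_counts()
        if counts.empty:
            counts = eth.dropna().value_counts()
        reference = counts.index[0] if not counts.empty else None
        for cat in sorted(c for c in eth.dropna().unique() if c != reference):
            cols[f"ethnicity_{cat}"] = [
                None if e is None else float(e == cat) for e in eth
            ]
    return pd.DataFrame(cols, dtype=float)


def snp_association(
    matrix: GenotypeMatrix,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-variant logistic association: ``status ~ dosage [+ covariates]``.

    Rows with a missing dosage or any missing covariate are dropped per
    model (complete-case); per-group effect-allele frequencies are computed
    on the samples actually used in each fit.  Monomorphic variants are
    reported with OR 1, p 1 and flag ``"monomorphic"`` rather than dropped.

    Returns a DataFrame with one row per variant (columns
    :data:`ASSOC_COLUMNS`).
    """
    matrix.require_status()
    y_all = matrix.case_mask.astype(float)
    cov = _covariate_frame(matrix, covariates)
    cov_ok = (
        np.ones(matrix.n_samples, dtype=bool)
        if cov.empty
        else ~cov.isna().any(axis=1).to_numpy()
    )
    cov_values = cov.to_numpy() if not cov.empty else np.empty((matrix.n_samples, 0))
    cov_names = list(cov.columns)

    rows = []
    for j, v in enumerate(matrix.variants):
        g = matrix.dosages[:, j]
        use = np.isfinite(g) & cov_ok
        n_used = int(use.sum())
        row = {
            "rsid": v.rsid,
            "gene_label": v.gene_label,
            "chrom": v.chrom,
            "pos": v.pos,
            "effect_allele": v.effect_allele,
            "other_allele": v.other_allele,
            "n_used": n_used,
        }
        y = y_all[use]
        gu = g[use]
        for group, mask in (("case", y == 1), ("control", y == 0)):
            gg = gu[mask]
            row[f"eaf_{group}"] = (
                float(gg.sum() / (2 * gg.size)) if gg.size else float("nan")
            )
        if n_used == 0 or np.all(gu == gu[0]):
            row.update(
                beta=0.0, se=float("nan"), or_=1.0, ci_low=float("nan"),
                ci_high=float("nan"), p=1.0, converged=True, flag="monomorphic",
            )
            rows.append(row)
            continue
        X = np.column_stack([np.ones(n_used), gu, cov_values[use]])
        beta, se, converged = fit_logistic(
            y, X, column_names=["intercept", "dosage", *cov_names]
        )
        b, s = float(beta[1]), float(se[1])
        z = b / s if s > 0 else float("inf")
        row.update(
            beta=b,
            se=s,
            or_=_safe_exp(b),
            ci_low=_safe_exp(b - Z_95 * s),
            ci_high=_safe_exp(b + Z_95 * s),
            p=float(2 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0,
            converged=converged,
            flag="" if converged else "not_converged",
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def allelic_or(
    eaf_case: float,
    eaf_control: float,
    n_case: int,
    n_control: int,
) -> tuple[float, float, float]:
    """Closed-form allelic odds ratio from per-group allele frequencies.

    Builds the 2 x 2 allele-count table (2n chromosomes per group), returns
    the cross-product OR with the Woolf (logit) 95% CI.  Frequencies must be
    strictly inside (0, 1); no continuity correction is applied silently.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("sample sizes must be positive")
    for name, f in (("eaf_case", eaf_case), ("eaf_control", eaf_control)):
        if not 0.0 < f < 1.0:
            raise BoundaryFrequencyError(
                f"{name}={f}: allelic OR needs frequencies strictly inside (0, 1)"
            )
    a = 2 * n_case * eaf_case          # effect alleles, cases
    b = 2 * n_case * (1 - eaf_case)    # other alleles, cases
    c = 2 * n_control * eaf_control
    d = 2 * n_control * (1 - eaf_control)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return or_, math.exp(log_or - Z_95 * se), math.exp(log_or + Z_95 * se)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Study-wide per-test significance threshold ``alpha / n_tests``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def write_association_table(assoc: pd.DataFrame, path: str | Path) -> None:
    """Write the association table as TSV (panel-table column layout)."""
    out = assoc.copy()
    out["or_ci"] = [
        f"{o:.2f} ({lo:.2f}-{hi:.2f})" if math.isfinite(lo) else f"{o:.2f} (NA)"
        for o, lo, hi in zip(out["or_"], out["ci_low"], out["ci_high"])
    ]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
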