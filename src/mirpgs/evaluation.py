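"""Replication harness: repeat the emulated study end to end and summarise.

These helpers run the whole analysis chain (simulate → per-SNP association →
risk orientation → score building → score-level association → ROC) on fresh
synthetic datasets drawn at the packaged study conditions, once per seeded
replicate, and collect the headline quantities: the weighted / unweighted
score's AUC and OR per SD (with in-sample ln(OR) weights, i.e. including any
winner's-curse optimism of in-sample evaluation) and the strongest variant's
risk-oriented OR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import snp_association
from .ld import greedy_prune, ld_matrix, priority_by_pvalue
from .orientation import orient_panel
from .roc import auc_mann_whitney
from .score import build_unweighted_model, build_weighted_model, compute_pgs, pgs_association
from .simulate import default_config, simulate

__all__ = ["replicate_study", "prune_default_fixture"]


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-replicate seeds (< 2^31) from one seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


def replicate_study(
    n_replicates: int = 50,
    seed: int = 0,
    top_rsid: str = "rs1057035",
) -> pd.DataFrame:
    """Replicate the 21-SNP study; one row of summary metrics per replicate.

    Each replicate simulates 464 cases / 1042 controls at the packaged
    per-group frequencies (conditional mode, default 2% missingness, no
    proxies), derives per-SNP weights in-sample as ln of the risk-oriented
    OR from unadjusted logistic fits, builds the weighted and unweighted
    standardised scores, and records Mann-Whitney AUC and logistic OR per
    SD for both, plus the risk-oriented OR of ``top_rsid``.
    """
    rows = []
    for rep_seed in child_seeds(seed, n_replicates):
        cfg = default_config(seed=rep_seed, with_proxies=False)
        matrix = simulate(cfg)
        assoc = snp_association(matrix)
        oriented = orient_panel(assoc)
        case, ctrl = matrix.case_mask, matrix.control_mask
        row: dict = {"seed": rep_seed}
        for mode, builder in (
            ("weighted", build_weighted_model),
            ("unweighted", build_unweighted_model),
        ):
            scores = compute_pgs(matrix, builder(oriented))
            row[f"or_sd_{mode}"] = pgs_association(scores, matrix).or_per_sd
            row[f"auc_{mode}"] = auc_mann_whitney(
                scores.standardized[case], scores.standardized[ctrl]
            )
        row["top_or_risk"] = float(
            oriented.set_index("rsid").loc[top_rsid, "or_risk"]
        )
        rows.append(row)
    return pd.DataFrame(rows)


def prune_default_fixture(seed: int = 0) -> tuple[int, int]:
    """Run association + greedy LD pruning on the default 28-variant fixture.

    Returns ``(n_kept, n_dropped)`` at the default r² > 0.2 exclusion rule
    with ascending-p priority — the 21-index + 7-proxy pruning arithmetic.
    """
    matrix = simulate(default_config(seed=seed))
    assoc = snp_association(matrix)
    result = greedy_prune(ld_matrix(matrix), priority_by_pvalue(assoc), threshold=0.2)
    return len(result.kept), len(result.dropped)
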