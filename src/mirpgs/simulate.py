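"""Synthetic case-control genotype generator.

Emulates the statistical structure of the emulated ccRCC study: 464 cases
and 1042 controls genotyped on a small panel of biallelic SNPs, with
per-group effect-allele frequencies, covariate composition (sex, age,
ethnicity) and ~2% missing calls matching the published summary tables,
plus high-LD proxy variants planted to exercise the pruning stage.

Two generative modes:

* ``conditional`` — genotypes drawn per group as ``Binomial(2, group EAF)``
  under HWE within each group, independent across index variants.  This is
  the direct counterpart of a published per-group frequency table.
* ``logistic`` — controls drawn from the population frequency (rare-disease
  approximation) and case genotypes tilted by ``OR^g``, the exact
  retrospective sampling distribution implied by a log-additive model.

Proxy variants are built at the haplotype level: each of the two allele
copies duplicates the parent's corresponding allele with probability ``c``
and is otherwise redrawn from the parent's group allele frequency, giving
dosage correlation r ≈ c (so r² ≈ c²).

Everything is driven by ``numpy.random.Generator`` seeded from the config:
identical (config, seed) pairs give byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datamodel import MISSING, GenotypeMatrix, SampleRecord, VariantRecord
from .errors import ConfigError

__all__ = [
    "SimVariant",
    "ProxySpec",
    "GroupCovariates",
    "CovariateConfig",
    "SimConfig",
    "default_panel",
    "default_covariates",
    "default_config",
    "simulate",
    "simulate_conditional",
    "simulate_logistic",
    "case_genotype_probs",
    "plant_proxy",
    "add_missingness",
    "simulate_covariates",
]

#: Haplotype copy probability giving a target proxy r² of ~0.6 (0.775² ≈ 0.6).
DEFAULT_PROXY_COPY_PROB = 0.775
#: Number of planted high-LD proxies in the default fixture.
DEFAULT_N_PROXIES = 7


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimVariant:
    """Simulation parameters for one index SNP.

    Conditional mode uses ``eaf_case``/``eaf_control``; logistic mode uses
    ``eaf`` (population) and ``or_``.
    """

    rsid: str
    chrom: str = "0"
    pos: int = 1
    effect_allele: str = "A"
    other_allele: str = "G"
    gene_label: str = ""
    eaf_case: float | None = None
    eaf_control: float | None = None
    eaf: float | None = None
    or_: float | None = None

    def record(self) -> VariantRecord:
        return VariantRecord(
            rsid=self.rsid, chrom=self.chrom, pos=self.pos,
            effect_allele=self.effect_allele, other_allele=self.other_allele,
            gene_label=self.gene_label,
        )


@dataclass(frozen=True)
class ProxySpec:
    """A planted high-LD proxy: copies ``parent_rsid`` with probability ``c``."""

    parent_rsid: str
    copy_probability: float = DEFAULT_PROXY_COPY_PROB
    rsid: str | None = None


@dataclass(frozen=True)
class GroupCovariates:
    male_fraction: float
    age_mean: float
    age_sd: float
    ethnicity: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CovariateConfig:
    case: GroupCovariates
    control: GroupCovariates
    age_min: float = 18.0


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one synthetic study."""

    variants: tuple[SimVariant, ...]
    proxies: tuple[ProxySpec, ...] = ()
    n_case: int = 464
    n_control: int = 1042
    missing_rate: float = 0.02
    covariates: CovariateConfig | None = None
    mode: str = "conditional"
    seed: int = 0

    def validate(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ConfigError("n_case and n_control must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if self.mode not in ("conditional", "logistic"):
            raise ConfigError(f"mode must be 'conditional' or 'logistic', got {self.mode!r}")
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            raise ConfigError("duplicate rsids in variant table")
        for v in self.variants:
            if self.mode == "conditional":
                freqs = (v.eaf_case, v.eaf_control)
                if any(f is None for f in freqs):
                    raise ConfigError(f"{v.rsid}: conditional mode needs per-group EAFs")
            else:
                if v.eaf is None or v.or_ is None:
                    raise ConfigError(f"{v.rsid}: logistic mode needs (eaf, or_)")
                if v.or_ <= 0:
                    raise ConfigError(f"{v.rsid}: OR must be positive, got {v.or_}")
                freqs = (v.eaf,)
            for f in freqs:
                if not 0.0 < f < 1.0:  # type: ignore[operator]
                    raise ConfigError(f"{v.rsid}: frequency {f} outside (0, 1)")
        for p in self.proxies:
            if p.parent_rsid not in rsids:
                raise ConfigError(f"proxy parent {p.parent_rsid!r} not in variant table")
            if not 0.0 <= p.copy_probability <= 1.0:
                raise ConfigError(f"proxy copy probability {p.copy_probability} outside [0, 1]")
        if self.covariates is not None:
            for label, grp in (("case", self.covariates.case), ("control", self.covariates.control)):
                if grp.ethnicity and abs(sum(grp.ethnicity.values()) - 1.0) > 1e-6:
                    raise ConfigError(f"{label} ethnicity proportions must sum to 1")


# ---------------------------------------------------------------------------
# Packaged defaults (published study structure)
# ---------------------------------------------------------------------------

def default_panel() -> tuple[SimVariant, ...]:
    """The packaged 21-SNP miRNA-biogenesis panel with per-group EAFs."""
    with resources.files("mirpgs.data").joinpath("ccrcc_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return tuple(
        SimVariant(
            rsid=r.rsid, chrom=str(r.chrom), pos=int(r.pos),
            effect_allele=r.effect_allele, other_allele=r.other_allele,
            gene_label=r.gene_label,
            eaf_case=float(r.eaf_case), eaf_control=float(r.eaf_control),
        )
        for r in df.itertuples()
    )


def default_covariates() -> CovariateConfig:
    """The packaged cohort composition (sex/age/ethnicity per group)."""
    with resources.files("mirpgs.data").joinpath("ccrcc_cohort.yaml").open() as fh:
        raw = yaml.safe_load(fh)

    def group(d: dict) -> GroupCovariates:
        return GroupCovariates(
            male_fraction=float(d["male_fraction"]),
            age_mean=float(d["age_mean"]),
            age_sd=float(d["age_sd"]),
            ethnicity={str(k): float(v) for k, v in d["ethnicity"].items()},
        )

    return CovariateConfig(case=group(raw["case"]), control=group(raw["control"]))


def default_config(
    seed: int = 0,
    with_proxies: bool = True,
    missing_rate: float = 0.02,
) -> SimConfig:
    """The default synthetic study: 21 index SNPs (+7 proxies), 464/1042.

    The 7 proxies are attached to the first 7 panel variants in table order
    at copy probability 0.775 (target r² ≈ 0.6), reproducing the study's
    28 → 21 pruning arithmetic; which index variants carry proxies is an
    arbitrary fixture choice, not a claim about the real excluded rsIDs.
    """
    panel = default_panel()
    proxies: tuple[ProxySpec, ...] = ()
    if with_proxies:
        proxies = tuple(
            ProxySpec(parent_rsid=v.rsid, copy_probability=DEFAULT_PROXY_COPY_PROB)
            for v in panel[:DEFAULT_N_PROXIES]
        )
    return SimConfig(
        variants=panel, proxies=proxies, missing_rate=missing_rate,
        covariates=default_covariates(), mode="conditional", seed=seed,
    )


# ---------------------------------------------------------------------------
# Genotype generation
# ---------------------------------------------------------------------------

def case_genotype_probs(eaf: float, or_: float) -> np.ndarray:
    """Case genotype distribution under retrospective log-additive sampling.

    ``P(g | case) ∝ OR^g · C(2,g) p^g (1-p)^(2-g)`` for g in {0, 1, 2}.
    """
    if or_ <= 0:
        raise ConfigError(f"OR must be positive, got {or_}")
    g = np.arange(3)
    base = stats.binom.pmf(g, 2, eaf)
    w = base * or_ ** g
    return w / w.sum()


def _draw_group(
    rng: np.random.Generator, n: int, variants: tuple[SimVariant, ...],
    group: str, mode: str,
) -> np.ndarray:
    out = np.empty((n, len(variants)), dtype=float)
    for j, v in enumerate(variants):
        if mode == "conditional":
            p = v.eaf_case if group == "case" else v.eaf_control
            out[:, j] = rng.binomial(2, p, size=n)
        else:
            if group == "control":
                out[:, j] = rng.binomial(2, v.eaf, size=n)
            else:
                out[:, j] = rng.choice(3, size=n, p=case_genotype_probs(v.eaf, v.or_))
    return out


def _base_matrix(config: SimConfig, rng: np.random.Generator) -> GenotypeMatrix:
    cases = _draw_group(rng, config.n_case, config.variants, "case", config.mode)
    controls = _draw_group(rng, config.n_control, config.variants, "control", config.mode)
    dosages = np.vstack([cases, controls])
    samples = [
        SampleRecord(sample_id=f"case_{i + 1:04d}", status="case")
        for i in range(config.n_case)
    ] + [
        SampleRecord(sample_id=f"ctrl_{i + 1:04d}", status="control")
        for i in range(config.n_control)
    ]
    return GenotypeMatrix(dosages, [v.record() for v in config.variants], samples)


def simulate_conditional(config: SimConfig) -> GenotypeMatrix:
    """Conditional-mode genotypes only (no proxies/covariates/missingness)."""
    config = replace(config, mode="conditional")
    config.validate()
    return _base_matrix(config, np.random.default_rng(config.seed))


def simulate_logistic(config: SimConfig) -> GenotypeMatrix:
    """Logistic-mode genotypes only (no proxies/covariates/missingness)."""
    config = replace(config, mode="logistic")
    config.validate()
    return _base_matrix(config, np.random.default_rng(config.seed))


# ---------------------------------------------------------------------------
# Proxies, missingness, covariates
# ---------------------------------------------------------------------------

def plant_proxy(
    matrix: GenotypeMatrix,
    parent_rsid: str,
    copy_probability: float,
    rng: np.random.Generator,
    proxy_rsid: str | None = None,
) -> GenotypeMatrix:
    """Append one high-LD proxy of ``parent_rsid`` built at haplotype level.

    The parent dosage is decomposed into two exchangeable allele copies;
    each proxy copy duplicates the parent's with probability ``c`` and is
    otherwise drawn fresh from the parent's allele frequency within the
    sample's group (preserving any case-control frequency difference).
    Expected dosage r² ≈ c².  Missing parent calls give missing proxy calls.
    """
    j = matrix.variant_index(parent_rsid)
    parent = matrix.variants[j]
    g = matrix.dosages[:, j]
    proxy_rsid = proxy_rsid or f"{parent_rsid}_proxy"

    # group-wise parent allele frequency for the fresh draws
    status = matrix.status
    freq = np.empty(matrix.n_samples)
    for grp in dict.fromkeys(status):
        m = status == grp
        gg = g[m]
        gg = gg[np.isfinite(gg)]
        freq[m] = gg.sum() / (2 * gg.size) if gg.size else 0.5

    n = matrix.n_samples
    h1 = np.where(g >= 1, 1.0, 0.0)          # decompose dosage into haplotypes
    h2 = np.where(g == 2, 1.0, 0.0)
    het = g == 1
    swap = rng.random(n) < 0.5               # heterozygote copies exchangeable
    h1_, h2_ = h1.copy(), h2.copy()
    h1_[het & swap], h2_[het & swap] = 0.0, 1.0

    proxy = np.full(n, MISSING)
    ok = np.isfinite(g)
    for h in (h1_, h2_):
        copy = rng.random(n) < copy_probability
        fresh = (rng.random(n) < freq).astype(float)
        allele = np.where(copy, h, fresh)
        proxy[ok] = np.where(np.isfinite(proxy[ok]), proxy[ok], 0.0) + allele[ok]

    record = VariantRecord(
        rsid=proxy_rsid, chrom=parent.chrom, pos=parent.pos + 1,
        effect_allele=parent.effect_allele, other_allele=parent.other_allele,
        gene_label=parent.gene_label,
    )
    dosages = np.column_stack([matrix.dosages, proxy])
    return GenotypeMatrix(dosages, [*matrix.variants, record], list(matrix.samples))


def add_missingness(
    matrix: GenotypeMatrix, rate: float, rng: np.random.Generator
) -> GenotypeMatrix:
    """Set each entry to missing independently with probability ``rate`` (MCAR)."""
    if not 0.0 <= rate < 1.0:
        raise ConfigError(f"missing rate must lie in [0, 1), got {rate}")
    out = matrix.copy()
    if rate > 0:
        mask = rng.random(out.dosages.shape) < rate
        out.dosages[mask] = MISSING
    return out


def simulate_covariates(
    config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-sample sex, age and ethnicity from the group distributions.

    Sex ~ Bernoulli(male fraction); age ~ Normal(mean, sd) truncated below
    at ``age_min`` (default 18); ethnicity ~ categorical.  Covariates are
    independent of genotypes, so adjusted and unadjusted genetic effects
    coincide in expectation.
    """
    cc = config.covariates
    if cc is None:
        raise ConfigError("config has no covariate specification")
    frames = []
    for grp_label, grp, n in (
        ("case", cc.case, config.n_case),
        ("control", cc.control, config.n_control),
    ):
        sex = np.where(rng.random(n) < grp.male_fraction, "male", "female")
        a = (cc.age_min - grp.age_mean) / grp.age_sd
        age = stats.truncnorm.rvs(
            a, np.inf, loc=grp.age_mean, scale=grp.age_sd, size=n, random_state=rng
        )
        if grp.ethnicity:
            cats = sorted(grp.ethnicity)
            probs = np.array([grp.ethnicity[c] for c in cats])
            eth = rng.choice(cats, size=n, p=probs / probs.sum())
        else:
            eth = np.array([None] * n, dtype=object)
        frames.append(
            pd.DataFrame(
                {"status": grp_label, "sex": sex, "age": age, "ethnicity": eth}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Top-level generator
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> GenotypeMatrix:
    """Generate the full synthetic study described by ``config``.

    Order of operations: index genotypes → planted proxies → covariates →
    missingness.  Bit-reproducible given (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    matrix = _base_matrix(config, rng)
    for k, proxy in enumerate(config.proxies):
        matrix = plant_proxy(
            matrix, proxy.parent_rsid, proxy.copy_probability, rng,
            proxy_rsid=proxy.rsid,
        )
    if config.covariates is not None:
        cov = simulate_covariates(config, rng)
        samples = [
            SampleRecord(
                sample_id=s.sample_id, status=s.status,
                sex=str(cov.at[i, "sex"]), age=float(cov.at[i, "age"]),
                ethnicity=None if cov.at[i, "ethnicity"] is None else str(cov.at[i, "ethnicity"]),
            )
            for i, s in enumerate(matrix.samples)
        ]
        matrix = matrix.with_samples(samples)
    if config.missing_rate > 0:
        matrix = add_missingness(matrix, config.missing_rate, rng)
    return matrix
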