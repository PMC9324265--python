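"""Core containers: variants, samples and the allele-dosage matrix.

The central object is :class:`GenotypeMatrix` — a samples × variants matrix of
effect-allele dosages (0, 1, 2, or NaN for a missing call) carrying ordered
:class:`VariantRecord` and :class:`SampleRecord` axes.  Dosage always counts
copies of the variant's *effect* allele; re-orienting a variant to its risk
allele is an explicit operation (:func:`mirpgs.orientation.dosage_flip`),
never an I/O side effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, UndefinedFrequencyError

__all__ = [
    "MISSING",
    "VariantRecord",
    "SampleRecord",
    "GenotypeMatrix",
]

#: Sentinel for a missing genotype call.  NaN is outside {0, 1, 2} and
#: propagates through arithmetic, which is exactly the behaviour we want.
MISSING: float = float("nan")

_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP with its genomic coordinates and allele labels.

    ``effect_allele`` is the allele whose copies the dosage column counts;
    ``other_allele`` is the complementary allele.  Positions are 1-based
    (GRCh37 in the packaged panel).
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    gene_label: str = ""

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"{self.rsid}: position must be positive, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in _VALID_ALLELES:
                raise ValueError(f"{self.rsid}: invalid allele {allele!r}")

    def swapped(self) -> "VariantRecord":
        """Return the record with effect and other allele exchanged."""
        return replace(
            self, effect_allele=self.other_allele, other_allele=self.effect_allele
        )


@dataclass(frozen=True)
class SampleRecord:
    """One study participant.

    ``status`` is ``"case"`` or ``"control"`` (may be None for genotype-only
    input until phenotypes are attached); ``age`` in years, None if unknown.
    """

    sample_id: str
    status: str | None = None
    sex: str | None = None
    age: float | None = None
    ethnicity: str | None = None

    def __post_init__(self) -> None:
        if self.status is not None and self.status not in ("case", "control"):
            raise ValueError(
                f"{self.sample_id}: status must be 'case' or 'control', got {self.status!r}"
            )
        if self.age is not None and self.age < 0:
            raise ValueError(f"{self.sample_id}: negative age {self.age}")


class GenotypeMatrix:
    """Samples × variants effect-allele dosage matrix.

    Parameters
    ----------
    dosages
        Array of shape ``(n_samples, n_variants)`` with entries in
        ``{0, 1, 2}`` or NaN for missing.  Stored as float64.
    variants, samples
        Ordered axis metadata; lengths must match the matrix shape.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        variants: Sequence[VariantRecord],
        samples: Sequence[SampleRecord],
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.float64)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if dosages.shape != (len(samples), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        finite = dosages[np.isfinite(dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage entries must be 0, 1, 2 or NaN; found {bad}")
        rsids = [v.rsid for v in variants]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in variant axis")
        self.dosages = dosages
        self.variants = list(variants)
        self.samples = list(samples)
        self._index = {rsid: j for j, rsid in enumerate(rsids)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def variant_index(self, rsid: str) -> int:
        try:
            return self._index[rsid]
        except KeyError:
            raise KeyError(f"unknown variant {rsid!r}") from None

    def variant(self, rsid: str) -> VariantRecord:
        return self.variants[self.variant_index(rsid)]

    def dosage_vector(self, rsid: str) -> np.ndarray:
        """Copy of the dosage column for one variant."""
        return self.dosages[:, self.variant_index(rsid)].copy()

    # -- group masks ---------------------------------------------------------

    @property
    def status(self) -> np.ndarray:
        """Object array of per-sample status labels (None where unset)."""
        return np.array([s.status for s in self.samples], dtype=object)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([s.status == "case" for s in self.samples])

    @property
    def control_mask(self) -> np.ndarray:
        return np.array([s.status == "control" for s in self.samples])

    def group_mask(self, subset: str) -> np.ndarray:
        """Boolean sample mask for ``"case"``, ``"control"`` or ``"all"``."""
        if subset == "all":
            return np.ones(self.n_samples, dtype=bool)
        if subset == "case":
            return self.case_mask
        if subset == "control":
            return self.control_mask
        raise ValueError(f"subset must be 'case', 'control' or 'all', got {subset!r}")

    # -- derived quantities --------------------------------------------------

    def effect_allele_frequency(self, rsid: str, subset: str = "all") -> float:
        """Frequency of the effect allele among non-missing genotypes.

        Computed as the dosage sum over non-missing samples in ``subset``,
        divided by twice the number of those samples.
        """
        g = self.dosages[self.group_mask(subset), self.variant_index(rsid)]
        g = g[np.isfinite(g)]
        if g.size == 0:
            raise UndefinedFrequencyError(
                f"{rsid}: all genotypes missing in subset {subset!r}"
            )
        return float(g.sum() / (2.0 * g.size))

    # -- manipulation --------------------------------------------------------

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), list(self.variants), list(self.samples))

    def subset_variants(self, rsids: Iterable[str]) -> "GenotypeMatrix":
        """New matrix restricted to ``rsids``, in the order given."""
        rsids = list(rsids)
        cols = [self.variant_index(r) for r in rsids]
        return GenotypeMatrix(
            self.dosages[:, cols], [self.variants[j] for j in cols], list(self.samples)
        )

    def with_samples(self, samples: Sequence[SampleRecord]) -> "GenotypeMatrix":
        """Replace the sample axis (e.g. after attaching phenotypes)."""
        if len(samples) != self.n_samples:
            raise ValueError("sample axis length mismatch")
        return GenotypeMatrix(self.dosages.copy(), list(self.variants), list(samples))

    def require_status(self) -> None:
        """Raise unless every sample carries a case/control label."""
        missing = [s.sample_id for s in self.samples if s.status is None]
        if missing:
            raise EmptyInputError(
                f"{len(missing)} samples lack case/control status "
                f"(first: {missing[0]}); attach a phenotype table first"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GenotypeMatrix {self.n_samples} samples x {self.n_variants} variants>"
        )
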