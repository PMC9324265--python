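"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`MirpgsError`
so callers can catch pipeline failures without masking programming errors.
"""


class MirpgsError(Exception):
    """Base class for all errors raised by mirpgs."""


class VcfParseError(MirpgsError):
    """Malformed VCF header or record."""


class UnsupportedRecordError(MirpgsError):
    """A VCF record the panel model cannot represent (e.g. multi-allelic)."""


class DosageValueError(MirpgsError):
    """A dosage cell outside {0, 1, 2, NA}."""


class UndefinedFrequencyError(MirpgsError):
    """Allele frequency requested where every genotype is missing."""


class EmptyInputError(MirpgsError):
    """An operation received an empty matrix or group."""


class DegenerateOutcomeError(MirpgsError):
    """Logistic outcome is constant; no model can be fit."""


class CollinearityError(MirpgsError):
    """Rank-deficient design matrix; names the offending column."""


class BoundaryFrequencyError(MirpgsError):
    """Allele frequency of exactly 0 or 1 where a closed form needs (0, 1)."""


class UndefinedLdError(MirpgsError):
    """Too few complete pairs, or zero dosage variance, for an r^2 estimate."""


class MissingVariantError(MirpgsError):
    """A score model names variants absent from the genotype matrix."""


class AlleleMismatchError(MirpgsError):
    """Model risk allele matches neither allele of the matrix variant."""


class DegenerateScoreError(MirpgsError):
    """Polygenic score has zero variance; per-SD association undefined."""


class ConfigError(MirpgsError):
    """Invalid simulation or pipeline configuration."""
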