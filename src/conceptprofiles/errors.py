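"""Exception types shared across the pipeline."""


class ConceptProfilesError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ConceptProfilesError):
    """Invalid generator or run configuration."""


class CorpusFormatError(ConceptProfilesError):
    """Malformed corpus record (bad line, duplicate doc id, empty corpus)."""


class UnknownConceptError(ConceptProfilesError):
    """A concept id is not present in the index or network."""


class ProfileEligibilityError(ConceptProfilesError):
    """Entity occurs in fewer documents than the profile threshold requires.

    Distinct from :class:`UnknownConceptError`: the concept exists but does
    not meet the minimum-abstract rule.
    """


class BenchmarkError(ConceptProfilesError):
    """Benchmark construction or evaluation is impossible as requested."""


class MissingArtifactError(ConceptProfilesError):
    """A pipeline stage requires an upstream artifact that does not exist."""
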