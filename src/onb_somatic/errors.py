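"""Exception hierarchy for the toolkit."""


class OnbSomaticError(Exception):
    """Base class for all package errors."""


class ConfigError(OnbSomaticError):
    """Invalid configuration (overlapping CNV segments, bad rates, missing paths)."""


class SamFormatError(OnbSomaticError):
    """Malformed SAM input (missing header, CIGAR/sequence mismatch)."""


class RangeError(OnbSomaticError):
    """Requested coordinates fall outside the contig."""


class PairingError(OnbSomaticError):
    """Tumor/normal calls do not refer to the same locus and allele."""


class ValidationError(OnbSomaticError):
    """A data table failed validation (e.g. a codon cell matching no known allele)."""
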