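"""Exception hierarchy shared across the pipeline stages."""


class NpjuryError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NpjuryError):
    """Invalid configuration (bad fractions, mismatched panels, unknown task)."""


class InputError(NpjuryError):
    """Invalid input data (unparseable SMILES, empty sets, bad vectors)."""


class FormatError(NpjuryError):
    """Malformed input file (missing columns, unreadable table)."""


class EmptyDatasetError(NpjuryError):
    """No records survived filtering; nothing to model."""


class TrainingError(NpjuryError):
    """Model training cannot proceed (e.g. a single-class label vector)."""
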