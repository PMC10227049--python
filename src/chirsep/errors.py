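"""Exception hierarchy."""


class ChirsepError(Exception):
    """Base class for package errors."""


class SmilesParseError(ChirsepError):
    """A SMILES string could not be parsed."""


class FeaturizationError(ChirsepError):
    """Graph or conformer construction failed for a molecule."""


class SchemaError(ChirsepError):
    """A required column is missing or malformed in an input table."""


class ContractError(ChirsepError, ValueError):
    """An operation was called with arguments violating its contract."""


class StateError(ChirsepError):
    """An operation was applied to an object in the wrong state."""


class TrainingError(ChirsepError):
    """Optimization diverged or could not proceed."""
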