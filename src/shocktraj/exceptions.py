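"""Package-wide exception types."""


class ShocktrajError(Exception):
    """Base class for all shocktraj errors."""


class ConfigError(ShocktrajError):
    """Invalid configuration; the message names the offending field."""


class SchemaError(ShocktrajError):
    """Input table is missing required columns or has unparseable rows."""


class InputError(ShocktrajError):
    """Invalid values passed to an operation (non-numeric, non-finite, ...)."""


class TrainingSetError(ShocktrajError):
    """Degenerate training set (e.g. one of the two classes is empty)."""


class NumericalError(ShocktrajError):
    """An eigensolver or optimizer failed to produce a usable result."""
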