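"""Exception hierarchy for the limb-BCG pipeline."""


class LimbBCGError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(LimbBCGError):
    """A configuration value is invalid or inconsistent."""


class DataError(LimbBCGError):
    """Input data violate a structural contract (annotations, channels, shapes)."""


class ProcessingError(LimbBCGError):
    """A processing stage cannot operate on otherwise valid data."""


class UnlabelableBeat(ProcessingError):
    """A beat lacks the I/J/K morphology (or PPG upstroke) needed for labeling."""
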