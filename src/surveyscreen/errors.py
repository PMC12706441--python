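"""Exception hierarchy shared across the package."""


class SurveyScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(SurveyScreenError):
    """The declared survey schema is malformed or a file does not match it."""


class LoadError(SurveyScreenError):
    """A response export could not be loaded (e.g. duplicate record ids)."""


class ConfigError(SurveyScreenError):
    """Invalid cohort, criteria or pipeline configuration."""


class CalibrationError(SurveyScreenError):
    """Control designation or threshold selection is impossible."""


class PipelineError(SurveyScreenError):
    """A pipeline stage failed; the message names the stage."""
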