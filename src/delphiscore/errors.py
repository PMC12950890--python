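"""Exception hierarchy."""


class DelphiScoreError(Exception):
    """Base class for all package errors."""


class ConfigError(DelphiScoreError, ValueError):
    """An instrument or pipeline configuration document is invalid."""


class UnknownProblemError(DelphiScoreError, KeyError):
    """A patient assessment references problem ids absent from the instrument."""

    def __init__(self, unknown_ids):
        self.unknown_ids = sorted(unknown_ids)
        super().__init__(
            "unknown problem id(s): " + ", ".join(self.unknown_ids)
        )


class RatingError(DelphiScoreError, ValueError):
    """A rating is missing, empty, or outside its declared scale."""
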