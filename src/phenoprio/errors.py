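"""Exception hierarchy.

``UsageError`` marks precondition/validation failures (CLI exit code 2);
``RuntimeFailure`` marks failures during an otherwise valid run (exit code 1).
"""


class PhenoprioError(Exception):
    """Base class for all package errors."""


class UsageError(PhenoprioError):
    """Invalid input, option combination or identifier syntax."""


class RuntimeFailure(PhenoprioError):
    """Unreadable/unwritable files, corrupt data, or internal failures."""
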