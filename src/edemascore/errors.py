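"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (validation 2, pairing 3,
I/O 4) so shell pipelines can tell bad data from bad wiring.
"""


class EdemaScoreError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(EdemaScoreError):
    """Malformed or inconsistent input values (bad level, bad EVLW, bad CSV row)."""

    exit_code = 2


class RubricError(ValidationError):
    """Unknown indicator or structurally invalid rubric."""


class InputError(ValidationError):
    """Out-of-domain arguments to a statistical operation."""


class PairingError(EdemaScoreError):
    """Readers/cases of paired inputs do not line up, or a case lacks a reference."""

    exit_code = 3


class ReportIOError(EdemaScoreError):
    """Unreadable or unwritable file."""

    exit_code = 4
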