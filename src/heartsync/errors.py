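"""Exception taxonomy shared across the package.

CLI exit-code mapping: parameter / input-format problems exit 2,
algorithmic failures (no heartbeat found, phase-lock loss, disconnected
alignment graph) exit 3.
"""


class ParameterError(ValueError):
    """An operation was called with invalid parameter values."""


class InputFormatError(ValueError):
    """An input file or array does not have the expected layout."""


class AcquisitionError(RuntimeError):
    """No periodic recurrence could be found in the brightfield stream."""


class AlignmentError(RuntimeError):
    """The relative-shift graph does not connect all reference sequences."""


class GatingError(RuntimeError):
    """Phase-lock could not be established or recovered during a run."""
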