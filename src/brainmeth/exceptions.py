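"""Errors raised by brainmeth readers and validators."""


class BrainMethError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BrainMethError, ValueError):
    """A file does not conform to the documented schema (wrong/missing
    columns, duplicate identifiers, unparseable cells)."""


class ValidationError(BrainMethError, ValueError):
    """A file parses but violates a domain invariant (value out of range,
    inconsistent category labels, broken cross-table constraint)."""


class PanelError(BrainMethError, ValueError):
    """A qMSP panel is incomplete or inconsistent; no classification call
    is produced from a malformed panel."""
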