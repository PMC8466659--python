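"""Exception hierarchy."""


class IfpError(Exception):
    """Base class for all ifpkit errors."""


class StructureError(IfpError):
    """A structure violates the input contract (missing metadata, bad bonds)."""


class PatternError(IfpError):
    """A moiety pattern is malformed, duplicated, or unknown."""


class DetectionContractError(IfpError):
    """A detector returned a result violating the detect contract."""


class MissingHydrogensError(StructureError):
    """Explicit hydrogens required by the requested detection are absent."""


class FileFormatError(IfpError):
    """A structure file could not be parsed."""


class FilterError(IfpError):
    """A network filter referenced unknown labels or invalid parameters."""
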