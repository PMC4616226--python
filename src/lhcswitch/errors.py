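"""Exception hierarchy for lhcswitch."""


class LhcswitchError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(LhcswitchError):
    """A fixed-width PDB record could not be parsed.

    Carries the 1-based line number of the offending record.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class PDBWriteError(LhcswitchError):
    """A model cannot be serialized to fixed-width PDB records."""


class MissingAtomError(LhcswitchError):
    """A named atom required by an operation is absent from the structure.

    Crystal structures legitimately omit atoms (e.g. disordered phytol
    tails), so every pigment-extraction path raises this named error
    instead of silently substituting coordinates.
    """

    def __init__(self, atom_name: str, context: str = ""):
        msg = f"missing atom {atom_name!r}"
        if context:
            msg += f" in {context}"
        super().__init__(msg)
        self.atom_name = atom_name
        self.context = context


class GeometryError(LhcswitchError):
    """Degenerate geometry: coincident points, collinear fit sets, etc."""


class RegistryError(LhcswitchError):
    """Invalid or incomplete pigment-registry configuration."""


class AnalysisError(LhcswitchError):
    """Invalid analysis input (empty series, mismatched lengths, ...)."""
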