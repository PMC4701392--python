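"""Exception hierarchy shared across the analysis modules."""


class CrystfoldError(Exception):
    """Base class for all package errors."""


class DegenerateSpectrumError(CrystfoldError):
    """Spectrum carries no usable intensity (zero or negative total)."""


class WindowError(CrystfoldError):
    """Requested wavelength window falls outside the recorded spectrum."""


class InvalidGeometryError(CrystfoldError):
    """Non-physical cuvette geometry (zero path or concentration)."""


class AmbiguousConditionError(CrystfoldError):
    """Two spectra claim the same denaturant condition."""


class NonIdentifiableError(CrystfoldError):
    """The data cannot constrain the requested model."""


class ConvergenceError(CrystfoldError):
    """Optimization failed to converge after multi-start."""


class StateOrderingError(CrystfoldError):
    """Fitted transition midpoints are not sequentially ordered."""


class InvalidMValueError(CrystfoldError):
    """An m-value is non-positive; midpoints are undefined."""


class ModelSelectionError(CrystfoldError):
    """No candidate model could be fitted to the data."""


class InvalidKineticsError(CrystfoldError):
    """Exponential fit collapsed to a non-positive rate."""


class DegenerateBaselineError(CrystfoldError):
    """ThT baseline spectrum has no intensity in the peak window."""


class StructureParseError(CrystfoldError):
    """PDB text could not be parsed into a structure."""


class AtomNotFoundError(CrystfoldError):
    """A requested (chain, residue, atom) selector matched nothing."""


class ChainNotFoundError(CrystfoldError):
    """A requested chain id is absent from the model."""


class PipelineError(CrystfoldError):
    """Stage-labelled failure raised by the orchestration layer."""
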