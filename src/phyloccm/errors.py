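"""Exception types raised across the package."""


class PhyloCCMError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(PhyloCCMError):
    """A state vector entry was not -1 or +1."""


class StateSpaceTooLargeError(PhyloCCMError):
    """The requested number of features exceeds the 2**n state-space guard."""


class InvalidBranchLengthError(PhyloCCMError):
    """A branch length was negative or otherwise unusable."""


class TreeShapeError(PhyloCCMError):
    """The tree violates a shape requirement (e.g. not strictly binary)."""


class MissingTipError(PhyloCCMError):
    """A leaf of the tree has no observed state."""


class MissingLeafError(PhyloCCMError):
    """A genome ID in the feature table has no corresponding leaf."""


class DegenerateTreeError(PhyloCCMError):
    """The tree has no positive path length to place a midpoint root on."""


class NewickFormatError(PhyloCCMError):
    """The Newick input failed to parse or lacks required edge lengths."""


class LabelError(PhyloCCMError):
    """Duplicate or empty leaf labels."""


class FeatureTableError(PhyloCCMError):
    """The feature table violates the 0/1 matrix contract."""


class ConstantFeatureError(PhyloCCMError):
    """A feature column is constant across genomes and cannot be fit."""


class ParameterError(PhyloCCMError):
    """Invalid user-supplied configuration values."""


class MatrixShapeError(PhyloCCMError):
    """Z/P matrices disagree in shape or feature ordering."""
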