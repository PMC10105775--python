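"""Exception hierarchy shared across the package."""


class XLValidateError(Exception):
    """Base class for all package-specific errors."""


class StructureFormatError(XLValidateError):
    """A structure file violates the expected PDB/mmCIF conventions."""


class EmptyStructureError(StructureFormatError):
    """No residue with a C-alpha atom was found."""


class PAEFormatError(XLValidateError):
    """A predicted-aligned-error JSON file is malformed."""


class CrossLinkFormatError(XLValidateError):
    """A cross-link table cannot be interpreted under the given column map."""


class SegmentationError(XLValidateError):
    """PAE segmentation could not be carried out with the given parameters."""


class SyntheticDataError(XLValidateError):
    """A synthetic-data request is infeasible (e.g. packing or pair pools)."""


class UndefinedValueError(XLValidateError):
    """A summary statistic is undefined for the given input (empty denominator)."""
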