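"""Exception hierarchy.

All package errors derive from :class:`NiftiMrsError` so callers can catch
one type at the CLI boundary.
"""


class NiftiMrsError(Exception):
    """Base class for all errors raised by this package."""


class NotNiftiMrsError(NiftiMrsError):
    """The file is a NIfTI file but carries no MRS header extension."""


class ExtensionParseError(NiftiMrsError):
    """The ecode-44 extension payload is not a valid JSON object."""


class WrongExtensionError(NiftiMrsError):
    """An extension record with an unexpected ecode was passed for parsing."""


class MandatoryKeyError(NiftiMrsError):
    """An operation attempted to remove or omit a mandatory metadata key."""


class KeyTypeError(NiftiMrsError):
    """A standard-defined key was given a value of the wrong JSON type."""


class UnknownTagError(NiftiMrsError):
    """A dim_{n} tag outside the vocabulary (and not DIM_USER_{0-2})."""


class DynamicHeaderError(NiftiMrsError):
    """A dim_{n}_header entry is malformed or has the wrong length."""


class QuaternionError(NiftiMrsError):
    """Quaternion parameters with norm greater than one beyond tolerance."""


class NonRigidAffineError(NiftiMrsError):
    """An affine with shear cannot be encoded as a NIfTI qform."""


class ConversionError(NiftiMrsError):
    """A text-format import failed (malformed data or missing metadata)."""
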