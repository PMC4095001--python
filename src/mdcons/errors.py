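"""Exception hierarchy.

Every failure class the pipeline can hit maps to its own exception so that
callers (and the CLI) can report a one-line diagnostic per failure class.
"""


class MDconsError(Exception):
    """Base class for all package errors."""


class MissingInputError(MDconsError, FileNotFoundError):
    """An input path does not exist or cannot be read."""


class NoModelsError(MDconsError):
    """A structure file contained zero parseable models."""


class ChainSelectionError(MDconsError):
    """Requested chains overlap between partners or match nothing."""


class EmptyPartnerError(MDconsError):
    """A frame has no residues assigned to one of the two partners."""


class NoContactsError(MDconsError):
    """No intermolecular contact exists in any frame (mean nc is zero)."""


class UnknownAtomError(MDconsError):
    """No van der Waals radius could be resolved for an atom."""


class SelectionError(MDconsError):
    """An atom selection is empty or ill-formed."""


class RegistryError(MDconsError):
    """A contact record refers to a residue missing from the registry."""
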