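"""Exception hierarchy shared across the package."""


class DualSarmError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DualSarmError):
    """A SMILES string could not be parsed, or violated an input contract."""


class ContractError(DualSarmError):
    """An argument violated a documented precondition."""


class InvalidProductError(DualSarmError):
    """Recombining two fragments produced a chemically invalid molecule."""


class DisconnectedMatrixError(DualSarmError):
    """The measured cells of a SAR matrix do not form a connected pattern.

    Carries the disconnected blocks as ``blocks``: a list of
    (rows, cols) tuples, one per connected component.
    """

    def __init__(self, blocks):
        self.blocks = blocks
        desc = "; ".join(
            f"block {i}: rows={sorted(r)} cols={sorted(c)}"
            for i, (r, c) in enumerate(blocks)
        )
        super().__init__(
            f"measured cells form {len(blocks)} disconnected blocks ({desc}); "
            "an additive model cannot link them"
        )
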