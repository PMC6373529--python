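"""Exception hierarchy shared by all stages.

The CLI maps :class:`InputError` to exit code 2 and :class:`StageError`
to exit code 3.
"""


class LigplaceError(Exception):
    """Base class for all toolkit errors."""


class InputError(LigplaceError, ValueError):
    """Malformed or unusable user input (bad SMILES, missing residue, ...)."""


class StageError(LigplaceError, RuntimeError):
    """A pipeline stage failed on otherwise valid input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
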