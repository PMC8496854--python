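"""Exception hierarchy.

All data-level failures raise a subclass of :class:`MoiethermError` so
callers (and the CLI) can separate usage errors from chemistry/data errors.
"""

from __future__ import annotations


class MoiethermError(Exception):
    """Base class for all package errors."""


class StructureParseError(MoiethermError):
    """The input string could not be parsed as InChI or SMILES."""

    def __init__(self, compound_id: str, structure: str, detail: str = ""):
        self.compound_id = compound_id
        self.structure = structure
        msg = f"could not parse structure for compound {compound_id!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class SanitizationError(MoiethermError):
    """The structure parsed but failed chemistry sanitization (e.g. valence)."""

    def __init__(self, compound_id: str, detail: str = ""):
        self.compound_id = compound_id
        msg = f"structure for compound {compound_id!r} failed sanitization"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class UnsupportedStructureError(MoiethermError):
    """Structure is parseable but outside the supported chemistry.

    Metals and polymeric repeat-unit wildcards are rejected: no training
    signal exists for them and their energetics are not additive in local
    atom environments.
    """


class UnknownCompoundError(MoiethermError, KeyError):
    """A reaction references a compound with no known structure."""

    def __init__(self, compound_id: str, context: str = ""):
        self.compound_id = compound_id
        msg = f"unknown compound {compound_id!r}"
        if context:
            msg += f" ({context})"
        Exception.__init__(self, msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return self.args[0]


class ReactionParseError(MoiethermError):
    """Malformed reaction string."""


class DecompositionError(MoiethermError):
    """One or more compounds could not be fragmented."""

    def __init__(self, failures: dict[str, str]):
        self.failures = dict(failures)
        ids = ", ".join(sorted(self.failures))
        super().__init__(f"fragmentation failed for compounds: {ids}")


class ConvergenceError(MoiethermError):
    """Iterative evidence maximization did not converge."""
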