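"""Exception hierarchy for mulsec."""


class MulsecError(Exception):
    """Base class for all mulsec errors."""


class MalformedSequenceError(MulsecError):
    """A sequence contains unexpected characters or has an invalid length."""


class UnknownResidueError(MulsecError):
    """A protein residue is absent from the codon usage table."""


class DesignInfeasibleError(MulsecError):
    """A constrained sequence design could not be found within the attempt budget."""


class CloningSiteConflictError(DesignInfeasibleError):
    """An assembled synthon contains a restriction site outside its designed flanks."""

    def __init__(self, message: str, position: int | None = None, motif: str | None = None):
        super().__init__(message)
        self.position = position
        self.motif = motif


class TilingInfeasibleError(MulsecError):
    """No constraint-satisfying nick placement exists for a synthon."""


class EmptyPoolError(MulsecError):
    """A pool has no oligos / no coverage signal to work with."""


class UnknownReferenceError(MulsecError):
    """An alignment refers to a reference absent from the provided set."""


class DropoutError(MulsecError):
    """Enrichment is undefined because the denominator fraction is zero."""
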