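"""Exception hierarchy for bridgewater."""


class BridgewaterError(Exception):
    """Base class for all bridgewater errors."""


class LigandNotFoundError(BridgewaterError):
    """No residue in the structure matches the ligand selector."""


class AmbiguousLigandError(BridgewaterError):
    """More than one distinct residue matches an under-specified ligand selector."""


class MalformedPDBError(BridgewaterError):
    """A coordinate record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"malformed PDB record at line {line_number}: {message}")
        self.line_number = line_number


class NoTrainingDataError(BridgewaterError):
    """Parameter optimization was invoked with an empty training set."""


class FixtureInfeasibleError(BridgewaterError):
    """A synthetic fixture specification could not be satisfied."""
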