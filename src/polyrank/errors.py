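"""Exception hierarchy shared across the package."""


class PolyrankError(Exception):
    """Base class for all package-specific errors."""


class SmilesParseError(PolyrankError):
    """A SMILES string could not be parsed into a molecular graph."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"cannot parse SMILES {smiles!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class ConfigurationError(PolyrankError):
    """Invalid or inconsistent configuration (missing columns, bad keys...)."""


class EmptyDatasetError(PolyrankError):
    """A dataset ended up with zero valid records."""


class ValidationError(PolyrankError):
    """Input values violate a documented invariant."""


class SchemeMismatchError(PolyrankError):
    """Fingerprints were produced under a different featurization scheme."""

    def __init__(self, expected: str, got: str):
        super().__init__(
            f"fingerprint scheme mismatch: model expects {expected!r}, got {got!r}"
        )


class ConvergenceError(PolyrankError):
    """The optimizer failed to reach the requested tolerance."""
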