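"""Exception types shared across the pipeline."""


class InputError(ValueError):
    """Invalid or inconsistent user input (malformed tree, alignment, table...)."""


class StaleVariantSpecError(InputError):
    """A point edit's expected ancestral residue does not match the background."""

    def __init__(self, position: int, expected: str, found: str):
        self.position = position
        self.expected = expected
        self.found = found
        super().__init__(
            f"stale variant spec at reference position {position}: "
            f"expected ancestral residue {expected!r}, background has {found!r}"
        )


class UndefinedDistanceError(ValueError):
    """A dissimilarity or normalisation is undefined (all-zero or zero denominator)."""


class IncomparableEffectsError(ValueError):
    """Mutation effects cannot be compared (e.g. one is a loss of function)."""
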