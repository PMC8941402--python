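"""Exception hierarchy for hairfield."""


class HairfieldError(Exception):
    """Base class for all hairfield errors."""


class InvalidParameterError(HairfieldError, ValueError):
    """A physical or numerical parameter is out of its valid range."""


class SingularGeometryError(HairfieldError, ValueError):
    """Two charges (hair tips, or a tip and the point charge) nearly coincide.

    The Coulomb force diverges as the separation goes to zero; distances
    below ``SINGULAR_DISTANCE`` (in hair lengths) are treated as singular.
    """


class SchemaError(HairfieldError, ValueError):
    """A configuration document violates the expected schema."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


#: Minimum tip/charge separation (hair lengths) before geometry is singular.
SINGULAR_DISTANCE = 1e-9
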