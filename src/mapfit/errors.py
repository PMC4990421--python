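"""Exception types shared across the package."""


class MapFormatError(ValueError):
    """A volumetric map file or header violates the expected MRC/CCP4 layout."""


class StructureFormatError(ValueError):
    """A coordinate file cannot be interpreted as a bead-per-residue model."""


class NumericalError(RuntimeError):
    """A numerical routine diverged (NaN energies, exploding dynamics, ...)."""
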