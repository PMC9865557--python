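"""Exception hierarchy for ilscale."""


class ILScaleError(Exception):
    """Base class for all package-specific errors."""


class TopologyParseError(ILScaleError):
    """Malformed or unresolvable topology text."""


class SharedAtomTypeError(ILScaleError):
    """An atom type is shared between target and non-target molecules."""

    def __init__(self, type_names):
        self.type_names = sorted(type_names)
        super().__init__(
            "atom type(s) shared between target and non-target molecules: "
            f"{', '.join(self.type_names)}; duplicate the type first "
            "(see duplicate_atom_type)"
        )


class SingularityError(ILScaleError):
    """A grid point (numerically) coincides with an atom position."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(
            "grid point(s) coincide with atom position(s): "
            + ", ".join(f"point {p} / atom {a}" for p, a in self.pairs)
        )


class UndefinedMetricError(ILScaleError):
    """A statistic is undefined for the given data (e.g. all values tied)."""


class UnitError(ILScaleError):
    """Mismatched or unsupported units."""


class ScheduleError(ILScaleError):
    """Invalid alchemical switching schedule (non-monotone lambda etc.)."""


class PairingError(ILScaleError):
    """Realization ids of two work stages cannot be paired."""


class SimulationError(ILScaleError):
    """The toy simulator entered an invalid state (e.g. box below 2 x cutoff)."""
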