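"""Exception hierarchy shared by all porekit stages."""


class PorekitError(Exception):
    """Base class for all porekit errors."""


class FormatError(PorekitError):
    """A structure or trajectory file could not be parsed."""


class TopologyError(PorekitError):
    """Coordinates do not match the declared topology."""


class SelectionError(PorekitError):
    """An atom/residue selection resolved to nothing (or is malformed)."""


class ConfigurationError(PorekitError):
    """Invalid configuration value (radius table, thresholds, specs)."""


class AnalysisError(PorekitError):
    """An analysis stage received input it cannot operate on."""


class GeometryError(PorekitError):
    """Degenerate geometry (coincident points, undefined angle)."""


class IntegrationError(PorekitError):
    """The dynamics integrator diverged."""
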