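"""Exception hierarchy for the swarmkin pipeline.

Errors are split by provenance: file/format problems, data-content
problems, degenerate geometry, and configuration mistakes. The CLI maps
these onto distinct exit codes.
"""


class SwarmkinError(Exception):
    """Base class for all swarmkin errors."""


class TrackFormatError(SwarmkinError):
    """A track table is structurally malformed (e.g. a mandatory column is missing)."""


class TrackDataError(SwarmkinError):
    """Track contents violate an invariant (e.g. non-monotonic timestamps)."""


class DegenerateSwarmError(SwarmkinError):
    """Too few or rank-deficient points to fit the swarm Gaussian / ellipsoid."""


class UnderDeterminedError(SwarmkinError):
    """Not enough distinct observations to fit the requested model."""


class ConfigError(SwarmkinError):
    """Invalid configuration value."""
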