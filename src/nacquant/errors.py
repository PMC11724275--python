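"""Exception hierarchy for nacquant."""


class NacquantError(Exception):
    """Base class for all nacquant errors."""


class ValidationError(NacquantError):
    """Inconsistent or duplicate identifiers / malformed inputs."""


class CoordinateError(NacquantError):
    """A feature interval falls outside its contig."""


class ContigNotFoundError(NacquantError):
    """An annotation references a contig absent from the genome."""


class EmptyGraphError(NacquantError):
    """No k-mer survives graph construction (all sequences too short)."""


class ConfigError(NacquantError):
    """Infeasible simulation or pipeline configuration."""
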