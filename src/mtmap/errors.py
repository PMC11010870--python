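"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, CapacityError -> 3,
ModelError -> 4.
"""


class MtmapError(Exception):
    """Base class for all package-specific errors."""


class ModelError(MtmapError):
    """Invalid model text or inconsistent network definition."""


class CapacityError(MtmapError):
    """A configured enumeration/state budget was exceeded."""


class ConfigError(MtmapError):
    """Invalid run configuration (paths, option combinations)."""
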