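"""Exception hierarchy for nestclust."""


class NestclustError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NestclustError, ValueError):
    """A parameter value violates a precondition."""


class InvalidInputError(NestclustError, ValueError):
    """An input dataset violates a precondition."""


class ConfigError(NestclustError, ValueError):
    """A configuration file or rule set is inconsistent."""


class UnreachableSiteError(NestclustError):
    """No route exists between two sites on the resistance surface."""

    def __init__(self, site_a, site_b, reason: str = "no route"):
        self.site_a = site_a
        self.site_b = site_b
        super().__init__(
            f"sites {site_a!r} and {site_b!r} are mutually unreachable ({reason})"
        )


class ParseError(NestclustError, ValueError):
    """An interchange file could not be parsed."""
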