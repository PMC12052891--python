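"""Exception taxonomy shared by all modules."""


class AopkgError(Exception):
    """Base class for all package errors."""


class NameResolutionError(AopkgError):
    """A category, predicate, or CURIE is not known to the relevant registry."""


class IntegrityError(AopkgError):
    """A graph violates a structural invariant (dangling edge, bad merge, ...)."""


class TopologyError(AopkgError):
    """A query graph is not a connected simple path of 1-6 hops."""


class AmbiguityError(AopkgError):
    """A label resolves to more than one synonym clique."""

    def __init__(self, token: str, candidates: list[str]):
        self.token = token
        self.candidates = sorted(candidates)
        super().__init__(
            f"label {token!r} is ambiguous between cliques: {', '.join(self.candidates)}"
        )


class BindingError(AopkgError):
    """A query template was instantiated with missing or unknown bindings."""


class ParameterError(AopkgError):
    """A size or configuration parameter is outside its documented bounds."""
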