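"""Shared exception types."""


class ParameterError(ValueError):
    """An argument is outside its allowed range or inconsistent with others."""


class TopologyError(KeyError):
    """A residue or atom identifier cannot be resolved against the topology."""


class ConnectivityError(RuntimeError):
    """A transition matrix or count matrix is not irreducible."""


class DataError(ValueError):
    """Input data violates a contract (e.g. non-positive distances)."""


class EmptyFeatureError(DataError):
    """A feature-construction step retained zero features."""
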