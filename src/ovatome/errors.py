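"""Exception types shared across the pipeline stages."""


class OvatomeError(Exception):
    """Base class for all ovatome errors."""


class InvalidConfigError(OvatomeError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class InvalidInputError(OvatomeError, ValueError):
    """An operation received data that violates its preconditions."""


class OboFormatError(OvatomeError, ValueError):
    """The ontology file is structurally invalid (cycle, dangling parent)."""


class UnknownTermError(OvatomeError, KeyError):
    """A GO term id was referenced that does not exist in the DAG."""
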