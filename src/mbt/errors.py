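"""Exception types shared across the toolkit."""


class ConfigurationError(ValueError):
    """A spec, plan or config object violates its invariants."""


class GeometryError(ValueError):
    """Two voxel lattices that must share geometry do not."""
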