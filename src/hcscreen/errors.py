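"""Exception types shared across the package."""


class HcscreenError(Exception):
    """Base class for all package-specific errors."""


class LayoutError(HcscreenError):
    """A plate layout cannot be constructed as requested."""


class GenerationError(HcscreenError):
    """A synthetic image or table cannot be generated as requested."""


class NormalizationError(HcscreenError):
    """A plate cannot be normalized (e.g. missing or degenerate controls)."""


class ContractError(HcscreenError):
    """An operation was called with inputs violating its contract."""
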