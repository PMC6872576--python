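"""Exception types shared across the package."""


class NaaquantError(Exception):
    """Base class for package-specific errors."""


class ParameterError(NaaquantError, ValueError):
    """A numeric or enum parameter violates its documented constraint."""


class InputError(NaaquantError, ValueError):
    """Runtime input (image, mask, trace) is malformed or inconsistent."""


class ConfigurationError(NaaquantError, ValueError):
    """A configuration file or config object failed validation."""


class SegmentationError(NaaquantError, RuntimeError):
    """Pixel classification could not be carried out on the given image."""


class PipelineError(NaaquantError, RuntimeError):
    """A pipeline stage failed; see the run manifest for details."""
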