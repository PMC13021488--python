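"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


class ParseError(ValueError):
    """An input file could not be parsed; the message carries the line number."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and its inputs."""
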