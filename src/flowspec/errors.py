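"""Package-wide error type.

All domain errors raise :class:`FlowSpecError` carrying a short machine-readable
``code`` (e.g. ``"peak_out_of_range"``, ``"no_flow"``) so callers and the CLI can
branch on the failure mode without parsing messages.
"""

from __future__ import annotations


class FlowSpecError(ValueError):
    """Domain error with a stable short code."""

    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(message if message is not None else code)


def require(condition: bool, code: str, message: str | None = None) -> None:
    if not condition:
        raise FlowSpecError(code, message)
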