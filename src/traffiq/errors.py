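"""Error taxonomy.

Every recoverable failure raises :class:`TraffiqError` with a short stable
``code`` so callers (and the pipeline's per-cell skip logic) can branch on it
without parsing messages.
"""

from __future__ import annotations


class TraffiqError(ValueError):
    """Domain error with a stable machine-readable code."""

    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(message or code)
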