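"""Shared plumbing: configuration errors and deterministic seed fan-out."""

from __future__ import annotations

import hashlib


class ConfigurationError(ValueError):
    """Raised when a config object violates one of its invariants."""


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage child seed from a global seed.

    Hash-based so stages can be rerun in isolation without sharing RNG
    state; result is always < 2**31.
    """
    digest = hashlib.sha256(f"{int(seed)}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
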