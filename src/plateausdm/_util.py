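"""Shared helpers: seed derivation, structured logging, table-style rounding."""

from __future__ import annotations

import hashlib
import logging
from decimal import Decimal, ROUND_HALF_UP

_LOG = logging.getLogger("plateausdm")


def get_logger() -> logging.Logger:
    return _LOG


def log_stage(stage: str, **fields) -> None:
    """Emit one structured log line: ``stage=<stage> key=value ...``."""
    parts = [f"stage={stage}"] + [f"{k}={v}" for k, v in fields.items()]
    _LOG.info(" ".join(parts))


def derive_seed(master: int, *parts) -> int:
    """Derive a child seed from a master seed and a path of string/int tags.

    The scheme is a SHA-256 hash of the master seed and the tag path,
    truncated to 31 bits, so per-stage / per-species / per-replicate streams
    are independent and reproducible from the single master seed.
    """
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for p in parts:
        h.update(b"/")
        h.update(str(p).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching conventional table formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
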