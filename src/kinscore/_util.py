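"""Shared helpers: error types, half-up rounding, logging."""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

logger = logging.getLogger("kinscore")


class KinscoreError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(KinscoreError):
    """A file does not conform to the expected layout (missing columns, bad header)."""


class ValidationError(KinscoreError):
    """A file parses but contains out-of-domain or inconsistent values."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), as tables of percentages are
    conventionally printed, rather than banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(float(x))).quantize(q, rounding=ROUND_HALF_UP))
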