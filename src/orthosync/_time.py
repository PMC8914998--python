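"""Integer-microsecond time base.

All timestamps are stored internally as int64 microseconds from stream-local
recording start. Union joins and marker alignment are then exact integer
operations; float equality never decides whether two samples coincide. CSV
round trips print 6 decimal places, i.e. exactly one quantum.
"""

from __future__ import annotations

import numpy as np

US_PER_S = 1_000_000


def to_us(seconds) -> np.ndarray | np.int64:
    """Convert seconds (scalar or array) to rounded integer microseconds."""
    return np.round(np.asarray(seconds, dtype=float) * US_PER_S).astype(np.int64)[()]


def to_s(us) -> np.ndarray | float:
    """Convert integer microseconds to float seconds."""
    return (np.asarray(us, dtype=np.int64) / US_PER_S)[()]


def format_us(us: np.ndarray) -> np.ndarray:
    """Format microsecond timestamps as fixed 6-decimal second strings."""
    return np.char.mod("%.6f", np.asarray(us, dtype=np.int64) / US_PER_S)
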