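"""Small derived quantities used in reporting."""

from __future__ import annotations

__all__ = ["cell_divisions"]


def cell_divisions(days: float, doubling_time_hours: float) -> float:
    """Number of doublings completed in ``days`` at the given doubling time.

    50 days at a ~21 h doubling time gives ~57.1 divisions.
    """
    if days < 0:
        raise ValueError("days must be >= 0")
    if doubling_time_hours <= 0:
        raise ValueError("doubling time must be > 0")
    return days * 24.0 / doubling_time_hours
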