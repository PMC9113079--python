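"""Result rendering helpers: the clinical vFFR colour scale."""

from __future__ import annotations

__all__ = ["vffr_to_colour", "GREEN", "ORANGE", "RED"]

# anchors: 1.00 no flow limitation, 0.80 borderline, 0.60 severe
GREEN = (0, 153, 0)
ORANGE = (255, 165, 0)
RED = (204, 0, 0)

_ANCHORS = ((1.00, GREEN), (0.80, ORANGE), (0.60, RED))


def vffr_to_colour(vffr: float) -> tuple[int, int, int]:
    """Piecewise-linear RGB map: green (1.00) -> orange (0.80) -> red (<= 0.60).

    Values below 0.60 clamp to red; values outside (0, 1] are rejected.
    """
    if not 0.0 < vffr <= 1.0:
        raise ValueError(f"vffr must lie in (0, 1], got {vffr}")
    if vffr <= 0.60:
        return RED
    for (v_hi, c_hi), (v_lo, c_lo) in zip(_ANCHORS, _ANCHORS[1:]):
        if v_lo <= vffr <= v_hi:
            t = (vffr - v_lo) / (v_hi - v_lo)
            return tuple(
                int(round(lo + t * (hi - lo))) for lo, hi in zip(c_lo, c_hi)
            )  # type: ignore[return-value]
    raise AssertionError("unreachable")
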