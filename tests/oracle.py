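"""Independent brute-force single-step rule table for the spindle model.

Written in absolute coordinates with explicit case analysis, deliberately
structured differently from the production update (which works in
midcell-offset coordinates with vectorized min/max expressions), so the
two can disagree if either misimplements the push/jam rules.
"""

from __future__ import annotations


def oracle_step(
    cell_length: float,
    radius: float,
    center: float,
    left_tip: float,
    right_tip: float,
    d_left: float,
    d_right: float,
    noise: float = 0.0,
):
    """One collision-resolved step.

    ``d_left`` is the signed displacement of the left tip in +x,
    ``d_right`` the signed displacement of the right tip in -x (both
    positive toward midcell). Returns (center, left_tip, right_tip).
    """
    L, r = cell_length, radius

    # desired tips, never retracting past the origin pole
    want_left = left_tip + d_left
    if want_left < 0.0:
        want_left = 0.0
    want_right = right_tip - d_right
    if want_right > L:
        want_right = L

    # how far each growing tip would cross into the nucleus
    over_left = want_left - (center - r)
    if over_left < 0.0:
        over_left = 0.0
    over_right = (center + r) - want_right
    if over_right < 0.0:
        over_right = 0.0

    # how far the nucleus could yield before contacting the opposite tip
    # (evaluated against the pre-step opposite tip: a simultaneous update)
    room_left = right_tip - (center + r)
    if room_left < 0.0:
        room_left = 0.0
    room_right = (center - r) - left_tip
    if room_right < 0.0:
        room_right = 0.0

    push_left = min(over_left, room_left)
    push_right = min(over_right, room_right)
    new_center = center + push_left - push_right

    # tips stop at the (possibly displaced) nucleus faces
    new_left = min(want_left, new_center - r)
    new_right = max(want_right, new_center + r)

    # diffusion, clamped at contacts and cell walls
    lo = max(r, new_left + r)
    hi = min(L - r, new_right - r)
    c = new_center + noise
    if c < lo:
        c = lo
    if c > hi:
        c = hi
    return c, new_left, new_right
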