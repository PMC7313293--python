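"""Day + 12-hour-clock timestamp formatting for schedules and sensor logs.

Simulation time is continuous hours from the start of the run; the start
itself falls at some hour of day 0 (e.g. 21.5 = 9:30 PM).  Output files carry
timestamps in the style ``"5d PM 1 h 13 m 59 s"``: day number since the run
began, AM/PM, and the 12-hour clock reading.
"""

from __future__ import annotations

import re

_FMT_RE = re.compile(
    r"^(?P<day>\d+)d (?P<ap>AM|PM) (?P<h>\d+) h (?P<m>\d+) m (?P<s>\d+) s$"
)


def format_sim_time(t_hours: float, init_tod_h: float) -> str:
    """Render ``t_hours`` after a start at ``init_tod_h`` hours of day 0."""
    if t_hours < 0:
        raise ValueError("t_hours must be >= 0")
    total_s = round((init_tod_h + t_hours) * 3600.0)
    day, rem = divmod(total_s, 86400)
    hod, rem = divmod(rem, 3600)
    minute, second = divmod(rem, 60)
    ampm = "AM" if hod < 12 else "PM"
    return f"{day}d {ampm} {hod % 12} h {minute} m {second} s"


def parse_sim_time(text: str, init_tod_h: float) -> float:
    """Inverse of :func:`format_sim_time` (to one-second resolution)."""
    m = _FMT_RE.match(text.strip())
    if m is None:
        raise ValueError(f"unparseable timestamp: {text!r}")
    hod = int(m["h"]) % 12 + (12 if m["ap"] == "PM" else 0)
    total_h = int(m["day"]) * 24 + hod + int(m["m"]) / 60.0 + int(m["s"]) / 3600.0
    return total_h - init_tod_h
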