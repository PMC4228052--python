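"""Plain-text serialization of spike trains.

One file holds many trains.  Each train is a header line starting with
``>`` carrying ``key=value`` metadata (always ``t_start`` and ``t_stop``),
followed by one line of whitespace-separated spike times in seconds (empty
line for a silent trial).  Round-trips exactly at 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .agent import SpikeTrain

__all__ = ["write_spike_trains", "read_spike_trains"]


def _fmt_value(v):
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v)).lower()
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return json.dumps(str(v))


def _parse_value(s: str):
    if s.startswith('"'):
        return json.loads(s)
    if s in ("true", "false"):
        return s == "true"
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def write_spike_trains(trains: list[SpikeTrain], path) -> None:
    lines = []
    for train in trains:
        fields = {"t_start": train.t_start, "t_stop": train.t_stop}
        fields.update(train.metadata)
        header = " ".join(f"{k}={_fmt_value(v)}" for k, v in fields.items())
        lines.append(f"> {header}")
        lines.append(" ".join(f"{t:.9g}" for t in train.times))
    Path(path).write_text("\n".join(lines) + "\n")


def read_spike_trains(path) -> list[SpikeTrain]:
    trains = []
    header = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith(">"):
            header = {}
            for token in line[1:].split():
                key, _, val = token.partition("=")
                header[key] = _parse_value(val)
        elif header is not None:
            times = np.array([float(t) for t in line.split()])
            t_start = float(header.pop("t_start"))
            t_stop = float(header.pop("t_stop"))
            trains.append(SpikeTrain(times, t_start, t_stop, header))
            header = None
    return trains
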