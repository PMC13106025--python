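"""ASCII ladder-diagram rendering of event logs.

Two rails (A above, V below) with one character column per ``ms_per_col``
milliseconds, intended for visual comparison with marker-channel strips.
"""

from __future__ import annotations

from typing import Dict, List

from .timing import Channel, EventLog, Marker

__all__ = ["render_ladder"]

_A_GLYPHS: Dict[Marker, str] = {
    Marker.AP: "P",
    Marker.AP_NONCAPTURE: "x",
    Marker.AS: "S",
    Marker.AR: "r",
    Marker.AS_BLANKED: "b",
}
_LEGEND = (
    "A rail: P=AP  x=AP non-capture  S=AS  r=AR  b=blanked sense | V rail: V=VP\n"
    "device: !=PVARP extension  ?=PMT suspect  D=PMT detect  T=PMT terminate  d=AP delayed"
)
_D_GLYPHS: Dict[Marker, str] = {
    Marker.PVARP_EXT: "!",
    Marker.PMT_SUSPECT: "?",
    Marker.PMT_DETECT: "D",
    Marker.PMT_TERMINATE: "T",
    Marker.AP_DELAYED: "d",
}


def render_ladder(log: EventLog, ms_per_col: int = 10, cols_per_line: int = 80) -> str:
    """Render the log as ASCII rails, chunked into strips."""
    if ms_per_col <= 0 or cols_per_line <= 0:
        raise ValueError("ms_per_col and cols_per_line must be > 0")
    if not log.events:
        return _LEGEND + "\n(empty log)\n"
    t_max = log.events[-1].time_ms
    n_cols = t_max // ms_per_col + 1
    a_rail = ["."] * n_cols
    v_rail = ["."] * n_cols
    d_rail = [" "] * n_cols

    for e in log:
        col = e.time_ms // ms_per_col
        if e.channel is Channel.A:
            a_rail[col] = _A_GLYPHS.get(e.marker, "*")
        elif e.channel is Channel.V:
            v_rail[col] = "V"
        else:
            d_rail[col] = _D_GLYPHS.get(e.marker, "*")

    lines: List[str] = [_LEGEND, ""]
    for start in range(0, n_cols, cols_per_line):
        end = min(start + cols_per_line, n_cols)
        t0 = start * ms_per_col
        lines.append(f"t={t0} ms (+{ms_per_col} ms/col)")
        lines.append("A |" + "".join(a_rail[start:end]))
        lines.append("V |" + "".join(v_rail[start:end]))
        chunk = "".join(d_rail[start:end])
        if chunk.strip():
            lines.append("  |" + chunk)
        lines.append("")
    return "\n".join(lines)
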