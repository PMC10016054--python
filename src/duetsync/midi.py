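"""Minimal Standard MIDI File (format 0/1) note-onset reader and writer.

Only what duet ingestion needs: note-on events (velocity > 0) with absolute
onset times in ms, converted from ticks via the file's tempo map (set-tempo
meta events; default 500,000 us per quarter note).  Running status is
handled on read; everything except note-on/off and set-tempo is skipped.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .simulate import EVENT_COLUMNS

DEFAULT_TEMPO_US = 500_000


@dataclass(frozen=True)
class MidiNote:
    track: int
    channel: int
    pitch: int
    velocity: int
    onset_ms: float


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _parse_track(data: bytes, track_no: int) -> tuple[list[MidiNote], list[tuple[int, int]]]:
    """Returns (notes with tick onsets stored in onset_ms field, tempo events)."""
    notes: list[MidiNote] = []
    tempos: list[tuple[int, int]] = []  # (tick, us_per_quarter)
    pos, tick, status = 0, 0, 0
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        byte = data[pos]
        if byte >= 0x80:
            status = byte
            pos += 1
        elif status == 0:
            raise ValueError("running status before any status byte")
        if status == 0xFF:  # meta
            meta_type = data[pos]
            length, pos2 = _read_varlen(data, pos + 1)
            payload = data[pos2 : pos2 + length]
            pos = pos2 + length
            if meta_type == 0x51:
                tempos.append((tick, int.from_bytes(payload, "big")))
            continue
        if status in (0xF0, 0xF7):  # sysex
            length, pos2 = _read_varlen(data, pos)
            pos = pos2 + length
            continue
        kind, channel = status & 0xF0, status & 0x0F
        n_data = 1 if kind in (0xC0, 0xD0) else 2
        params = data[pos : pos + n_data]
        pos += n_data
        if kind == 0x90 and params[1] > 0:
            notes.append(MidiNote(track_no, channel, params[0], params[1], float(tick)))
    return notes, tempos


def _ticks_to_ms(tick: float, tempo_map: list[tuple[int, int]], ppq: int) -> float:
    ms, last_tick, tempo = 0.0, 0, DEFAULT_TEMPO_US
    for t_tick, t_us in tempo_map:
        if t_tick >= tick:
            break
        ms += (t_tick - last_tick) * tempo / (ppq * 1000.0)
        last_tick, tempo = t_tick, t_us
    return ms + (tick - last_tick) * tempo / (ppq * 1000.0)


def read_midi(path: str | Path) -> list[MidiNote]:
    """All note-on events of an SMF, onsets in ms via the tempo map."""
    data = Path(path).read_bytes()
    if data[:4] != b"MThd":
        raise ValueError(f"{path}: not a Standard MIDI File (missing MThd)")
    header_len, fmt, n_tracks, division = struct.unpack(">IHHH", data[4:14])
    if fmt not in (0, 1):
        raise ValueError(f"{path}: unsupported SMF format {fmt}")
    if division & 0x8000:
        raise ValueError(f"{path}: SMPTE time division is not supported")
    pos = 8 + header_len
    notes: list[MidiNote] = []
    tempo_map: list[tuple[int, int]] = []
    for track_no in range(n_tracks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError(f"{path}: expected MTrk chunk in track {track_no}")
        (length,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        track_notes, tempos = _parse_track(data[pos + 8 : pos + 8 + length], track_no)
        notes.extend(track_notes)
        tempo_map.extend(tempos)  # format 0/1: tempo lives in (the first) track
        pos += 8 + length
    tempo_map.sort()
    out = [
        MidiNote(n.track, n.channel, n.pitch, n.velocity, _ticks_to_ms(n.onset_ms, tempo_map, division))
        for n in notes
    ]
    out.sort(key=lambda n: (n.onset_ms, n.channel, n.pitch))
    return out


def events_from_midi(
    path: str | Path,
    pair_id: int = 1,
    session: int = 1,
    trial_id: int = 1,
    melody_channel: int = 0,
    bass_channel: int = 1,
    notes_per_phrase: int = 7,
) -> pd.DataFrame:
    """Ingest one trial from an SMF: channel -> player role, note order ->
    phrase/position (first 7 notes per player are phrase 1)."""
    notes = read_midi(path)
    role_of = {melody_channel: "melody", bass_channel: "bass"}
    rows = []
    counters = {"melody": 0, "bass": 0}
    for note in notes:
        role = role_of.get(note.channel)
        if role is None:
            continue
        idx = counters[role]
        counters[role] += 1
        phrase, position = divmod(idx, notes_per_phrase)
        rows.append(
            {
                "pair_id": pair_id,
                "session": session,
                "trial_id": trial_id,
                "player_role": role,
                "phrase": phrase + 1,
                "position": position + 1,
                "pitch": note.pitch,
                "onset_ms": note.onset_ms,
            }
        )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events.sort_values(["player_role", "phrase", "position"], ascending=[False, True, True]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# writer (fixture construction and round-trip checks)
# ---------------------------------------------------------------------------

def _varlen(value: int) -> bytes:
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(chunks))


def write_midi(
    path: str | Path,
    notes: list[tuple[int, int, float]],
    ppq: int = 480,
    tempo_us: int = DEFAULT_TEMPO_US,
) -> None:
    """Write a single-track (format 0) SMF from (channel, pitch, onset_ms).

    Constant tempo; each note-on is paired with a note-off 100 ticks later is
    unnecessary for onset ingestion, so notes are emitted as note-on followed
    by a zero-velocity note-on at the next event time.
    """
    events: list[tuple[int, bytes]] = [(0, bytes((0xFF, 0x51, 0x03)) + tempo_us.to_bytes(3, "big"))]
    for channel, pitch, onset_ms in sorted(notes, key=lambda n: n[2]):
        tick = round(onset_ms * 1000.0 * ppq / tempo_us)
        events.append((tick, bytes((0x90 | channel, pitch, 64))))
        events.append((tick + ppq // 4, bytes((0x80 | channel, pitch, 0))))
    events.sort(key=lambda e: e[0])
    track = b""
    last = 0
    for tick, msg in events:
        track += _varlen(tick - last) + msg
        last = tick
    track += _varlen(0) + bytes((0xFF, 0x2F, 0x00))  # end of track
    header = b"MThd" + struct.pack(">IHHH", 6, 0, 1, ppq)
    Path(path).write_bytes(header + b"MTrk" + struct.pack(">I", len(track)) + track)
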