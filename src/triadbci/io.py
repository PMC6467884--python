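"""File formats: single-channel EDF and CSV for EEG, CSV/JSON for session logs.

The EDF writer/reader handles the plain (non-plus) European Data Format
with a single signal, which is all this package records: 16-bit samples,
one data record per second when the recording length allows, physical
units in microvolts.  Files written here are readable by standard EDF
tools (e.g. MNE's EDF reader).

Session logs serialize to JSON (lossless, plan and seeds embedded for
provenance) or to a flat CSV with one row per trial x round; the CSV
carries the plan in ``#``-prefixed metadata lines so it round-trips into
an equivalent log.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
from pathlib import Path

import numpy as np

from .game import RoundRecord, SessionLog, SessionPlan
from .synth_eeg import EEGRecording

__all__ = [
    "read_eeg",
    "write_eeg",
    "write_session_log",
    "read_session_log",
]

_EDF_HEADER = 256
_EDF_SIGNAL_HEADER = 256


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a single-channel recording as a plain EDF file."""
    n = len(rec.samples)
    fs = rec.fs
    if fs == int(fs) and n % int(fs) == 0:
        samples_per_record = int(fs)
        record_duration = 1.0
    else:
        samples_per_record = n
        record_duration = n / fs
    n_records = n // samples_per_record

    phys_max = float(np.max(np.abs(rec.samples)))
    if phys_max == 0:
        phys_max = 1.0
    # use the value as it will be stored in the 8-char header field, so the
    # reader's rescaling gain matches the writer's exactly
    phys_max = float(f"{phys_max:.6g}"[:8])
    dig_min, dig_max = -32768, 32767
    # encode with the exact inverse of the reader's affine rescaling
    gain = (2 * phys_max) / (dig_max - dig_min)
    digital = np.clip(
        np.round((rec.samples + phys_max) / gain) + dig_min, dig_min, dig_max
    ).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(_EDF_HEADER + _EDF_SIGNAL_HEADER), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad(f"{record_duration:g}"[:8], 8),
            _pad("1", 4),
        ]
    )
    signal_header = b"".join(
        [
            _pad(rec.label, 16),
            _pad("", 80),
            _pad("uV", 8),
            _pad(f"{-phys_max:.6g}"[:8], 8),
            _pad(f"{phys_max:.6g}"[:8], 8),
            _pad(str(dig_min), 8),
            _pad(str(dig_max), 8),
            _pad("", 80),
            _pad(str(samples_per_record), 8),
            _pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        fh.write(digital.tobytes())


def read_edf(path: str | Path) -> EEGRecording:
    """Read a single-channel plain EDF file written by :func:`write_edf`."""
    raw = Path(path).read_bytes()
    if len(raw) < _EDF_HEADER:
        raise ValueError(f"{path}: truncated or corrupt EDF header")

    def fld(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", errors="replace").strip()

    try:
        n_records = int(fld(236, 8))
        record_duration = float(fld(244, 8))
        n_signals = int(fld(252, 4))
    except ValueError as exc:
        raise ValueError(f"{path}: corrupt EDF header ({exc})") from None
    if n_signals != 1:
        raise ValueError(f"{path}: expected a single-channel EDF, found {n_signals} signals")
    if record_duration <= 0:
        raise ValueError(f"{path}: missing or invalid record duration (sampling rate unknown)")
    sig = _EDF_HEADER
    label = fld(sig + 0, 16)
    phys_min = float(fld(sig + 96 + 8, 8))
    phys_max = float(fld(sig + 96 + 16, 8))
    dig_min = int(fld(sig + 96 + 24, 8))
    dig_max = int(fld(sig + 96 + 32, 8))
    samples_per_record = int(fld(sig + 96 + 40 + 80, 8))
    fs = samples_per_record / record_duration

    data_offset = _EDF_HEADER + _EDF_SIGNAL_HEADER
    digital = np.frombuffer(
        raw, dtype="<i2", count=n_records * samples_per_record, offset=data_offset
    ).astype(np.float64)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    samples = (digital - dig_min) * gain + phys_min
    return EEGRecording(samples=samples, fs=fs, label=label or "Oz")


def write_csv_eeg(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as two-column CSV with a ``# fs=`` metadata line."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={rec.fs!r} label={rec.label} start_time={rec.start_time!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["time_s", "amplitude_uV"])
        for t, v in zip(rec.times, rec.samples):
            writer.writerow([repr(float(t)), repr(float(v))])


def read_csv_eeg(path: str | Path) -> EEGRecording:
    """Read a two-column CSV recording; the sampling rate must be in metadata."""
    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            for token in line.lstrip("#").split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            body_start = i + 1
        else:
            break
    if "fs" not in meta:
        raise ValueError(
            f"{path}: missing required 'fs' (sampling rate) in CSV metadata line"
        )
    fs = float(meta["fs"])
    reader = csv.reader(lines[body_start:])
    header = next(reader, None)
    if header is None or "amplitude" not in ",".join(header):
        raise ValueError(f"{path}: expected a 'time_s,amplitude_uV' header row")
    samples = np.array([float(row[1]) for row in reader if row])
    return EEGRecording(
        samples=samples,
        fs=fs,
        label=meta.get("label", "Oz"),
        start_time=float(meta.get("start_time", 0.0)),
    )


def write_eeg(rec: EEGRecording, path: str | Path, format: str | None = None) -> None:
    """Write an EEG recording as EDF or CSV (inferred from the suffix)."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "edf":
        write_edf(rec, path)
    elif fmt == "csv":
        write_csv_eeg(rec, path)
    else:
        raise ValueError(f"unsupported EEG format {fmt!r}; use 'edf' or 'csv'")


def read_eeg(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read an EEG recording from EDF or CSV (inferred from the suffix)."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "edf":
        return read_edf(path)
    if fmt == "csv":
        return read_csv_eeg(path)
    raise ValueError(f"unsupported EEG format {fmt!r}; use 'edf' or 'csv'")


_CSV_COLUMNS = [
    "trial",
    "round",
    "truth",
    "s1_intent",
    "s1_sent",
    "s2_intent",
    "s2_sent",
    "percept1",
    "percept2",
    "receiver_decision",
    "outcome",
    "forced_flag",
    "excluded_flag",
]


def _log_to_dict(log: SessionLog) -> dict:
    return {
        "plan": {
            "trials": list(log.plan.trials),
            "bad_sender": log.plan.bad_sender,
            "forced_error_trials": sorted(log.plan.forced_error_trials),
            "seed": log.plan.seed,
        },
        "seed": log.seed,
        "exclusion_mask": sorted(log.exclusion_mask),
        "outcomes": list(log.outcomes),
        "rows": [
            {
                "trial": r.trial,
                "round": r.round,
                "truth": r.truth,
                "s1_intent": r.s1_intent,
                "s1_sent": r.s1_sent,
                "s2_intent": r.s2_intent,
                "s2_sent": r.s2_sent,
                "percept1": r.percept1,
                "percept2": r.percept2,
                "receiver_intent": r.receiver_intent,
                "receiver_decision": r.receiver_decision,
                "forced_flag": r.forced_flag,
                "pulse_times": list(r.pulse_times),
                "trust_weights": list(r.trust_weights),
            }
            for r in log.rows
        ],
    }


def write_session_log(log: SessionLog, path: str | Path, format: str | None = None) -> None:
    """Serialize a session log as JSON (lossless) or flat CSV."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "json":
        Path(path).write_text(json.dumps(_log_to_dict(log), indent=1))
        return
    if fmt != "csv":
        raise ValueError(f"unsupported log format {fmt!r}; use 'json' or 'csv'")
    buf = _stdio.StringIO()
    buf.write(f"# plan_seed={log.plan.seed} session_seed={log.seed} bad_sender={log.plan.bad_sender}\n")
    writer = csv.writer(buf)
    writer.writerow(_CSV_COLUMNS)
    for r in log.rows:
        writer.writerow(
            [
                r.trial,
                r.round,
                r.truth,
                r.s1_intent,
                r.s1_sent,
                r.s2_intent,
                r.s2_sent,
                r.percept1,
                r.percept2,
                r.receiver_decision,
                log.outcomes[r.trial] if r.trial < len(log.outcomes) else "pending",
                int(r.forced_flag),
                int(r.trial in log.exclusion_mask),
            ]
        )
    Path(path).write_text(buf.getvalue())


def read_session_log(path: str | Path, format: str | None = None) -> SessionLog:
    """Deserialize a session log written by :func:`write_session_log`.

    The CSV form reconstructs the plan from metadata and row flags;
    per-round pulse times and trust trajectories (absent from the flat
    table) come back as defaults.
    """
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "json":
        d = json.loads(Path(path).read_text())
        plan = SessionPlan(
            trials=tuple(d["plan"]["trials"]),
            bad_sender=d["plan"]["bad_sender"],
            forced_error_trials=frozenset(d["plan"]["forced_error_trials"]),
            seed=d["plan"]["seed"],
        )
        rows = [
            RoundRecord(
                trial=r["trial"],
                round=r["round"],
                truth=r["truth"],
                s1_intent=r["s1_intent"],
                s1_sent=r["s1_sent"],
                s2_intent=r["s2_intent"],
                s2_sent=r["s2_sent"],
                percept1=r["percept1"],
                percept2=r["percept2"],
                receiver_intent=r["receiver_intent"],
                receiver_decision=r["receiver_decision"],
                forced_flag=r["forced_flag"],
                pulse_times=tuple(r["pulse_times"]),
                trust_weights=tuple(r["trust_weights"]),
            )
            for r in d["rows"]
        ]
        return SessionLog(
            plan=plan,
            rows=rows,
            outcomes=list(d["outcomes"]),
            exclusion_mask=frozenset(d["exclusion_mask"]),
            seed=d["seed"],
        )
    if fmt != "csv":
        raise ValueError(f"unsupported log format {fmt!r}; use 'json' or 'csv'")

    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    body = []
    for line in lines:
        if line.startswith("#"):
            for token in line.lstrip("#").split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
        else:
            body.append(line)
    reader = csv.DictReader(body)
    rows, outcomes, excluded, forced, truths = [], {}, set(), set(), {}
    for rec in reader:
        trial = int(rec["trial"])
        rows.append(
            RoundRecord(
                trial=trial,
                round=int(rec["round"]),
                truth=int(rec["truth"]),
                s1_intent=int(rec["s1_intent"]),
                s1_sent=int(rec["s1_sent"]),
                s2_intent=int(rec["s2_intent"]),
                s2_sent=int(rec["s2_sent"]),
                percept1=rec["percept1"],
                percept2=rec["percept2"],
                receiver_intent=int(rec["receiver_decision"]),
                receiver_decision=int(rec["receiver_decision"]),
                forced_flag=bool(int(rec["forced_flag"])),
            )
        )
        outcomes[trial] = rec["outcome"]
        if int(rec["excluded_flag"]):
            excluded.add(trial)
        if bool(int(rec["forced_flag"])):
            forced.add(trial)
        if int(rec["round"]) == 1:
            truths[trial] = int(rec["truth"])
    n_trials = max(outcomes) + 1
    plan = SessionPlan(
        trials=tuple(truths[t] for t in range(n_trials)),
        bad_sender=int(meta.get("bad_sender", 0)),
        forced_error_trials=frozenset(forced),
        seed=int(meta.get("plan_seed", 0)),
    )
    return SessionLog(
        plan=plan,
        rows=rows,
        outcomes=[outcomes[t] for t in range(n_trials)],
        exclusion_mask=frozenset(excluded),
        seed=int(meta.get("session_seed", 0)),
    )
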