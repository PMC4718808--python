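"""Session container and plain-text on-disk layout.

A *session* bundles one continuous LFP channel with per-unit spike trains,
a trial table and per-unit waveform features. Trials are 1.5 s nose pokes;
the odor is released 250 ms after poke onset. Sessions are stored as a
directory of CSV files plus a JSON manifest so that everything remains
diffable and language-neutral:

    manifest.json   sampling rate, sizes, metadata, schema version
    lfp.csv         one sample per line (a.u.)
    spikes.csv      unit_id,time
    trials.csv      trial,onset,outcome,odor,position,context,block
    units.csv       unit_id,cell_class,mean_rate_hz,half_max_width_us,peak_trough_us
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("spikerhythm")

POKE_DURATION = 1.5  # s; analyzed nose pokes are sustained for exactly this long
ODOR_DELAY = 0.25    # s between poke onset and odor release

SCHEMA_VERSION = 1

TRIAL_COLUMNS = ["trial", "onset", "outcome", "odor", "position", "context", "block"]
UNIT_COLUMNS = ["unit_id", "cell_class", "mean_rate_hz", "half_max_width_us",
                "peak_trough_us"]


class SessionSchemaError(ValueError):
    """A session directory or table violates the expected schema."""


@dataclass
class Session:
    """In-memory session: LFP + spike trains + trial table + unit table."""

    lfp: np.ndarray
    fs: float
    trials: pd.DataFrame
    spikes: dict[str, np.ndarray]
    units: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.lfp) / self.fs

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def accuracy(self) -> float:
        """Fraction of analyzed trials with a correct outcome."""
        if len(self.trials) == 0:
            return float("nan")
        return float((self.trials["outcome"] == "correct").mean())

    def half_sessions(self) -> tuple["Session", "Session"]:
        """Split into the two context halves; each half is analyzed separately."""
        half = self.n_trials // 2
        out = []
        for i, tr in enumerate((self.trials.iloc[:half], self.trials.iloc[half:])):
            meta = dict(self.meta)
            meta["half_session"] = i
            out.append(Session(self.lfp, self.fs, tr.reset_index(drop=True),
                               self.spikes, self.units, meta))
        return out[0], out[1]

    def validate(self) -> None:
        """Raise :class:`SessionSchemaError` on any structural violation."""
        if not np.all(np.isfinite(self.lfp)):
            raise SessionSchemaError("LFP contains non-finite samples")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise SessionSchemaError(f"trials table missing columns: {missing}")
        dur = self.duration
        onsets = self.trials["onset"].to_numpy(float)
        if len(onsets) and (onsets.min() < 0 or (onsets + POKE_DURATION).max() > dur):
            raise SessionSchemaError(
                "trial poke window extends past the recorded LFP "
                f"(duration {dur:.3f} s)")
        bad = set(self.trials["outcome"]) - {"correct", "incorrect"}
        if bad:
            raise SessionSchemaError(f"unknown trial outcomes: {sorted(bad)}")
        for uid, st in self.spikes.items():
            st = np.asarray(st, float)
            if len(st) and (st.min() < 0 or st.max() > dur):
                raise SessionSchemaError(
                    f"unit {uid}: spike times outside [0, {dur:.3f}] s")
            if np.any(np.diff(st) < 0):
                raise SessionSchemaError(f"unit {uid}: spike times not sorted")


def trial_window(onset: float) -> tuple[float, float]:
    """Half-open poke window [onset, onset + 1.5 s)."""
    return onset, onset + POKE_DURATION


def write_session(session: Session, out_dir: str | Path) -> Path:
    """Write a session to ``out_dir`` in the plain-text layout. Lossless
    round-trip up to float formatting (times and samples written with 9
    significant digits, well beyond measurement precision)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "lfp.csv", session.lfp, fmt="%.9g")
    rows = []
    for uid in session.units["unit_id"]:
        for t in session.spikes.get(str(uid), []):
            rows.append((uid, t))
    spikes = pd.DataFrame(rows, columns=["unit_id", "time"])
    spikes.to_csv(out / "spikes.csv", index=False, float_format="%.9g")
    session.trials.to_csv(out / "trials.csv", index=False, float_format="%.9g")
    session.units.to_csv(out / "units.csv", index=False, float_format="%.9g")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "sampling_rate_hz": session.fs,
        "n_samples": int(len(session.lfp)),
        "n_trials": int(session.n_trials),
        "n_units": int(len(session.units)),
        "meta": session.meta,
        "files": ["lfp.csv", "spikes.csv", "trials.csv", "units.csv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_session(in_dir: str | Path, validate: bool = True) -> Session:
    """Read a session directory written by :func:`write_session`."""
    src = Path(in_dir)
    man_path = src / "manifest.json"
    if not man_path.exists():
        raise SessionSchemaError(f"missing manifest.json in {src}")
    manifest = json.loads(man_path.read_text())
    for fname in ("lfp.csv", "spikes.csv", "trials.csv", "units.csv"):
        if not (src / fname).exists():
            raise SessionSchemaError(f"missing {fname} in {src}")
    lfp = np.loadtxt(src / "lfp.csv", dtype=float, ndmin=1)
    trials = pd.read_csv(src / "trials.csv")
    units = pd.read_csv(src / "units.csv")
    spk = pd.read_csv(src / "spikes.csv")
    spikes: dict[str, np.ndarray] = {}
    for uid in units["unit_id"]:
        uid = str(uid)
        sel = spk.loc[spk["unit_id"].astype(str) == uid, "time"]
        spikes[uid] = np.sort(sel.to_numpy(float))
    units["unit_id"] = units["unit_id"].astype(str)
    sess = Session(lfp=lfp, fs=float(manifest["sampling_rate_hz"]),
                   trials=trials, spikes=spikes, units=units,
                   meta=manifest.get("meta", {}))
    if validate:
        sess.validate()
    return sess


def filter_sessions(sessions: list[Session],
                    min_accuracy: float = 0.75) -> list[Session]:
    """Keep sessions whose behavioral accuracy is at least ``min_accuracy``.

    Sessions with an empty trial table are dropped with a warning.
    """
    kept = []
    for s in sessions:
        if s.n_trials == 0:
            log.warning("dropping session %s: empty trial table",
                        s.meta.get("session_id", "?"))
            continue
        if s.accuracy() >= min_accuracy:
            kept.append(s)
        else:
            log.info("dropping session %s: accuracy %.3f < %.2f",
                     s.meta.get("session_id", "?"), s.accuracy(), min_accuracy)
    return kept
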