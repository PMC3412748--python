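"""Epoch file formats: long-format TSV plus a JSON sidecar per session.

The TSV has one row per sample (columns: subject_id, paradigm, trial_index,
phase, stimulus, channel, t_s, value); beat channels use one row per beat
with ``value`` the beat time in ms.  The sidecar records the sampling rate,
channel units and the per-epoch onset/offset (and UCS) times the TSV cannot
carry.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .epochs import CHANNELS, CHANNEL_UNITS, SAMPLED_CHANNELS, SignalEpoch
from .exceptions import ParseError, ValidationError

TSV_COLUMNS = [
    "subject_id", "paradigm", "trial_index", "phase", "stimulus", "channel",
    "t_s", "value",
]

_KEY_FIELDS = ("subject_id", "paradigm", "trial_index", "phase", "stimulus", "channel")


def _epoch_key(ep: SignalEpoch):
    return (ep.subject_id, ep.paradigm, int(ep.trial_index),
            ep.phase or "", ep.stimulus, ep.channel)


def write_epochs(epochs: Iterable[SignalEpoch], tsv_path, sidecar_path) -> None:
    """Write an epoch collection to TSV + JSON sidecar."""
    epochs = list(epochs)
    frames = []
    meta = []
    for ep in epochs:
        if ep.channel in SAMPLED_CHANNELS:
            t = ep.sample_times
            vals = ep.samples
        else:
            t = ep.beat_times / 1000.0
            vals = ep.beat_times
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": ep.subject_id,
                    "paradigm": ep.paradigm,
                    "trial_index": ep.trial_index,
                    "phase": ep.phase or "",
                    "stimulus": ep.stimulus,
                    "channel": ep.channel,
                    "t_s": np.round(t, 9),
                    "value": vals,
                }
            )
        )
        meta.append(
            {
                "subject_id": ep.subject_id,
                "paradigm": ep.paradigm,
                "trial_index": int(ep.trial_index),
                "phase": ep.phase,
                "stimulus": ep.stimulus,
                "channel": ep.channel,
                "sampling_rate": ep.sampling_rate,
                "onset_time": ep.onset_time,
                "offset_time": ep.offset_time,
                "ucs_onset_time": ep.ucs_onset_time,
                "ucs_offset_time": ep.ucs_offset_time,
            }
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TSV_COLUMNS)
    table.to_csv(tsv_path, sep="\t", index=False)
    sidecar = {"units": CHANNEL_UNITS, "epochs": meta}
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_epochs(tsv_path, sidecar_path) -> List[SignalEpoch]:
    """Read and validate an epoch collection from TSV + JSON sidecar.

    Raises :class:`ParseError` naming the offending line or field for
    malformed rows, unknown channel labels or sidecar/TSV disagreements.
    """
    try:
        table = pd.read_csv(tsv_path, sep="\t", dtype={"phase": str}, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{tsv_path}: {exc}") from exc
    missing_cols = [c for c in TSV_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ParseError(f"{tsv_path}: missing columns {missing_cols}")
    bad = set(table["channel"]) - set(CHANNELS)
    if bad:
        raise ParseError(f"{tsv_path}: unknown channel labels {sorted(bad)}")
    try:
        sidecar = json.loads(Path(sidecar_path).read_text())
        entries = sidecar["epochs"]
    except KeyError as exc:
        raise ParseError(f"{sidecar_path}: missing sidecar field {exc}") from exc
    except Exception as exc:
        raise ParseError(f"{sidecar_path}: {exc}") from exc

    by_key = {}
    for i, m in enumerate(entries):
        try:
            key = (m["subject_id"], m["paradigm"], int(m["trial_index"]),
                   m["phase"] or "", m["stimulus"], m["channel"])
        except KeyError as exc:
            raise ParseError(f"{sidecar_path}: epoch entry {i} missing field {exc}") from exc
        by_key[key] = m

    epochs = []
    grouped = table.groupby(list(_KEY_FIELDS), sort=False)
    for key, rows in grouped:
        key = (key[0], key[1], int(key[2]), key[3], key[4], key[5])
        m = by_key.get(key)
        if m is None:
            raise ParseError(
                f"{tsv_path}: epoch {key} has no sidecar entry (first line "
                f"{rows.index[0] + 2})"
            )
        channel = key[5]
        rows = rows.sort_values("t_s")
        common = dict(
            subject_id=key[0],
            paradigm=key[1],
            trial_index=key[2],
            phase=key[3] or None,
            stimulus=key[4],
            channel=channel,
            onset_time=float(m["onset_time"]),
            offset_time=float(m["offset_time"]),
            ucs_onset_time=m.get("ucs_onset_time"),
            ucs_offset_time=m.get("ucs_offset_time"),
        )
        try:
            if channel in SAMPLED_CHANNELS:
                ep = SignalEpoch(
                    samples=rows["value"].to_numpy(dtype=float),
                    sampling_rate=float(m["sampling_rate"]),
                    **common,
                )
            else:
                ep = SignalEpoch(
                    beat_times=rows["value"].to_numpy(dtype=float), **common
                )
        except ValidationError as exc:
            raise ParseError(f"{tsv_path}: epoch {key}: {exc}") from exc
        epochs.append(ep)

    if len(by_key) != len(epochs):
        seen = {_epoch_key(e) for e in epochs}
        orphans = [k for k in by_key if k not in seen]
        raise ParseError(f"{sidecar_path}: sidecar entries without TSV rows: {orphans[:3]}")
    return epochs


def write_features_csv(features: pd.DataFrame, path) -> None:
    """Features CSV: one row per subject, missing values as empty fields."""
    features.to_csv(path, index=False, na_rep="")


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
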