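"""Session fixture I/O: columnar TSV per recording + JSON sidecar.

The fixture format is deliberately plain text: one column per channel
with a header row of labels, and a sidecar ``<prefix>.json`` holding the
sampling rate, seeds, ground-truth parameters, and trigger sample
indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording


def write_session_fixture(prefix, recording: Recording, triggers=None,
                          metadata: dict | None = None) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (channels as columns) and ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    side = prefix.with_suffix(".json")
    pd.DataFrame(recording.data.T, columns=list(recording.channels)).to_csv(
        tsv, sep="\t", index=False, float_format="%.6g"
    )
    meta = {
        "fs": recording.fs,
        "channels": list(recording.channels),
        "ground_truth": recording.ground_truth,
        "trigger_samples": [int(t) for t in triggers] if triggers is not None else None,
    }
    if metadata:
        meta.update(metadata)
    side.write_text(json.dumps(meta, indent=2, default=float))
    return tsv, side


def read_session_fixture(prefix) -> tuple[Recording, dict]:
    """Read a fixture written by :func:`write_session_fixture`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    rec = Recording(
        data=np.ascontiguousarray(df.to_numpy().T),
        fs=float(meta["fs"]),
        channels=tuple(meta["channels"]),
        ground_truth=meta.get("ground_truth"),
    )
    return rec, meta
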