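"""Session file format: a directory with a JSON manifest plus one delimited
text (CSV) table per channel.

The manifest registers every channel with its file name and per-column
units; readers validate the registry, reject newer format majors, preserve
unknown channels opaquely, and report parse failures with the offending
file and row.  Timestamps are seconds from session start throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = "1.0"
MANIFEST_NAME = "manifest.json"


class SessionFormatError(RuntimeError):
    pass


@dataclass
class ChannelSpec:
    file: str
    units: dict[str, str]
    cadence_hz: float | None = None


@dataclass
class SessionManifest:
    session_id: str
    kind: str
    seed: int | None = None
    created: str = ""
    format_version: str = FORMAT_VERSION
    device_config: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    channels: dict[str, ChannelSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat(timespec="seconds")


def write_session(
    out_dir,
    manifest: SessionManifest,
    channels: dict[str, pd.DataFrame],
    units: dict[str, dict[str, str]],
) -> SessionManifest:
    """Write a session directory; returns the completed manifest.

    Every value column of every channel must have a declared unit; duplicate
    channel names are rejected.  Tables round-trip bit-exactly through
    ``repr``-precision CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(set(channels)) != len(channels):
        raise SessionFormatError("duplicate channel names")
    manifest.channels = {}
    for name, table in channels.items():
        if name in manifest.channels:
            raise SessionFormatError(f"duplicate channel {name!r}")
        cols_needing_units = [c for c in table.columns if c != "t_s"]
        declared = units.get(name, {})
        missing = [c for c in cols_needing_units if c not in declared]
        if missing:
            raise SessionFormatError(f"channel {name!r}: missing units for {missing}")
        fname = f"{name}.csv"
        table.to_csv(out / fname, index=False, float_format="%.17g")
        manifest.channels[name] = ChannelSpec(file=fname, units=dict(declared))

    doc = {
        "format_version": manifest.format_version,
        "session_id": manifest.session_id,
        "kind": manifest.kind,
        "created": manifest.created,
        "seed": manifest.seed,
        "device_config": manifest.device_config,
        "protocol": manifest.protocol,
        "channels": {
            n: {"file": c.file, "units": c.units, "cadence_hz": c.cadence_hz}
            for n, c in manifest.channels.items()
        },
    }
    (out / MANIFEST_NAME).write_text(json.dumps(doc, indent=1))
    return manifest


def read_session(directory) -> tuple[SessionManifest, dict[str, pd.DataFrame]]:
    """Read and validate a session directory.

    Raises :class:`SessionFormatError` for a missing manifest, a newer
    format major, a registered-but-missing file, or a corrupted table (the
    error names the file and row).  Files on disk that the manifest does not
    register are ignored with a warning attribute rather than an error.
    """
    d = Path(directory)
    mpath = d / MANIFEST_NAME
    if not mpath.exists():
        raise SessionFormatError(f"no {MANIFEST_NAME} in {d}")
    doc = json.loads(mpath.read_text())
    version = doc.get("format_version", "0.0")
    if int(str(version).split(".")[0]) > int(FORMAT_VERSION.split(".")[0]):
        raise SessionFormatError(
            f"session format {version} is newer than supported {FORMAT_VERSION}"
        )
    manifest = SessionManifest(
        session_id=doc["session_id"],
        kind=doc["kind"],
        seed=doc.get("seed"),
        created=doc.get("created", ""),
        format_version=version,
        device_config=doc.get("device_config", {}),
        protocol=doc.get("protocol", {}),
        channels={
            n: ChannelSpec(file=c["file"], units=c.get("units", {}), cadence_hz=c.get("cadence_hz"))
            for n, c in doc.get("channels", {}).items()
        },
    )
    channels: dict[str, pd.DataFrame] = {}
    for name, spec in manifest.channels.items():
        fpath = d / spec.file
        if not fpath.exists():
            raise SessionFormatError(f"channel {name!r}: file {spec.file} is missing")
        try:
            table = pd.read_csv(fpath, float_precision="round_trip")
        except Exception as exc:  # surface the file in the error
            raise SessionFormatError(f"{spec.file}: failed to parse ({exc})") from exc
        if "t_s" in table.columns:
            table["t_s"] = table["t_s"].astype(float)
        _validate_table(table, fpath.name)
        channels[name] = table
    return manifest, channels


def _validate_table(table: pd.DataFrame, fname: str) -> None:
    if "t_s" in table.columns:
        t = table["t_s"].to_numpy()
        bad = np.nonzero(~np.isfinite(t))[0]
        if bad.size:
            raise SessionFormatError(f"{fname}: row {int(bad[0]) + 2}: non-finite timestamp")
    numeric = table.select_dtypes(include="number")
    if numeric.shape[1]:
        nan_rows = np.nonzero(numeric.isna().any(axis=1).to_numpy())[0]
        if nan_rows.size:
            raise SessionFormatError(f"{fname}: row {int(nan_rows[0]) + 2}: missing value")
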