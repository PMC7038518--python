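"""Snap manifest I/O.

A manifest is the positional ledger of a scan: one JSON record per snap
(strip index, angle index, angle, depth, band, filename, plus whatever a
stage appends — crop offsets, gains).  Stored as JSON lines with a leading
schema header; unknown fields round-trip untouched.
"""

from __future__ import annotations

import json
from pathlib import Path

SCHEMA_VERSION = 1

REQUIRED_FIELDS = ("strip_idx", "angle_idx", "angle_deg", "depth_mm",
                   "band_nm")


class ManifestError(ValueError):
    pass


def validate_records(records: list[dict]) -> None:
    """Check required fields and (strip, angle, band) uniqueness."""
    seen = set()
    for i, rec in enumerate(records):
        for f in REQUIRED_FIELDS:
            if f not in rec:
                raise ManifestError(f"record {i} missing field {f!r}")
        key = (rec["strip_idx"], rec["angle_idx"], rec["band_nm"])
        if key in seen:
            raise ManifestError(f"duplicate (strip, angle, band) {key}")
        seen.add(key)


def write_manifest(records: list[dict], path) -> None:
    validate_records(records)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"schema_version": SCHEMA_VERSION}) + "\n")
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_manifest(path, check_paths: bool = False) -> list[dict]:
    path = Path(path)
    records: list[dict] = []
    with path.open() as fh:
        first = fh.readline()
        head = json.loads(first) if first.strip() else {}
        if "schema_version" not in head:
            # headerless file: the first line is already a record
            records.append(head)
        elif head["schema_version"] > SCHEMA_VERSION:
            raise ManifestError(
                f"manifest schema {head['schema_version']} is newer than "
                f"supported {SCHEMA_VERSION}")
        for line in fh:
            if line.strip():
                records.append(json.loads(line))
    validate_records(records)
    if check_paths:
        for rec in records:
            if "filename" in rec:
                p = path.parent / rec["filename"]
                if not p.exists():
                    raise ManifestError(f"missing snap file {p}")
    return records
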