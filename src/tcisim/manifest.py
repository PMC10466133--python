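"""Run manifests: a JSON record that makes every run re-creatable.

A manifest snapshots the configuration, seed and package version together
with a checksum inventory of every file the run wrote, so a rerun from the
same manifest must reproduce the outputs byte-identically (timestamps aside).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

from . import __version__

__all__ = ["write_manifest", "read_manifest", "sha256_file"]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int, files: list[str]) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "artifact": "tcisim",
        "version": __version__,
        "created_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "outputs": {
            name: sha256_file(out_dir / name)
            for name in sorted(files)
            if (out_dir / name).exists()
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
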