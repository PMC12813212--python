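"""Run manifests: config snapshot, input/output checksums, seeds, version."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the run seed: stable, collision-resistant,
    and below 2**31 so it can feed any RNG API."""
    digest = hashlib.sha256(f"{stage}:{base_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def write_manifest(out_dir, command: str, config: dict, inputs=(), outputs=(),
                   seed=None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "inputs": {str(p): file_checksum(p) for p in inputs if Path(p).exists()},
        "outputs": {str(p): file_checksum(p) for p in outputs if Path(p).exists()},
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
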