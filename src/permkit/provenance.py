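"""Run-metadata sidecars: every tabular artifact gets a JSON companion
recording the package version, parameters, seed, and input-file hashes, so
an output can always be traced back to how it was produced."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_sidecar(
    artifact_path: str | Path,
    parameters: dict,
    inputs: list[str | Path] | None = None,
    seed: int | None = None,
) -> Path:
    """Write ``<artifact>.meta.json`` next to an output file."""
    artifact_path = Path(artifact_path)
    meta = {
        "artifact": artifact_path.name,
        "version": __version__,
        "seed": seed,
        "parameters": {k: v for k, v in parameters.items() if v is not None},
        "inputs": {
            str(p): _hash_file(Path(p)) for p in (inputs or []) if Path(p).exists()
        },
    }
    out = artifact_path.with_suffix(artifact_path.suffix + ".meta.json")
    out.write_text(json.dumps(meta, indent=1, default=str))
    return out
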