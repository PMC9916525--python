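"""Reproducibility manifest written next to every pipeline output."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    subcommand: str,
    parameters: dict,
    seed: int | None,
    input_paths: dict[str, str | Path],
    output_paths: list[str | Path],
) -> dict:
    from . import __version__

    return {
        "tool": "ipscmine",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "subcommand": subcommand,
        "parameters": parameters,
        "master_seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in input_paths.items()
            if Path(p).exists()
        },
        "outputs": [str(p) for p in output_paths],
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
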