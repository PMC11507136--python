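"""Provenance-stamped CSV output.

Every table the pipeline writes carries a comment header recording the
package version, the RNG seed and a hash of the generating configuration,
so a result file can always be traced back to the run that produced it.
Headers are deterministic (no timestamps): a rerun with the same seed and
configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__


def config_hash(config: Mapping[str, Any]) -> str:
    """SHA-256 of the canonical JSON form of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance_lines(meta: Mapping[str, Any]) -> list[str]:
    lines = [f"# telehealth-cea version: {__version__}"]
    for key, value in meta.items():
        lines.append(f"# {key}: {value}")
    return lines


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, Any] | None = None) -> None:
    """Write ``df`` as CSV preceded by '#'-prefixed provenance lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance_lines(meta or {}):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping provenance lines."""
    return pd.read_csv(path, comment="#")
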