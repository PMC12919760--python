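"""Delimited-text report writing with embedded provenance.

Every report carries the bundle's config hash, the seed in force and the
package version as ``#``-prefixed comment lines above the CSV header, so
results remain traceable to the exact configuration that produced them.
Numeric results live only in these files, never in logs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["write_report", "read_report"]


def write_report(df: pd.DataFrame, path, *, config_hash: str,
                 seed: int | None = None,
                 extra: dict[str, object] | None = None,
                 index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config_hash, "seed": seed, "version": __version__}
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        for key, value in meta.items():
            if value is not None:
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=index)
    return path


def read_report(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a report back, returning (frame, metadata)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            key, _, value = line[2:].partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    return df, meta
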