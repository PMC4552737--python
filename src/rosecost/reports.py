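"""CSV report serialization with a provenance header.

Every report starts with ``#``-prefixed comment lines echoing the package
version, the configuration and the run settings, so any numeric cell in a
written report can be regenerated from the file alone.  Headers contain no
timestamps: reruns with the same inputs are byte-identical.
"""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Mapping

import pandas as pd


def _package_version() -> str:
    try:
        return version("rosecost")
    except PackageNotFoundError:  # pragma: no cover - only when run from a checkout
        return "unknown"


def provenance(**settings) -> dict[str, str]:
    """Assemble the standard provenance header fields."""
    meta = {"rosecost_version": _package_version()}
    meta.update({k: str(v) for k, v in settings.items() if v is not None})
    return meta


def write_table(
    frame: pd.DataFrame, path: str | Path, meta: Mapping[str, str], index: bool = False
) -> Path:
    """Write a DataFrame as CSV preceded by '# key: value' provenance lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# {key}: {value}" for key, value in meta.items()]
    body = frame.to_csv(index=index)
    path.write_text("\n".join(lines) + "\n" + body, encoding="utf-8")
    return path


def read_table(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read back a report written by :func:`write_table`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(": ")
            meta[key] = value
    frame = pd.read_csv(path, comment="#")
    return meta, frame
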