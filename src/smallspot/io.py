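"""Delimited-text table I/O with a minimal `# key = value` header block.

All pipeline tables are tab-separated so they stay human-readable and
round-trip losslessly through pandas.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd


def write_table(df: pd.DataFrame, path, header: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = v.strip()
            else:
                lines.append(line)
    return (
        pd.read_csv(_io.StringIO("".join(lines)), sep="\t", float_precision="round_trip"),
        meta,
    )
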