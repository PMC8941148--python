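"""CSV interchange with provenance headers.

Every table written by a pipeline stage carries '#'-prefixed header
lines recording the stage, its parameters and the seed, so any numeric
output is traceable; readers skip these lines transparently.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        # shortest round-trip float representation: written tables re-read
        # bit-identically
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def read_provenance(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            out[key.strip()] = value.strip()
    return out
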