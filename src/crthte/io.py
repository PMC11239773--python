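"""Reading and writing the package's delimited tables.

All artifacts are tab-separated files with a header row: the
individual-level table, the cluster table, the allocation (cluster_id,
arm), the cluster-level summary, raw fit results, and the
operating-characteristics summary.  Column layouts are documented on
the producing modules.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .randomize import Allocation

__all__ = [
    "write_table",
    "read_table",
    "write_allocation",
    "read_allocation",
    "load_config",
]


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_allocation(allocation: Allocation, path: str | Path) -> Path:
    return write_table(allocation.to_frame(), path)


def read_allocation(path: str | Path) -> Allocation:
    frame = read_table(path)
    return Allocation(
        arms={int(r.cluster_id): int(r.arm) for r in frame.itertuples()}
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config
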