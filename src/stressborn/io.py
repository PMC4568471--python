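"""CSV/JSON contracts shared by the pipeline stages.

Schemas
-------
``individuals.csv``: id, birth_year, birth_month, region, mother_id,
    birth_order, maternal_age, last_seen_age, censored, calving_ages
    (semicolon-separated ages in years).
``gcm.csv``: female_id, age, month, concentration_ng_g.
``bins.csv``: the observation-bin modelling table (one elephant x 3-year bin
    per row).

Files written by this module start with a single ``#`` metadata comment line
(config hash and seed) so that a run is attributable; readers skip it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "config_hash",
    "write_csv",
    "read_csv",
    "write_individuals",
    "read_individuals",
    "write_json",
    "read_json",
]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _meta_line(meta: Optional[dict]) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# {parts}\n"


def write_csv(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_meta_line(meta))
        df.to_csv(fh, index=False)


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_individuals(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    out = df.copy()
    out["calving_ages"] = [
        ";".join(repr(float(a)) for a in ages) for ages in out["calving_ages"]
    ]
    write_csv(out, path, meta)


def read_individuals(path) -> pd.DataFrame:
    df = read_csv(path, dtype={"mother_id": str})
    df["mother_id"] = df["mother_id"].fillna("")
    df["calving_ages"] = [
        [float(a) for a in str(s).split(";") if a] if isinstance(s, str) else []
        for s in df["calving_ages"]
    ]
    return df


def write_json(obj, path, meta: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if meta:
        payload["_meta"] = dict(sorted(meta.items()))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
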