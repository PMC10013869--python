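"""Serialization of circuit specifications, parameters, and batch results."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .circuits import CircuitSpec, Concentrations, RateParameters
from .metrics import ResponseSummary

__all__ = [
    "save_circuit",
    "load_circuit",
    "summaries_to_csv",
    "load_parameter_table",
]


def save_circuit(
    path: str | Path,
    spec: CircuitSpec,
    params: RateParameters | None = None,
    conc: Concentrations | None = None,
) -> None:
    """Write spec (+ optional parameters/concentrations) as YAML or JSON."""
    payload: dict = {"spec": asdict(spec)}
    if params is not None:
        payload["params"] = asdict(params)
    if conc is not None:
        payload["conc"] = asdict(conc)
    path = Path(path)
    text = (
        json.dumps(payload, indent=1)
        if path.suffix == ".json"
        else yaml.safe_dump(payload, sort_keys=False)
    )
    path.write_text(text)


def load_circuit(
    path: str | Path,
) -> tuple[CircuitSpec, RateParameters | None, Concentrations | None]:
    path = Path(path)
    raw = (
        json.loads(path.read_text())
        if path.suffix == ".json"
        else yaml.safe_load(path.read_text())
    )
    spec = CircuitSpec(**raw["spec"])
    params = RateParameters(**raw["params"]) if "params" in raw else None
    conc = Concentrations(**raw["conc"]) if "conc" in raw else None
    return spec, params, conc


def summaries_to_csv(
    path: str | Path, summaries: dict[str, ResponseSummary]
) -> pd.DataFrame:
    """Write a metrics table keyed by circuit_id; returns the DataFrame."""
    df = pd.DataFrame(
        [{"circuit_id": cid, **rs.to_dict()} for cid, rs in summaries.items()]
    )
    df.to_csv(path, index=False)
    return df


def load_parameter_table(path: str | Path) -> dict[str, RateParameters]:
    """Read a circuit-parameter CSV (circuit_id + RateParameters columns)."""
    df = pd.read_csv(path)
    fields = set(RateParameters.__dataclass_fields__)
    out = {}
    for _, row in df.iterrows():
        kw = {k: v for k, v in row.items() if k in fields and pd.notna(v)}
        out[str(row["circuit_id"])] = RateParameters(**kw)
    return out
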