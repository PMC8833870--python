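"""File formats: TAC CSV, patient-bundle JSON, S-matrix/sphere/mass CSVs,
run configuration YAML, and the machine-readable report schema.

All CSVs are comma-separated, dot-decimal, UTF-8, with a mandatory header.
Units are carried in column names.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dose_engine import SphereModelTable, SValueMatrix
from .kinetics import SampleMode, TimeActivityCurve
from .source_mapping import Lesion, PatientBundle

__all__ = [
    "read_tac_csv",
    "write_tac_csv",
    "read_patient_bundle",
    "write_patient_bundle",
    "read_s_matrix",
    "read_sphere_table",
    "read_tissue_weights",
    "packaged_data_path",
    "load_report_schema",
    "validate_report",
]

_TAC_COLUMNS = ["region", "time_h", "value", "mode"]


def packaged_data_path(name: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(resources.files("dosepipe.data") / name)


def read_tac_csv(path: str | Path, injected_activity_mbq: float) -> dict[str, TimeActivityCurve]:
    """Read curves from a ``region,time_h,value,mode`` CSV, one per region."""
    df = pd.read_csv(path)
    missing = [c for c in _TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TAC CSV missing columns: {missing}")
    curves: dict[str, TimeActivityCurve] = {}
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("time_h")
        modes = set(grp["mode"])
        if len(modes) != 1:
            raise ValueError(f"mixed modes for region {region!r}")
        curves[str(region)] = TimeActivityCurve.from_arrays(
            str(region),
            grp["time_h"].to_numpy(float),
            grp["value"].to_numpy(float),
            injected_activity_mbq,
            mode=SampleMode(modes.pop()),
        )
    return curves


def write_tac_csv(path: str | Path, curves: dict[str, TimeActivityCurve]) -> None:
    rows = [
        {"region": c.region, "time_h": s.time_h, "value": s.value, "mode": s.mode.value}
        for c in curves.values()
        for s in c.samples
    ]
    pd.DataFrame(rows, columns=_TAC_COLUMNS).to_csv(path, index=False)


def _curve_to_json(curve: TimeActivityCurve) -> dict[str, Any]:
    return {
        "region": curve.region,
        "mode": curve.mode.value,
        "samples": [{"time_h": s.time_h, "value": s.value} for s in curve.samples],
    }


def _curve_from_json(obj: dict[str, Any], injected: float) -> TimeActivityCurve:
    mode = SampleMode(obj.get("mode", "activity"))
    return TimeActivityCurve.from_arrays(
        obj["region"],
        [s["time_h"] for s in obj["samples"]],
        [s["value"] for s in obj["samples"]],
        injected,
        mode=mode,
    )


def write_patient_bundle(path: str | Path, bundle: PatientBundle) -> None:
    obj = {
        "patient_id": bundle.patient_id,
        "injected_activity_MBq": bundle.injected_activity_mbq,
        "kidney_volume_mL": bundle.kidney_volume_ml,
        "curves": [_curve_to_json(c) for c in bundle.curves.values()],
        "lesions": [
            {
                "id": lesion.lesion_id,
                "volume_mL": lesion.volume_ml,
                "conc_curve": _curve_to_json(lesion.conc_curve),
            }
            for lesion in bundle.lesions
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=2), encoding="utf-8")


def read_patient_bundle(path: str | Path) -> PatientBundle:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    injected = float(obj["injected_activity_MBq"])
    curves = {c["region"]: _curve_from_json(c, injected) for c in obj["curves"]}
    lesions = tuple(
        Lesion(
            lesion_id=str(item["id"]),
            volume_ml=float(item["volume_mL"]),
            conc_curve=_curve_from_json(item["conc_curve"], injected),
        )
        for item in obj.get("lesions", [])
    )
    return PatientBundle(
        patient_id=str(obj["patient_id"]),
        injected_activity_mbq=injected,
        kidney_volume_ml=float(obj["kidney_volume_mL"]),
        curves=curves,
        lesions=lesions,
    )


def read_s_matrix(
    s_values_path: str | Path, masses_path: str | Path | None = None,
    phantom: str = "file", provenance: str = "",
) -> SValueMatrix:
    """Load an S-matrix from ``source,target,s_value_Gy_per_MBq_h`` CSV.

    ``masses_path`` optionally supplies ``region,mass_g`` reference masses
    used for patient-specific self-dose scaling.
    """
    df = pd.read_csv(s_values_path)
    required = ["source", "target", "s_value_Gy_per_MBq_h"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"S-matrix CSV missing columns: {missing}")
    sources = list(dict.fromkeys(df["source"]))
    targets = list(dict.fromkeys(df["target"]))
    values = np.zeros((len(targets), len(sources)))
    for _, row in df.iterrows():
        values[targets.index(row["target"]), sources.index(row["source"])] = float(
            row["s_value_Gy_per_MBq_h"]
        )
    masses: dict[str, float] = {}
    if masses_path is not None:
        mdf = pd.read_csv(masses_path)
        if not {"region", "mass_g"} <= set(mdf.columns):
            raise ValueError("masses CSV needs columns region,mass_g")
        masses = dict(zip(mdf["region"].astype(str), mdf["mass_g"].astype(float)))
    return SValueMatrix(
        sources=tuple(sources),
        targets=tuple(targets),
        values=values,
        reference_masses_g=masses,
        phantom=phantom,
        provenance=provenance or str(s_values_path),
    )


def read_sphere_table(
    path: str | Path, delta_gy_g_per_mbq_h: float, density_g_per_ml: float = 1.92
) -> SphereModelTable:
    """Load absorbed-fraction nodes from a ``mass_g,phi`` CSV."""
    df = pd.read_csv(path)
    if not {"mass_g", "phi"} <= set(df.columns):
        raise ValueError("sphere CSV needs columns mass_g,phi")
    return SphereModelTable(
        delta_gy_g_per_mbq_h=delta_gy_g_per_mbq_h,
        phi_nodes=tuple(zip(df["mass_g"].astype(float), df["phi"].astype(float))),
        tissue_density_g_per_ml=density_g_per_ml,
    )


def read_tissue_weights(path: str | Path) -> dict[str, float]:
    """Load tissue weighting factors from a ``region,weight`` CSV."""
    df = pd.read_csv(path)
    if not {"region", "weight"} <= set(df.columns):
        raise ValueError("weights CSV needs columns region,weight")
    return dict(zip(df["region"].astype(str), df["weight"].astype(float)))


def load_yaml(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        obj = yaml.safe_load(fh)
    return obj or {}


# --- report schema -----------------------------------------------------

def load_report_schema() -> dict[str, Any]:
    """The JSON schema the machine-readable cohort report conforms to."""
    return json.loads(packaged_data_path("report_schema.json").read_text("utf-8"))


def _check(instance: Any, schema: dict[str, Any], path: str, errors: list[str]) -> None:
    typ = schema.get("type")
    typemap = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "boolean": bool, "null": type(None),
    }
    if typ is not None:
        expected = typemap[typ]
        ok = isinstance(instance, expected)
        if typ == "number" and isinstance(instance, bool):
            ok = False
        if not ok:
            errors.append(f"{path or '$'}: expected {typ}")
            return
    if typ == "object":
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{path or '$'}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}", errors)
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            known = set(schema.get("properties", {}))
            for key, value in instance.items():
                if key not in known:
                    _check(value, extra, f"{path}.{key}", errors)
    elif typ == "array" and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{path}[{i}]", errors)


def validate_report(report: Any, schema: dict[str, Any] | None = None) -> list[str]:
    """Structurally validate a report against the shipped JSON schema.

    Covers the schema subset used (type/required/properties/items/
    additionalProperties). Returns a list of violations, empty when valid.
    """
    schema = schema or load_report_schema()
    errors: list[str] = []
    _check(report, schema, "", errors)
    return errors
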