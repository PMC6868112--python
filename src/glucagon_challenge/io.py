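"""File formats, configuration, and reproducibility plumbing.

All tabular I/O is CSV.  A subject record carries minutes and the
documented header

    time_min,glucose_g_per_L,insulin_mU_per_L,glucagon_pmol_per_L,
    fhgp_g_per_h_per_L,rd_g_per_h_per_L

(times are converted to hours internally).  Parameter files are flat
key-value YAML; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .cohort import CohortSpec, NoiseModel, ObservationSchedule, SubjectRecord
from .model import BaselineState, FixedKinetics, Protocol, SubjectParameters
from .profiling import EstimationResult, SmoothingConfig

RECORD_COLUMNS = [
    "time_min",
    "glucose_g_per_L",
    "insulin_mU_per_L",
    "glucagon_pmol_per_L",
    "fhgp_g_per_h_per_L",
    "rd_g_per_h_per_L",
]

_CHANNELS = ["glucose", "insulin", "glucagon", "fhgp", "rd"]

# Table-style column order for parameter tables (fitted constants + the
# observed glucose peak)
PARAM_COLUMNS = ["V_1", "V_ii", "V_h", "K_id", "k_degI", "k_degE", "k_in",
                 "K1_prime", "b_G", "V_id", "G_max"]


class FormatError(ValueError):
    """A CSV or config file does not match the documented layout."""


def record_to_frame(record: SubjectRecord) -> pd.DataFrame:
    data = dict(zip(RECORD_COLUMNS,
                    [record.times_min] + [getattr(record, ch) for ch in _CHANNELS]))
    return pd.DataFrame(data)


def write_record(record: SubjectRecord, path) -> None:
    record_to_frame(record).to_csv(path, index=False)


def read_record(path, subject_id: Optional[str] = None,
                visit: str = "before") -> SubjectRecord:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in RECORD_COLUMNS]
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {extra}")
    if subject_id is None:
        subject_id = Path(path).stem.rsplit("_", 1)[0]
    return SubjectRecord(
        subject_id=subject_id, visit=visit,
        times_min=df["time_min"].to_numpy(float),
        glucose=df["glucose_g_per_L"].to_numpy(float),
        insulin=df["insulin_mU_per_L"].to_numpy(float),
        glucagon=df["glucagon_pmol_per_L"].to_numpy(float),
        fhgp=df["fhgp_g_per_h_per_L"].to_numpy(float),
        rd=df["rd_g_per_h_per_L"].to_numpy(float),
    )


def record_filename(record: SubjectRecord) -> str:
    return f"{record.subject_id}_{record.visit}.csv"


def result_row(record: SubjectRecord, result: EstimationResult) -> dict:
    """One parameter-table row (fitted constants plus observed G_max)."""
    p = result.theta_hat
    row = {c: getattr(p, c) for c in PARAM_COLUMNS if c != "G_max"}
    row["G_max"] = float(np.max(record.glucose))
    return row


def truth_row(record: SubjectRecord) -> Optional[dict]:
    if record.true_params is None:
        return None
    p = record.true_params
    row = {c: getattr(p, c) for c in PARAM_COLUMNS if c != "G_max"}
    row["G_max"] = float(np.max(record.glucose))
    return row


def write_parameter_table(rows: dict, path) -> None:
    """``rows``: mapping subject_id -> row dict (see :func:`result_row`)."""
    df = pd.DataFrame(rows).T
    df.index.name = "subject_id"
    df[PARAM_COLUMNS].to_csv(path)


def read_parameter_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id",
                     float_precision="round_trip")
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df[PARAM_COLUMNS]


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# configuration


def _from_mapping(cls, mapping, where):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise FormatError(f"{where}: unknown key(s) {sorted(unknown)}")
    converted = {}
    for k, v in mapping.items():
        converted[k] = tuple(v) if isinstance(v, list) else v
    return cls(**converted)


@dataclasses.dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable, seed-reproducible."""

    protocol: Protocol = dataclasses.field(default_factory=Protocol)
    fixed: FixedKinetics = dataclasses.field(default_factory=FixedKinetics)
    noise: NoiseModel = dataclasses.field(default_factory=NoiseModel)
    cohort: CohortSpec = dataclasses.field(default_factory=CohortSpec)
    smoothing: SmoothingConfig = dataclasses.field(default_factory=SmoothingConfig)
    schedule: ObservationSchedule = dataclasses.field(
        default_factory=ObservationSchedule)
    seed: int = 0

    _SECTIONS = {
        "protocol": Protocol, "fixed": FixedKinetics, "noise": NoiseModel,
        "cohort": CohortSpec, "smoothing": SmoothingConfig,
        "schedule": ObservationSchedule,
    }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls._SECTIONS) - {"seed"}
        if unknown:
            raise FormatError(f"{path}: unknown section(s) {sorted(unknown)}")
        kwargs = {"seed": int(raw.get("seed", 0))}
        for name, section_cls in cls._SECTIONS.items():
            if name in raw:
                kwargs[name] = _from_mapping(section_cls, raw[name] or {},
                                             f"{path}:{name}")
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed,
            noise=dataclasses.replace(self.noise, seed=seed),
            cohort=dataclasses.replace(self.cohort, seed=seed))

    def to_dict(self) -> dict:
        out = {"seed": self.seed}
        for name in self._SECTIONS:
            d = dataclasses.asdict(getattr(self, name))
            out[name] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in d.items()}
        return out


def write_manifest(path, config: RunConfig, extra: Optional[dict] = None) -> None:
    payload = {"version": _version, "config": config.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=str) + "\n")


def subject_config_to_yaml(params: SubjectParameters,
                           baseline: Optional[BaselineState] = None) -> str:
    """Flat key-value dump of one subject's parameters (and baseline)."""
    out = dataclasses.asdict(params)
    if baseline is not None:
        out.update({f"baseline_{k}": v
                    for k, v in dataclasses.asdict(baseline).items()})
    return yaml.safe_dump(out, sort_keys=True)


def subject_config_from_yaml(text: str):
    raw = yaml.safe_load(text) or {}
    pfields = {f.name for f in dataclasses.fields(SubjectParameters)}
    bfields = {f.name for f in dataclasses.fields(BaselineState)}
    pkw, bkw, unknown = {}, {}, []
    for k, v in raw.items():
        if k in pfields:
            pkw[k] = v
        elif k.startswith("baseline_") and k[len("baseline_"):] in bfields:
            bkw[k[len("baseline_"):]] = v
        else:
            unknown.append(k)
    if unknown:
        raise FormatError(f"unknown key(s) {sorted(unknown)}")
    params = SubjectParameters(**pkw)
    baseline = BaselineState(**bkw) if bkw else None
    return params, baseline
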