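"""Cohort tables, waveforms, configs and result files.

All quantities are SI internally (Pa, m3, m3/s, s).  Millilitres and
ml/min appear only at the I/O boundary and are converted on read.
Missing cells (e.g. the unmeasured ICP of patient 11) are carried as
NaN, never as zero.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ML_PER_M3 = 1e6
#: 1 ml/min in m3/s
ML_MIN_TO_M3_S = 1e-6 / 60.0

GROUPS = ("healthy", "patient")
SCHEMES = ("A", "B", "C")

_FIXTURE_FILES = {"healthy": "table2_healthy.csv", "patient": "table3_patients.csv"}

#: Summary-statistic column names shared by the fixtures and CohortTable.
SUMMARY_CELLS = ("mean", "sd", "se", "cv_percent", "ci_lower", "ci_upper")


class FixtureError(RuntimeError):
    """A bundled fixture is missing or fails validation."""


@dataclass
class CohortTable:
    """Rectangular per-subject measurements for one study group.

    ``variables`` maps a variable name to a float vector of length
    ``len(subject_ids)``; NaN marks a missing cell.  ``printed`` holds
    the source's own summary cells (mean/sd/se/cv/CI) when the table
    was loaded from a fixture, for regression checks; ``misprints``
    lists ``(variable, cell)`` pairs known to be typeset wrongly in the
    source.
    """

    group: str
    subject_ids: list[str]
    variables: dict[str, np.ndarray]
    units: dict[str, str]
    printed: dict[str, dict[str, float]] = field(default_factory=dict)
    misprints: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        n = len(self.subject_ids)
        for name, vec in self.variables.items():
            vec = np.asarray(vec, dtype=float)
            self.variables[name] = vec
            if vec.shape != (n,):
                raise ValueError(
                    f"variable {name!r} has length {vec.shape}, expected ({n},)"
                )
            if name not in self.units:
                raise ValueError(f"variable {name!r} has no declared unit")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def values(self, variable: str, drop_missing: bool = False) -> np.ndarray:
        try:
            v = self.variables[variable]
        except KeyError:
            raise KeyError(
                f"table for group {self.group!r} has no variable {variable!r}; "
                f"available: {sorted(self.variables)}"
            ) from None
        return v[~np.isnan(v)] if drop_missing else v


@dataclass
class MeshConvergenceTable:
    """Grid-refinement values (coarse/medium/fine) per patient plus
    fine-mesh element counts."""

    subject_ids: list[str]
    #: (quantity, grid) -> per-patient vector
    values: dict[tuple[str, str], np.ndarray]
    units: dict[str, str]

    GRIDS = ("coarse", "medium", "fine")

    def __post_init__(self):
        quantities = {q for q, _ in self.values if not q.startswith("fine_mesh")}
        for q in quantities:
            for g in self.GRIDS:
                if (q, g) not in self.values:
                    raise FixtureError(f"mesh table lacks grid {g!r} for {q!r}")
        for vec in self.values.values():
            if not np.all(np.asarray(vec) > 0):
                raise FixtureError("mesh table values must be positive")


@dataclass
class Waveform:
    """One period of a sampled periodic signal.

    Sample times cover [0, period): strictly increasing, starting at 0,
    last sample < period.  Units are declared, not inferred.
    """

    period: float
    times: np.ndarray
    values: np.ndarray
    units: str

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1-d arrays")
        if self.times.size < 2:
            raise ValueError("waveform needs at least two samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"times must be strictly increasing (row {row})")
        if self.times[0] != 0.0:
            raise ValueError("first sample time must be 0")
        if self.times[-1] >= self.period:
            raise ValueError("last sample time must be < period")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite")

    def __call__(self, t) -> np.ndarray:
        """Periodic linear interpolation at arbitrary times."""
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        tp = np.concatenate([self.times, [self.period]])
        vp = np.concatenate([self.values, [self.values[0]]])
        return np.interp(tt, tp, vp)

    def closed_cycle(self) -> tuple[np.ndarray, np.ndarray]:
        """Samples with the first point appended at t = period, so that
        trapezoidal quadrature covers the full cycle."""
        return (
            np.concatenate([self.times, [self.period]]),
            np.concatenate([self.values, [self.values[0]]]),
        )

    def cycle_mean(self) -> float:
        t, v = self.closed_cycle()
        return float(np.trapezoid(v, t) / self.period)


# ---------------------------------------------------------------------------
# Fixture loading
# ---------------------------------------------------------------------------

def _fixture_text(name: str) -> str:
    ref = resources.files("csfbc.data").joinpath(name)
    try:
        return ref.read_text(encoding="utf-8")
    except (FileNotFoundError, OSError) as exc:
        raise FixtureError(f"bundled fixture {name!r} is missing or unreadable") from exc


def load_cohort_fixture(which: str) -> CohortTable:
    """Load the bundled per-subject table for one group, cell-exact.

    Values are returned exactly as printed in the source tables;
    volumes keep their ml units (see ``variables`` keys), pressures Pa.
    """
    if which not in _FIXTURE_FILES:
        raise ValueError(f"which must be one of {GROUPS}, got {which!r}")
    name = _FIXTURE_FILES[which]
    df = pd.read_csv(io.StringIO(_fixture_text(name)), comment="#", dtype=str)
    expected_lead = ["variable", "unit"]
    if list(df.columns[:2]) != expected_lead or "mean" not in df.columns:
        raise FixtureError(f"fixture {name!r} is corrupt: unexpected columns")
    subject_cols = [c for c in df.columns if c.startswith("No.")]
    variables, units, printed = {}, {}, {}
    misprints: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        var = row["variable"]
        units[var] = row["unit"]
        vals = [
            math.nan if str(x).strip() in ("NA", "nan", "") else float(x)
            for x in row[subject_cols]
        ]
        variables[var] = np.array(vals)
        printed[var] = {c: float(row[c]) for c in SUMMARY_CELLS}
        flags = str(row.get("flags", "") or "")
        if "ci_misprint" in flags:
            misprints.update({(var, "ci_lower"), (var, "ci_upper")})
    table = CohortTable(
        group=which,
        subject_ids=subject_cols,
        variables=variables,
        units=units,
        printed=printed,
        misprints=misprints,
    )
    _validate_fixture(table)
    return table


def _validate_fixture(table: CohortTable) -> None:
    expected_n = {"healthy": 8, "patient": 11}[table.group]
    if table.n_subjects != expected_n:
        raise FixtureError(
            f"{table.group} fixture has {table.n_subjects} subjects, expected {expected_n}"
        )
    if table.group == "patient":
        icp = table.values("experimental_ICP_SAS_Pa")
        if int(np.sum(~np.isnan(icp))) != 10:
            raise FixtureError("patient fixture must have ICP for exactly 10 patients")


def load_mesh_convergence_fixture() -> MeshConvergenceTable:
    df = pd.read_csv(io.StringIO(_fixture_text("table4_mesh.csv")), comment="#")
    subject_cols = [c for c in df.columns if c.startswith("No.")]
    values, units = {}, {}
    for _, row in df.iterrows():
        q, g = row["quantity"], row["grid"]
        units[q] = row["unit"]
        values[(q, g)] = row[subject_cols].to_numpy(dtype=float)
    return MeshConvergenceTable(subject_ids=subject_cols, values=values, units=units)


# ---------------------------------------------------------------------------
# Waveform I/O
# ---------------------------------------------------------------------------

def write_waveform(waveform: Waveform, path) -> None:
    """CSV with header comments declaring units and period."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"# units: {waveform.units}\n")
        fh.write(f"# period_s: {waveform.period!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value"])
        for t, v in zip(waveform.times, waveform.values):
            writer.writerow([repr(float(t)), repr(float(v))])


def read_waveform(path) -> Waveform:
    """Read a waveform CSV; ml/min values are converted to m3/s."""
    path = Path(path)
    units, period = None, None
    rows = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                if key.strip() == "units":
                    units = val.strip()
                elif key.strip() == "period_s":
                    period = float(val)
                continue
            rows.append((lineno, line))
    if units is None or period is None:
        raise ValueError(f"{path}: missing '# units:' or '# period_s:' header")
    header, data = rows[0], rows[1:]
    if header[1].split(",")[0] != "time_s":
        raise ValueError(f"{path}: expected header 'time_s,value'")
    times, values = [], []
    prev_t = -math.inf
    for lineno, line in data:
        t_s, v_s = line.split(",")
        t = float(t_s)
        if t <= prev_t:
            raise ValueError(f"{path}: non-monotone time column at row {lineno}")
        prev_t = t
        times.append(t)
        values.append(float(v_s))
    values = np.array(values)
    if units == "ml/min":
        values = values * ML_MIN_TO_M3_S
        units = "m3/s"
    return Waveform(period=period, times=np.array(times), values=values, units=units)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA = {
    "subject": {
        "group": "healthy",
        "ventricular_volume_ml": None,  # default filled by group below
        "aqueduct_radius_m": None,
        "aqueduct_length_m": 0.015,
        "baseline_pressure_Pa": None,  # defaults to outlet pressure of group
    },
    "material": {
        "E_Pa": 584.4,
        "nu": 0.35,
        "prony_g": [0.285, 0.285, 0.285],
        "prony_tau_s": [3.1, 27.0, 410.0],
        "void_ratio": 0.2,
        "permeability": 4.08e-12,
    },
    "bc": {
        "scheme": None,  # required
        "mean_inflow_ml_min": 0.35,
        "pulsatile_amplitude_ml_min": 7.5,  # healthy-scale oscillation; generator overrides per subject
        "outlet_split_ml_min": [0.18, 0.17],
        "period_s": 1.0,
        "waveform_csv": None,  # normalized shape; default: canonical 3-harmonic shape
    },
    "solver": {
        "dt_s": 0.01,
        "n_cycles": 5,
        "mode": "FSI",
        "sas_compliance_m3_Pa": 1e-9,
        "outlet_resistance_Pa_s_m3": 8e9,
        "production_resistance_Pa_s_m3": 1e9,
        "darcy_leak": False,
        "darcy_leak_length_m": 0.05,
        "darcy_leak_area_m2": 1e-3,
    },
}

_GROUP_DEFAULTS = {
    "healthy": {"ventricular_volume_ml": 20.3, "aqueduct_radius_m": 1.0e-3},
    "patient": {"ventricular_volume_ml": 281.6, "aqueduct_radius_m": 1.5e-3},
}

_REQUIRED = {("bc", "scheme")}


@dataclass
class RunConfig:
    subject: dict
    material: dict
    bc: dict
    solver: dict

    def as_dict(self) -> dict:
        return {
            "subject": dict(self.subject),
            "material": dict(self.material),
            "bc": dict(self.bc),
            "solver": dict(self.solver),
        }


def parse_config(raw: dict) -> RunConfig:
    """Validate a raw section->key mapping, fill defaults, reject unknowns."""
    raw = raw or {}
    unknown_sections = set(raw) - set(_CONFIG_SCHEMA)
    if unknown_sections:
        raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
    filled = {}
    for section, defaults in _CONFIG_SCHEMA.items():
        given = raw.get(section) or {}
        unknown = set(given) - set(defaults)
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
        filled[section] = {**defaults, **given}
    for section, key in _REQUIRED:
        if filled[section][key] is None:
            raise ValueError(f"missing required config key: {section}.{key}")
    scheme = filled["bc"]["scheme"]
    if scheme not in SCHEMES:
        raise ValueError(f"bc.scheme must be one of {set(SCHEMES)}, got {scheme!r}")
    group = filled["subject"]["group"]
    if group not in GROUPS:
        raise ValueError(f"subject.group must be one of {GROUPS}, got {group!r}")
    for key, default in _GROUP_DEFAULTS[group].items():
        if filled["subject"][key] is None:
            filled["subject"][key] = default
    return RunConfig(**filled)


def load_config(path) -> RunConfig:
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw)


# ---------------------------------------------------------------------------
# Result / table export
# ---------------------------------------------------------------------------

def write_result_json(result, path) -> None:
    """Serialize a solver SimulationResult to JSON (full precision)."""
    payload = result.to_dict()
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def read_result_json(path):
    from .solver import SimulationResult

    with Path(path).open("r", encoding="utf-8") as fh:
        return SimulationResult.from_dict(json.load(fh))


def write_cohort_table(table: CohortTable, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"# group: {table.group}\n")
        writer = csv.writer(fh)
        writer.writerow(["variable", "unit", *table.subject_ids])
        for var, vec in table.variables.items():
            cells = ["NA" if math.isnan(v) else repr(float(v)) for v in vec]
            writer.writerow([var, table.units[var], *cells])


def read_cohort_table(path) -> CohortTable:
    path = Path(path)
    group = None
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# group:"):
            group = first.partition(":")[2].strip()
        df = pd.read_csv(fh, dtype=str)
    if group is None:
        raise ValueError(f"{path}: missing '# group:' header")
    subject_cols = list(df.columns[2:])
    variables, units = {}, {}
    for _, row in df.iterrows():
        var = row["variable"]
        units[var] = row["unit"]
        variables[var] = np.array(
            [math.nan if str(x) == "NA" else float(x) for x in row[subject_cols]]
        )
    return CohortTable(group=group, subject_ids=subject_cols, variables=variables, units=units)
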