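"""Cohort tables: CSV I/O, multi-modality consensus and cohort simulation.

The native table dialect is flat: one header row with ``patient_id``,
``t_category`` and one ``<modality>_<level>`` column per reported
modality/level pair, values 0 (healthy), 1 (metastatic) or empty (unknown).
T-categories T0-T2 map to "early" and T3-T4 to "late" at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import ModelParams, SpreadGraph
from .likelihood import (
    MODALITIES,
    PERFECT_MODALITY,
    DataError,
    Modality,
    T_CATEGORIES,
)

_T_CATEGORY_MAP = {
    "T0": "early", "T1": "early", "T2": "early",
    "T3": "late", "T4": "late",
    "early": "early", "late": "late", "advanced": "late",
}


@dataclass
class PatientRecord:
    """One patient: T-category plus per-modality ternary level statuses."""

    patient_id: str
    t_category: str
    observations: dict[str, dict[str, int | None]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def status(self, modality_name: str) -> dict[str, int | None]:
        """Ternary involvement for one modality; absent modality reports nothing."""
        return self.observations.get(modality_name, {})


@dataclass
class Cohort:
    """A homogeneous list of patient records over one set of levels."""

    records: list[PatientRecord]
    lnl_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def modalities(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            for m in rec.observations:
                seen.setdefault(m)
        return tuple(seen)

    def counts(
        self, modality_name: str, pattern: Mapping[str, int | None]
    ) -> tuple[int, int]:
        """(matching, total) records whose statuses agree with ``pattern``
        on every level the pattern pins to 0 or 1, counting only records
        that report all pinned levels."""
        match = total = 0
        pinned = {k: v for k, v in pattern.items() if v is not None}
        for rec in self.records:
            st = rec.status(modality_name)
            if any(st.get(lvl) is None for lvl in pinned):
                continue
            total += 1
            if all(st[lvl] == v for lvl, v in pinned.items()):
                match += 1
        return match, total


def _normalize_t_category(raw: str, row: int) -> str:
    key = str(raw).strip()
    if key not in _T_CATEGORY_MAP:
        raise DataError(f"row {row}: unrecognized t_category {raw!r}")
    return _T_CATEGORY_MAP[key]


def _parse_status(raw, row: int, col: str) -> int | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "" or text.lower() in ("nan", "none", "unknown"):
        return None
    if text in ("0", "0.0", "False", "false"):
        return 0
    if text in ("1", "1.0", "True", "true"):
        return 1
    raise DataError(f"row {row}, column {col}: unparseable status {raw!r}")


def read_cohort(path: str | Path, lnl_names: Sequence[str] | None = None) -> Cohort:
    """Read a flat-dialect cohort CSV.

    Level order is taken from first appearance in the header unless
    ``lnl_names`` pins it explicitly.
    """
    df = pd.read_csv(path, dtype=str)
    if "t_category" not in df.columns:
        raise DataError(f"{path}: missing required column 't_category'")
    status_cols: list[tuple[str, str, str]] = []  # (column, modality, level)
    seen_levels: dict[str, None] = {}
    for col in df.columns:
        if col in ("patient_id", "t_category"):
            continue
        if "_" not in col:
            raise DataError(f"{path}: column {col!r} is not <modality>_<level>")
        modality, level = col.rsplit("_", 1)
        status_cols.append((col, modality, level))
        seen_levels.setdefault(level)
    levels = tuple(lnl_names) if lnl_names is not None else tuple(seen_levels)
    records = []
    for i, row in df.iterrows():
        pid = str(row["patient_id"]) if "patient_id" in df.columns else str(i)
        tcat = _normalize_t_category(row["t_category"], i)
        obs: dict[str, dict[str, int | None]] = {}
        for col, modality, level in status_cols:
            obs.setdefault(modality, {})[level] = _parse_status(row[col], i, col)
        records.append(PatientRecord(pid, tcat, obs))
    return Cohort(records, levels, metadata={"source": str(path)})


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Inverse of :func:`read_cohort`; unknowns serialize as empty cells."""
    modalities = cohort.modalities
    columns = ["patient_id", "t_category"] + [
        f"{m}_{lvl}" for m in modalities for lvl in cohort.lnl_names
    ]
    rows = []
    for rec in cohort.records:
        row: dict[str, object] = {
            "patient_id": rec.patient_id,
            "t_category": rec.t_category,
        }
        for m in modalities:
            st = rec.status(m)
            for lvl in cohort.lnl_names:
                v = st.get(lvl)
                row[f"{m}_{lvl}"] = "" if v is None else int(v)
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def resolve_consensus(
    record: PatientRecord,
    lnl_names: Sequence[str],
    modality_registry: Mapping[str, Modality] = MODALITIES,
) -> dict[str, int | None]:
    """Most-likely true involvement per level from conflicting modalities.

    Pathology, when reported, is taken as ground truth for that level.
    Otherwise the state maximizing the product over reporting modalities of
    ``P(report | state)`` wins, with exact ties resolved to involved
    (the clinically conservative call).  Levels nobody reports stay unknown.
    """
    consensus: dict[str, int | None] = {}
    for level in lnl_names:
        reports: list[tuple[Modality, int]] = []
        for mod_name, statuses in record.observations.items():
            if mod_name == "consensus":
                continue
            status = statuses.get(level)
            if status is None:
                continue
            if mod_name not in modality_registry:
                raise DataError(f"modality {mod_name!r} not in registry")
            reports.append((modality_registry[mod_name], status))
        if not reports:
            consensus[level] = None
            continue
        path_reports = [s for m, s in reports if m.name == "pathology"]
        if path_reports:
            consensus[level] = path_reports[0]
            continue
        lik_involved = lik_healthy = 1.0
        for mod, s in reports:
            lik_involved *= mod.sensitivity if s == 1 else 1.0 - mod.sensitivity
            lik_healthy *= 1.0 - mod.specificity if s == 1 else mod.specificity
        consensus[level] = 1 if lik_involved >= lik_healthy else 0
    return consensus


def add_consensus(
    cohort: Cohort, modality_registry: Mapping[str, Modality] = MODALITIES
) -> Cohort:
    """Return a cohort with a "consensus" modality resolved for every record."""
    records = []
    for rec in cohort.records:
        obs = dict(rec.observations)
        obs["consensus"] = resolve_consensus(rec, cohort.lnl_names, modality_registry)
        records.append(
            PatientRecord(rec.patient_id, rec.t_category, obs, dict(rec.metadata))
        )
    return Cohort(records, cohort.lnl_names, dict(cohort.metadata))


def simulate_cohort(
    graph: SpreadGraph,
    params: ModelParams,
    n: int,
    fraction_late: float = 0.5,
    modality: Modality = PERFECT_MODALITY,
    seed: int | np.random.Generator = 0,
) -> Cohort:
    """Sample a synthetic cohort from the generative model.

    Per patient: draw the T-category, draw the diagnose time from the
    matching binomial prior, evolve the hidden state from all-healthy with
    per-level seeding probabilities, then corrupt the final state through
    the modality's sensitivity/specificity.  The generating hidden state and
    diagnose time are kept in record metadata for diagnostics only.
    """
    if n < 1:
        raise DataError("need n >= 1 simulated patients")
    if not 0.0 <= fraction_late <= 1.0:
        raise DataError("fraction_late must be in [0, 1]")
    params.validate(graph)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = graph.lnl_names
    V = len(names)
    b = np.array([params.b[v] for v in names])
    arcs = [(names.index(p), names.index(c), params.t[(p, c)]) for p, c in graph.lnl_arcs]

    late = rng.random(n) < fraction_late
    p_diag = np.where(late, params.p_late, params.p_early)
    t_d = rng.binomial(params.t_max, p_diag)

    X = np.zeros((n, V), dtype=np.int8)
    for step in range(params.t_max):
        active = t_d > step
        if not np.any(active):
            break
        stay = np.broadcast_to(1.0 - b, (n, V)).copy()
        for r, c, t in arcs:
            stay[:, c] *= np.where(X[:, r] == 1, 1.0 - t, 1.0)
        seeded = (X == 0) & (rng.random((n, V)) < 1.0 - stay) & active[:, None]
        X[seeded] = 1

    if modality.is_perfect:
        Z = X.copy()
    else:
        hit = rng.random((n, V))
        Z = np.where(X == 1, hit < modality.sensitivity, hit < 1.0 - modality.specificity)
        Z = Z.astype(np.int8)

    records = []
    for i in range(n):
        obs = {modality.name: {names[v]: int(Z[i, v]) for v in range(V)}}
        records.append(
            PatientRecord(
                patient_id=f"sim{i:06d}",
                t_category="late" if late[i] else "early",
                observations=obs,
                metadata={
                    "t_d": int(t_d[i]),
                    "hidden": tuple(int(x) for x in X[i]),
                },
            )
        )
    return Cohort(
        records,
        names,
        metadata={"source": "simulated", "seed": repr(seed), "n": n},
    )


def convert_lydata(path: str | Path, lnl_names: Sequence[str] | None = None) -> Cohort:
    """Convert a three-row-header interinstitutional cohort table.

    Expects a CSV whose header spans three rows: top = modality (or a
    ``tumor`` info block holding ``t_stage``), middle = side (``ipsi`` rows
    are used), bottom = level label.  Returns a flat-dialect cohort.
    """
    df = pd.read_csv(path, header=[0, 1, 2])
    tstage_cols = [c for c in df.columns if c[2] == "t_stage"]
    if not tstage_cols:
        raise DataError(f"{path}: no t_stage column found in three-row header")
    tstage = df[tstage_cols[0]]
    seen_levels: dict[str, None] = {}
    status_cols = []
    for col in df.columns:
        top, mid, bottom = col
        if mid == "ipsi" and top in MODALITIES:
            status_cols.append((col, top, bottom))
            seen_levels.setdefault(bottom)
    levels = tuple(lnl_names) if lnl_names is not None else tuple(seen_levels)
    records = []
    for i in range(len(df)):
        stage = int(float(tstage.iloc[i]))
        tcat = _normalize_t_category(f"T{stage}", i)
        obs: dict[str, dict[str, int | None]] = {}
        for col, modality, level in status_cols:
            obs.setdefault(modality, {})[level] = _parse_status(
                df[col].iloc[i], i, "/".join(col)
            )
        records.append(PatientRecord(str(i), tcat, obs))
    return Cohort(records, levels, metadata={"source": str(path)})
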