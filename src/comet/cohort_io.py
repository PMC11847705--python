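"""Reading coded-EHR event tables and omics matrices into analysis cohorts.

The input layout mirrors a minimal OMOP extract: one long table of coded
events (patient, concept code, day, source table), a per-patient anchor
table (delivery and/or diagnosis day), a per-sample table linking omics
samples to patients and sampling days, and an omics matrix. Dates are
integer day offsets from an arbitrary epoch (ISO dates are converted to
proleptic ordinals on load); all observation windows are closed intervals
on whole days.

Two windowing rules are supported. The pregnancy rule starts every window
280 days before delivery; omics-cohort windows end at the sampling day while
pretraining-cohort windows end at a random day drawn uniformly from the 100
days up to delivery (emulating the sampling design of the omics study). The
cancer rule keeps all history up to the sampling day (omics cohort) or the
diagnosis day (pretraining cohort).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCE_TABLES = frozenset({
    "measurement", "observation", "drug_exposure",
    "condition_occurrence", "procedure_occurrence",
})

PREGNANCY_LOOKBACK = 280   # days of pregnancy before delivery
PRETRAIN_SAMPLE_SPAN = 100  # random cut drawn within this many days of delivery


class FormatError(ValueError):
    """Malformed input table (missing column, unparseable date)."""


class LinkageError(ValueError):
    """Omics sample that cannot be joined to a patient."""


@dataclass
class EHREvent:
    patient_id: str
    concept_id: str
    event_date: int
    source_table: str


@dataclass
class AnchorDates:
    delivery_date: int | None = None
    diagnosis_date: int | None = None
    sampling_date: int | None = None


@dataclass
class PatientRecord:
    """One analysis unit: a patient's windowed day-grouped codes, plus an
    omics vector and outcome for omics-cohort records.

    A patient with several omics samples yields several records sharing
    ``patient_id`` (distinguished by ``record_id``); grouped splits keep
    them together.
    """

    patient_id: str
    windowed_events: list[tuple[int, list[str]]]
    outcome: float
    cohort: str  # "pretraining" | "omics"
    record_id: str = ""
    omics_vector: np.ndarray | None = None
    window: tuple[float, float] = (-math.inf, math.inf)

    def __post_init__(self):
        if not self.record_id:
            self.record_id = self.patient_id
        if (self.cohort == "omics") != (self.omics_vector is not None):
            raise ValueError("omics_vector present iff cohort == 'omics'")


@dataclass
class CohortBundle:
    pretraining: list[PatientRecord]
    omics: list[PatientRecord]
    analyte_names: list[str]
    manifest: dict = field(default_factory=dict)

    @property
    def records(self) -> list[PatientRecord]:
        return self.pretraining + self.omics


def _to_day(value, line_no: int | None = None) -> int:
    """Integer day offset from an int-like or ISO-date string."""
    try:
        return int(value)
    except (TypeError, ValueError):
        pass
    try:
        return date.fromisoformat(str(value)).toordinal()
    except ValueError:
        where = f" at line {line_no}" if line_no is not None else ""
        raise FormatError(f"unparseable date {value!r}{where}") from None


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def load_events(path) -> pd.DataFrame:
    """Load an event table, dropping concept_id 0 and unknown source tables.

    Returns a DataFrame with columns ``patient_id``, ``concept_id``,
    ``event_date`` (int day) and ``source_table`` — the collection of
    validated events.
    """
    df = _read_table(path)
    required = ["patient_id", "concept_id", "date", "source_table"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"events table is missing column {col!r}")
    if len(df) == 0:
        return pd.DataFrame(
            columns=["patient_id", "concept_id", "event_date", "source_table"])
    days = [_to_day(v, line_no=i + 2) for i, v in enumerate(df["date"])]
    df = df.assign(event_date=days)
    null_concept = df["concept_id"].astype(str).str.strip() == "0"
    df = df[~null_concept]
    bad_table = ~df["source_table"].isin(SOURCE_TABLES)
    if bad_table.any():
        logger.warning("dropping %d events from non-clinical source tables: %s",
                       int(bad_table.sum()),
                       sorted(df.loc[bad_table, "source_table"].unique()))
        df = df[~bad_table]
    return df[["patient_id", "concept_id", "event_date", "source_table"]].reset_index(drop=True)


def pregnancy_window(anchors: AnchorDates, cohort: str,
                     rng: np.random.Generator) -> tuple[int, int]:
    """Observation window for the days-to-labour-onset task."""
    if anchors.delivery_date is None:
        raise ValueError("pregnancy window requires a delivery_date")
    start = anchors.delivery_date - PREGNANCY_LOOKBACK
    if cohort == "omics":
        if anchors.sampling_date is None:
            raise ValueError("omics-cohort patients need a sampling_date")
        if anchors.sampling_date < start:
            raise ValueError(
                "sampling_date precedes the start of pregnancy; invalid cohort")
        end = anchors.sampling_date
    else:
        end = int(rng.integers(anchors.delivery_date - PRETRAIN_SAMPLE_SPAN,
                               anchors.delivery_date + 1))
    return start, end


def cancer_window(anchors: AnchorDates, cohort: str) -> tuple[float, int]:
    """Observation window for the 3-year-mortality task: all history up to
    sampling (omics) or first diagnosis (pretraining)."""
    if cohort == "omics":
        if anchors.sampling_date is None:
            raise ValueError("omics-cohort patients need a sampling_date")
        return (-math.inf, anchors.sampling_date)
    if anchors.diagnosis_date is None:
        raise ValueError("pretraining-cohort patients need a diagnosis_date")
    return (-math.inf, anchors.diagnosis_date)


def _window_events(patient_events: pd.DataFrame,
                   window: tuple[float, float]) -> list[tuple[int, list[str]]]:
    lo, hi = window
    sel = patient_events[(patient_events["event_date"] >= lo)
                         & (patient_events["event_date"] <= hi)]
    out: list[tuple[int, list[str]]] = []
    for day, grp in sel.groupby("event_date", sort=True):
        out.append((int(day), list(grp["concept_id"])))
    return out


def assemble_cohort(events: pd.DataFrame,
                    anchors: dict[str, AnchorDates],
                    omics_table: pd.DataFrame | None,
                    samples: pd.DataFrame | None,
                    outcomes: dict[str, float] | None,
                    task: str,
                    rng: np.random.Generator | None = None) -> CohortBundle:
    """Partition patients into pretraining and omics cohorts and window them.

    Parameters
    ----------
    events
        Output of :func:`load_events`.
    anchors
        Per-patient anchor days.
    omics_table
        Samples x analytes matrix; first column ``sample_id``.
    samples
        Table with ``sample_id``, ``patient_id``, ``sampling_date`` linking
        omics samples to patients.
    outcomes
        Per-patient labels; required for ``task='cancer'`` (binary 3-year
        mortality). For ``task='pregnancy'`` the label is computed as days
        from the window end to delivery.
    """
    if task not in {"pregnancy", "cancer"}:
        raise ValueError(f"unknown task {task!r}")
    if task == "pregnancy" and rng is None:
        raise ValueError("pregnancy task needs an rng for pretraining cutoffs")

    by_patient = {pid: grp for pid, grp in events.groupby("patient_id")}
    empty = events.iloc[0:0]

    sample_rows: list[tuple[str, str, int]] = []
    analyte_names: list[str] = []
    omics_by_sample: dict[str, np.ndarray] = {}
    if omics_table is not None:
        if samples is None:
            raise LinkageError("an omics table requires a samples link table")
        analyte_names = [c for c in omics_table.columns if c != "sample_id"]
        mat = omics_table.set_index("sample_id")[analyte_names].astype(float)
        link = samples.set_index("sample_id")
        unmatched = [sid for sid in mat.index
                     if sid not in link.index
                     or str(link.loc[sid, "patient_id"]) not in anchors]
        if unmatched:
            raise LinkageError(
                f"omics samples with no matching patient: {sorted(unmatched)}")
        for sid in mat.index:
            pid = str(link.loc[sid, "patient_id"])
            sday = _to_day(link.loc[sid, "sampling_date"])
            sample_rows.append((str(sid), pid, sday))
            omics_by_sample[str(sid)] = mat.loc[sid].to_numpy()

    omics_patients = {pid for _, pid, _ in sample_rows}
    pretraining: list[PatientRecord] = []
    omics: list[PatientRecord] = []

    def make_record(pid: str, anchor: AnchorDates, cohort: str,
                    record_id: str, omics_vec: np.ndarray | None) -> PatientRecord:
        if task == "pregnancy":
            window = pregnancy_window(anchor, cohort, rng)
            outcome = float(anchor.delivery_date - window[1])
        else:
            window = cancer_window(anchor, cohort)
            if outcomes is None or pid not in outcomes:
                raise ValueError(f"cancer task needs an outcome label for {pid}")
            outcome = float(outcomes[pid])
        wev = _window_events(by_patient.get(pid, empty), window)
        if not wev:
            logger.warning("patient %s has no events inside the window; "
                           "record kept with empty sequence", record_id)
        return PatientRecord(patient_id=pid, windowed_events=wev,
                             outcome=outcome, cohort=cohort,
                             record_id=record_id, omics_vector=omics_vec,
                             window=window)

    for pid, anchor in anchors.items():
        if pid in omics_patients:
            continue
        pretraining.append(make_record(pid, anchor, "pretraining", pid, None))

    for sid, pid, sday in sample_rows:
        anchor = anchors[pid]
        a = AnchorDates(delivery_date=anchor.delivery_date,
                        diagnosis_date=anchor.diagnosis_date,
                        sampling_date=sday)
        omics.append(make_record(pid, a, "omics", sid, omics_by_sample[sid]))

    manifest = {
        "task": task,
        "n_pretraining": len(pretraining),
        "n_omics_records": len(omics),
        "n_omics_patients": len(omics_patients),
        "n_analytes": len(analyte_names),
    }
    return CohortBundle(pretraining=pretraining, omics=omics,
                        analyte_names=analyte_names, manifest=manifest)


# ---------------------------------------------------------------------------
# Bundle serialization: one events/records table pair per cohort plus a JSON
# manifest, all plain text.

def save_bundle(bundle: CohortBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cohort, records in (("pretraining", bundle.pretraining),
                            ("omics", bundle.omics)):
        ev_rows, rec_rows, om_rows = [], [], []
        for r in records:
            rec_rows.append({
                "record_id": r.record_id, "patient_id": r.patient_id,
                "outcome": r.outcome,
                "window_start": r.window[0], "window_end": r.window[1],
            })
            for day, codes in r.windowed_events:
                for code in codes:
                    ev_rows.append({"record_id": r.record_id,
                                    "day_index": day, "concept_id": code})
            if r.omics_vector is not None:
                om_rows.append([r.record_id] + list(r.omics_vector))
        pd.DataFrame(rec_rows).to_csv(outdir / f"{cohort}_records.tsv",
                                      sep="\t", index=False)
        pd.DataFrame(ev_rows).to_csv(outdir / f"{cohort}_events.tsv",
                                     sep="\t", index=False)
        if om_rows:
            pd.DataFrame(om_rows,
                         columns=["record_id"] + bundle.analyte_names
                         ).to_csv(outdir / "omics_matrix.tsv",
                                  sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))


def load_bundle(indir) -> CohortBundle:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    omics_path = indir / "omics_matrix.tsv"
    analyte_names: list[str] = []
    omics_map: dict[str, np.ndarray] = {}
    if omics_path.exists():
        om = pd.read_csv(omics_path, sep="\t", dtype={"record_id": str})
        analyte_names = [c for c in om.columns if c != "record_id"]
        for _, row in om.iterrows():
            omics_map[str(row["record_id"])] = row[analyte_names].to_numpy(float)

    out: dict[str, list[PatientRecord]] = {}
    for cohort in ("pretraining", "omics"):
        recs = pd.read_csv(indir / f"{cohort}_records.tsv", sep="\t",
                           dtype={"record_id": str, "patient_id": str})
        evs = pd.read_csv(indir / f"{cohort}_events.tsv", sep="\t",
                          dtype={"record_id": str, "concept_id": str})
        ev_by_rec = {rid: grp for rid, grp in evs.groupby("record_id")}
        records = []
        for _, row in recs.iterrows():
            rid = str(row["record_id"])
            wev: list[tuple[int, list[str]]] = []
            if rid in ev_by_rec:
                for day, grp in ev_by_rec[rid].groupby("day_index", sort=True):
                    wev.append((int(day), list(grp["concept_id"])))
            records.append(PatientRecord(
                patient_id=str(row["patient_id"]), windowed_events=wev,
                outcome=float(row["outcome"]), cohort=cohort, record_id=rid,
                omics_vector=omics_map.get(rid),
                window=(float(row["window_start"]), float(row["window_end"]))))
        out[cohort] = records
    return CohortBundle(pretraining=out["pretraining"], omics=out["omics"],
                        analyte_names=analyte_names, manifest=manifest)
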