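"""Text-format interchange: BIDS-style events tables, design-matrix CSVs
with JSON sidecars, and MVPA beta-map manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (RATING_ORDERS, TRIAL_SPAN, RunSchedule, SubjectDesign,
                     TrialEvent, condition_name)
from .glm import DesignMatrix
from .images import VoxelMap, load_map
from .ratings import RatingRecord

EVENT_COLUMNS = ["onset", "duration", "trial_type", "run", "trial",
                 "emotion", "intention", "value", "intention_percent",
                 "value_amount", "rating", "rating_order"]


def events_frame(design: SubjectDesign,
                 records: list[RatingRecord] | None = None) -> pd.DataFrame:
    """Long events table: one row per rating-screen event of each
    condition trial plus one row per null trial."""
    from .ratings import rating_lookup
    lookup = rating_lookup(records) if records else {}
    rows = []
    for run in design.runs:
        for t in run.trials:
            if t.is_null:
                rows.append({
                    "onset": t.onset, "duration": t.span, "trial_type": "null",
                    "run": run.run_index, "trial": t.trial_index,
                    "emotion": np.nan, "intention": np.nan, "value": np.nan,
                    "intention_percent": 0, "value_amount": 0,
                    "rating": np.nan, "rating_order": run.rating_order})
                continue
            rec = lookup.get((design.subject_id, run.run_index, t.trial_index))
            for emotion in ("gratitude", "joy"):
                rating = getattr(rec, emotion) if rec else None
                rows.append({
                    "onset": t.rating_onset(emotion),
                    "duration": t.rating_duration(emotion),
                    "trial_type": condition_name(
                        emotion, t.intention_level, t.value_level),
                    "run": run.run_index, "trial": t.trial_index,
                    "emotion": emotion, "intention": t.intention_level,
                    "value": t.value_level,
                    "intention_percent": t.intention_percent,
                    "value_amount": t.value_amount,
                    "rating": np.nan if rating is None else float(rating),
                    "rating_order": run.rating_order})
    return pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values(
        ["run", "onset"]).reset_index(drop=True)


def write_events(design: SubjectDesign, path,
                 records: list[RatingRecord] | None = None) -> None:
    events_frame(design, records).to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def design_from_events(events: pd.DataFrame, subject_id: int = 0,
                       tr: float = 2.3, n_volumes: int = 145,
                       order_scheme: str = "A-B-B-A-A-B"
                       ) -> tuple[SubjectDesign, list[RatingRecord]]:
    """Reconstruct a subject design (and any recorded ratings) from an
    events table written by :func:`write_events`.

    Null trials round-trip with an arbitrary admissible 6 s / 6 s rating
    split, which downstream models never consume.
    """
    runs = []
    records = []
    for run_idx, run_ev in events.groupby("run"):
        order = run_ev["rating_order"].iloc[0]
        if order not in RATING_ORDERS:
            raise ValueError(f"unknown rating order {order!r}")
        trials = []
        for trial_idx, tev in run_ev.groupby("trial"):
            # null trials carry no emotion (note read_csv parses the
            # literal string "null" as NaN, so test the emotion column)
            if tev["emotion"].isna().all():
                trials.append(TrialEvent(
                    run_index=int(run_idx), trial_index=int(trial_idx),
                    onset=float(tev["onset"].iloc[0]), is_null=True,
                    intention_level=None, intention_percent=0,
                    value_level=None, value_amount=0, rating_order=order,
                    rating1_duration=6.0, rating2_duration=6.0))
                continue
            tev = tev.sort_values("onset")
            first, second = tev.iloc[0], tev.iloc[1]
            trial_onset = float(first["onset"]) - 3.5
            trials.append(TrialEvent(
                run_index=int(run_idx), trial_index=int(trial_idx),
                onset=trial_onset, is_null=False,
                intention_level=str(first["intention"]),
                intention_percent=int(first["intention_percent"]),
                value_level=str(first["value"]),
                value_amount=int(first["value_amount"]),
                rating_order=order,
                rating1_duration=float(first["duration"]),
                rating2_duration=float(second["duration"])))
            ratings = {row["emotion"]: row["rating"]
                       for _, row in tev.iterrows()}
            records.append(RatingRecord(
                subject_id=subject_id, run_index=int(run_idx),
                trial_index=int(trial_idx),
                gratitude=None if pd.isna(ratings.get("gratitude"))
                else int(ratings["gratitude"]),
                joy=None if pd.isna(ratings.get("joy"))
                else int(ratings["joy"])))
        trials.sort(key=lambda t: t.onset)
        runs.append(RunSchedule(run_index=int(run_idx), rating_order=order,
                                trials=tuple(trials), tr=tr,
                                n_volumes=n_volumes))
    runs.sort(key=lambda r: r.run_index)
    return (SubjectDesign(subject_id=subject_id, order_scheme=order_scheme,
                          runs=tuple(runs)), records)


def write_design_matrix(X: DesignMatrix, csv_path) -> None:
    csv_path = Path(csv_path)
    X.to_frame().to_csv(csv_path, index=False)
    sidecar = {
        "names": list(X.names), "tr": X.tr,
        "run_volumes": list(X.run_volumes),
        "modulator_order": list(X.modulator_order),
        "orthogonalized": bool(X.orthogonalized),
        "dropped": list(X.dropped),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_design_matrix(csv_path) -> DesignMatrix:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return DesignMatrix(
        matrix=frame.to_numpy(float), names=meta["names"], tr=meta["tr"],
        run_volumes=meta["run_volumes"],
        modulator_order=tuple(meta["modulator_order"]),
        orthogonalized=meta["orthogonalized"], dropped=meta["dropped"])


def read_manifest(path, mask=None) -> tuple[dict, dict]:
    """MVPA manifest CSV (columns subject, emotion, path) -> two dicts of
    beta :class:`VoxelMap` keyed by subject."""
    manifest = pd.read_csv(path)
    base = Path(path).parent
    maps_g, maps_j = {}, {}
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        vmap = load_map(p, mask=mask)
        target = maps_g if row["emotion"] == "gratitude" else maps_j
        target[row["subject"]] = vmap
    return maps_g, maps_j
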