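"""Reading, writing and validation of every tabular artifact in the pipeline.

All stages exchange data through the plain-text dialects defined here: gaze
samples as TSV, trial designs / scores / stage results as CSV.  Schema
violations raise :class:`TableFormatError` rather than being coerced, and
every numeric column round-trips at full precision (17 significant digits).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical AOI condition labels, in storage order.
CONDITIONS = ("target", "agent_related", "action_related", "unrelated")

#: Closed set of participant group labels.
GROUPS = ("autistic", "NT")

#: Column order of the canonical long-format gaze dialect.
GAZE_COLUMNS = (
    "participant_id", "trial_id", "t_ms",
    "lx", "ly", "rx", "ry", "l_valid", "r_valid",
)

SCORE_COLUMNS = (
    "participant_id", "group", "age", "verbal_iq", "cars_total", "aq_total",
    "aq_social_skills", "aq_attention_switching", "aq_attention_to_detail",
    "aq_communication", "aq_imagination",
)

AQ_SUBSCALES = (
    "aq_social_skills", "aq_attention_switching", "aq_attention_to_detail",
    "aq_communication", "aq_imagination",
)

DESIGN_COLUMNS = (
    "trial_id", "quadruplet_id", "sentence_id", "position", "condition", "word",
)

#: Format string giving lossless float round-trips through text.
FLOAT_FMT = "%.17g"

SCHEMA_VERSION = "vwpgaze-v1"


class TableFormatError(ValueError):
    """A table violates the documented dialect (missing column, bad value...)."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display and recording geometry.

    Defaults describe a 24-inch 1920x1080 display viewed from 650 mm and a
    120-Hz binocular eye tracker.  The pixel pitch is derived from the
    diagonal size, and angular quantities use a flat-screen arctangent model
    about the screen centre.
    """

    width_px: int = 1920
    height_px: int = 1080
    diagonal_inch: float = 24.0
    viewing_distance_mm: float = 650.0
    sampling_rate_hz: float = 120.0

    @property
    def pixel_pitch_mm(self) -> float:
        diag_px = math.hypot(self.width_px, self.height_px)
        return self.diagonal_inch * 25.4 / diag_px

    @property
    def sample_interval_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def px_to_deg(self, dist_px: float | np.ndarray) -> float | np.ndarray:
        """Visual angle (degrees) subtended by an on-screen distance in px."""
        mm = np.asarray(dist_px, dtype=float) * self.pixel_pitch_mm
        out = np.degrees(np.arctan2(mm, self.viewing_distance_mm))
        return float(out) if np.isscalar(dist_px) else out

    def deg_to_px(self, deg: float) -> float:
        mm = math.tan(math.radians(deg)) * self.viewing_distance_mm
        return mm / self.pixel_pitch_mm


@dataclass
class GazeTable:
    """Ordered 120-Hz gaze samples for one participant across trials."""

    samples: pd.DataFrame
    participant_id: str
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    group: str | None = None

    def trial_ids(self) -> list:
        return list(dict.fromkeys(self.samples["trial_id"]))

    def trial(self, trial_id) -> pd.DataFrame:
        return self.samples[self.samples["trial_id"] == trial_id]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")


def validate_gaze_frame(df: pd.DataFrame, geometry: ScreenGeometry,
                        path="<memory>") -> pd.DataFrame:
    """Validate and normalize a raw gaze frame in place.

    Timestamps must be strictly increasing within each trial; rows whose
    coordinates fall outside the screen are retained with the corresponding
    eye flagged invalid; empty coordinates are only legal on invalid eyes.
    """
    _require_columns(df, GAZE_COLUMNS, path)
    df = df.loc[:, list(GAZE_COLUMNS)].copy()
    for col in ("lx", "ly", "rx", "ry", "t_ms"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("l_valid", "r_valid"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int8)

    for trial_id, sub in df.groupby("trial_id", sort=False):
        t = sub["t_ms"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            line = sub.index[bad[0] + 1] + 2  # +2: header plus 0-based index
            raise TableFormatError(
                f"{path}: non-monotone timestamps in trial {trial_id!r} "
                f"near line {line}")

    for eye in "lr":
        x, y = df[f"{eye}x"], df[f"{eye}y"]
        valid = df[f"{eye}_valid"].astype(bool)
        out = valid & (
            x.isna() | y.isna()
            | (x < 0) | (x >= geometry.width_px)
            | (y < 0) | (y >= geometry.height_px)
        )
        df.loc[out, f"{eye}_valid"] = 0
    return df


def read_gaze_table(path, geometry: ScreenGeometry | None = None,
                    participant_id: str | None = None,
                    group: str | None = None,
                    column_map: Mapping[str, str] | None = None) -> GazeTable:
    """Read one participant's gaze TSV in the canonical dialect.

    ``column_map`` renames foreign column names onto the canonical ones, so
    exports from other trackers can be ingested without rewriting files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    geometry = geometry or ScreenGeometry()
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    df = validate_gaze_frame(df, geometry, path)
    pids = df["participant_id"].unique()
    if participant_id is None:
        if len(pids) != 1:
            raise TableFormatError(
                f"{path}: expected a single participant, found {list(pids)}")
        participant_id = str(pids[0])
    elif set(map(str, pids)) - {str(participant_id)}:
        raise TableFormatError(
            f"{path}: unknown participant(s) {sorted(set(pids))}, "
            f"expected {participant_id}")
    return GazeTable(df, str(participant_id), geometry, group)


def write_gaze_table(table: GazeTable, path) -> None:
    table.samples.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_score_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return validate_score_frame(df, path)


def validate_score_frame(df: pd.DataFrame, path="<memory>") -> pd.DataFrame:
    _require_columns(df, SCORE_COLUMNS, path)
    df = df.loc[:, list(SCORE_COLUMNS)].copy()
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise TableFormatError(f"{path}: unknown group label(s) {sorted(bad)}; "
                               f"allowed: {GROUPS}")
    has_total = df["aq_total"].notna()
    for sub in AQ_SUBSCALES:
        if (has_total & df[sub].isna()).any():
            raise TableFormatError(
                f"{path}: {sub} missing for rows with an AQ total")
    return df


def write_score_table(df: pd.DataFrame, path) -> None:
    validate_score_frame(df).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_design_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, DESIGN_COLUMNS, path)
    counts = df.groupby("trial_id")["condition"].agg(
        lambda s: sorted(s) == sorted(CONDITIONS))
    if not counts.all():
        bad = counts.index[~counts].tolist()
        raise TableFormatError(
            f"{path}: trial(s) {bad} do not assign each condition to exactly "
            "one position")
    return df


def write_design_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Stage-result files

RESULT_SCHEMAS = {
    "clusters": ["group", "comparison", "start_ms", "end_ms", "n_bins",
                 "sum_t", "p"],
    "growth": ["term", "estimate", "se", "t", "p"],
    "divergence": ["group", "dp_estimate_ms", "ci_lo_ms", "ci_hi_ms",
                   "original_onset_ms", "n_missing"],
    "correlations": ["scope", "index", "measure", "n", "r", "p",
                     "ci_lo", "ci_hi", "family", "fdr_p"],
    "indices": ["participant_id", "group", "log_ratio_index",
                "individual_dp_ms", "dp_run_bins"],
}


def write_results(results: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write one schema-versioned CSV per result class.

    ``results`` maps a result-class name (a key of :data:`RESULT_SCHEMAS`, or
    any custom name for auxiliary tables) to its frame.  Empty frames yield
    header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        schema = RESULT_SCHEMAS.get(name)
        if schema is not None:
            missing = [c for c in schema if c not in df.columns]
            if missing:
                raise TableFormatError(
                    f"result class {name!r} missing column(s) {missing}")
            df = df.loc[:, schema + [c for c in df.columns if c not in schema]]
        target = out_dir / f"{name}.csv"
        with open(target, "w") as fh:
            fh.write(f"# {SCHEMA_VERSION} {name}\n")
            df.to_csv(fh, index=False, float_format=FLOAT_FMT)
        written.append(target)
    return written


def read_result(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def dataclass_frame(items: Sequence, columns: Sequence[str]) -> pd.DataFrame:
    """Tabulate a list of dataclass instances on the given fields."""
    rows = [{c: getattr(it, c) for c in columns} for it in items]
    return pd.DataFrame(rows, columns=list(columns))


def asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
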