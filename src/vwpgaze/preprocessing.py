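"""Raw gaze samples -> binary binned-fixation tensor.

The fixation filter is a velocity-threshold (I-VT) classifier with the
conventional surrounding steps, applied in this order per trial:

1. linear interpolation of invalid gaps up to 75 ms, separately per eye;
2. binocular averaging where both eyes are valid, single-eye fallback else;
3. velocity-threshold classification (default 30 deg/s over a 20-ms window);
4. merging of adjacent fixations separated by <= 75 ms AND <= 0.5 deg
   (conjunctive criteria, applied to a fixpoint so merging is idempotent);
5. removal of fixations shorter than 100 ms.

Fixation centroids are then assigned to four 384x384-px square AOIs (one per
screen position, equidistant from the screen centre, half-open boundaries)
and binary-coded into 50-ms bins over the [0, 2500) ms analysis window: a
condition is coded 1 in a bin iff a fixation assigned to it overlaps the bin
by more than ``min_overlap_ms`` (default: any positive overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CONDITIONS, GazeTable, ScreenGeometry

logger = logging.getLogger(__name__)

#: Half-width of the default AOI square, px.
AOI_SIZE_PX = 384

DEFAULT_WINDOW = (0.0, 2500.0)
DEFAULT_BIN_WIDTH = 50.0


@dataclass(frozen=True)
class FixationParams:
    """Tunable thresholds of the fixation filter (times in ms, angles deg)."""

    max_gap_ms: float = 75.0            # blink-gap interpolation limit
    velocity_threshold_deg_s: float = 30.0
    velocity_window_ms: float = 20.0
    merge_max_gap_ms: float = 75.0
    merge_max_angle_deg: float = 0.5
    min_duration_ms: float = 100.0


@dataclass
class Fixation:
    """A classified stable-gaze event."""

    onset_ms: float
    offset_ms: float
    x: float
    y: float
    source: str = "binocular"   # binocular | left_only | right_only
    trial_id: object = None

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


class AOILayoutError(ValueError):
    pass


@dataclass(frozen=True)
class AOILayout:
    """Four equal square AOIs, one per screen position.

    ``origins`` maps position index (0..3) to the (left, top) corner of a
    ``size_px`` square.  Containment is half-open: left/top edges inclusive,
    right/bottom exclusive.  The per-trial position -> condition mapping is
    supplied at assignment time (it changes every trial).
    """

    origins: Mapping[int, tuple[float, float]]
    size_px: float = AOI_SIZE_PX

    def __post_init__(self):
        items = sorted(self.origins.items())
        for (pa, (xa, ya)) in items:
            for (pb, (xb, yb)) in items:
                if pa < pb and abs(xa - xb) < self.size_px \
                        and abs(ya - yb) < self.size_px:
                    raise AOILayoutError(
                        f"AOIs {pa} and {pb} overlap")

    def position_at(self, x: float, y: float) -> int | None:
        for pos, (left, top) in self.origins.items():
            if left <= x < left + self.size_px and top <= y < top + self.size_px:
                return pos
        return None

    def center(self, pos: int) -> tuple[float, float]:
        left, top = self.origins[pos]
        return left + self.size_px / 2, top + self.size_px / 2


def default_layout(geometry: ScreenGeometry | None = None,
                   size_px: float = AOI_SIZE_PX) -> AOILayout:
    """Quadrant layout: AOI centres equidistant from the screen centre."""
    g = geometry or ScreenGeometry()
    cx = {0: g.width_px * 0.25, 1: g.width_px * 0.75}
    cy = {0: g.height_px * 0.25, 1: g.height_px * 0.75}
    origins = {}
    for pos, (ix, iy) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)]):
        origins[pos] = (cx[ix] - size_px / 2, cy[iy] - size_px / 2)
    return AOILayout(origins, size_px)


# ---------------------------------------------------------------------------
# Fixation detection


def _interpolate_gaps(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                      valid: np.ndarray, max_gap_ms: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly fill interior invalid runs spanning <= max_gap_ms."""
    valid = valid.copy()
    x, y = x.copy(), y.copy()
    n = len(t)
    dt = float(np.median(np.diff(t))) if n > 1 else 0.0
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        # invalid run [i, j); only interior gaps (valid data on both sides)
        # of missing duration <= max_gap_ms are filled
        gap_ms = (j - i) * dt
        if i > 0 and j < n and gap_ms <= max_gap_ms + 1e-6:
            frac = (t[i:j] - t[i - 1]) / (t[j] - t[i - 1])
            x[i:j] = x[i - 1] + frac * (x[j] - x[i - 1])
            y[i:j] = y[i - 1] + frac * (y[j] - y[i - 1])
            valid[i:j] = True
        i = j
    return x, y, valid


def combine_eyes(trial: pd.DataFrame, params: FixationParams,
                 geometry: ScreenGeometry
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gap-interpolate each eye then average; fall back to a single eye.

    Returns (t, x, y, valid, source_code) with source 2=binocular, 0=left,
    1=right.
    """
    t = trial["t_ms"].to_numpy(dtype=float)
    lx, ly, lv = _interpolate_gaps(
        t, trial["lx"].to_numpy(float), trial["ly"].to_numpy(float),
        trial["l_valid"].to_numpy(bool), params.max_gap_ms)
    rx, ry, rv = _interpolate_gaps(
        t, trial["rx"].to_numpy(float), trial["ry"].to_numpy(float),
        trial["r_valid"].to_numpy(bool), params.max_gap_ms)
    x = np.full(len(t), np.nan)
    y = np.full(len(t), np.nan)
    src = np.full(len(t), -1, dtype=np.int8)
    both = lv & rv
    x[both] = (lx[both] + rx[both]) / 2
    y[both] = (ly[both] + ry[both]) / 2
    src[both] = 2
    lonly = lv & ~rv
    x[lonly], y[lonly], src[lonly] = lx[lonly], ly[lonly], 0
    ronly = rv & ~lv
    x[ronly], y[ronly], src[ronly] = rx[ronly], ry[ronly], 1
    return t, x, y, (lv | rv), src


def _angular_velocity(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                      valid: np.ndarray, geometry: ScreenGeometry,
                      window_ms: float) -> np.ndarray:
    """Point-to-point angular velocity (deg/s) over ~window_ms, per sample."""
    n = len(t)
    dt = np.median(np.diff(t)) if n > 1 else 1.0
    half = max(1, int(round(window_ms / 2.0 / dt)))
    v = np.full(n, np.inf)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    ok = valid[lo] & valid[hi] & valid & (hi > lo)
    dist = np.hypot(x[hi] - x[lo], y[hi] - y[lo])
    span_s = (t[hi] - t[lo]) / 1000.0
    with np.errstate(invalid="ignore", divide="ignore"):
        vel = geometry.px_to_deg(dist) / span_s
    v[ok] = vel[ok]
    return v


def merge_fixations(fixations: list[Fixation], params: FixationParams,
                    geometry: ScreenGeometry) -> list[Fixation]:
    """Merge adjacent fixations (gap <= 75 ms AND angle <= 0.5 deg).

    Applied left to right until no pair merges, so the operation is
    idempotent.
    """
    fixations = sorted(fixations, key=lambda f: f.onset_ms)
    changed = True
    while changed:
        changed = False
        out: list[Fixation] = []
        for fix in fixations:
            if out:
                prev = out[-1]
                gap = fix.onset_ms - prev.offset_ms
                sep = geometry.px_to_deg(
                    np.hypot(fix.x - prev.x, fix.y - prev.y))
                if gap <= params.merge_max_gap_ms + 1e-9 \
                        and sep <= params.merge_max_angle_deg + 1e-12:
                    wa, wb = prev.duration_ms, fix.duration_ms
                    tot = wa + wb
                    out[-1] = replace(
                        prev,
                        offset_ms=fix.offset_ms,
                        x=(prev.x * wa + fix.x * wb) / tot,
                        y=(prev.y * wa + fix.y * wb) / tot,
                        source=prev.source if prev.source == fix.source
                        else "binocular",
                    )
                    changed = True
                    continue
            out.append(fix)
        fixations = out
    return fixations


_SOURCE_NAMES = {0: "left_only", 1: "right_only", 2: "binocular"}


def detect_fixations_trial(trial: pd.DataFrame, geometry: ScreenGeometry,
                           params: FixationParams | None = None,
                           trial_id=None) -> list[Fixation]:
    """Run the full I-VT pipeline on one trial's samples."""
    params = params or FixationParams()
    if geometry is None:
        raise ValueError("screen geometry required: the merge-angle and "
                         "velocity criteria are defined in visual degrees")
    t, x, y, valid, src = combine_eyes(trial, params, geometry)
    if len(t) == 0:
        return []
    dt = float(np.median(np.diff(t))) if len(t) > 1 else geometry.sample_interval_ms
    vel = _angular_velocity(t, x, y, valid, geometry,
                            params.velocity_window_ms)
    is_fix = valid & (vel < params.velocity_threshold_deg_s)

    fixations: list[Fixation] = []
    i, n = 0, len(t)
    while i < n:
        if not is_fix[i]:
            i += 1
            continue
        j = i
        while j < n and is_fix[j]:
            j += 1
        seg = slice(i, j)
        counts = np.bincount(src[seg][src[seg] >= 0], minlength=3)
        source = "binocular" if counts[2] > 0 else _SOURCE_NAMES[
            int(np.argmax(counts[:2]))]
        fixations.append(Fixation(
            onset_ms=float(t[i]), offset_ms=float(t[j - 1] + dt),
            x=float(np.mean(x[seg])), y=float(np.mean(y[seg])),
            source=source, trial_id=trial_id))
        i = j

    fixations = merge_fixations(fixations, params, geometry)
    return [f for f in fixations
            if f.duration_ms >= params.min_duration_ms - 1e-9]


def detect_fixations(table: GazeTable,
                     params: FixationParams | None = None) -> list[Fixation]:
    """Classify fixations for every trial of one participant's gaze table."""
    out: list[Fixation] = []
    for trial_id, trial in table.samples.groupby("trial_id", sort=False):
        out.extend(detect_fixations_trial(trial, table.geometry, params,
                                          trial_id=trial_id))
    return out


# ---------------------------------------------------------------------------
# AOI assignment and binning


def assign_aoi(fix: Fixation, layout: AOILayout,
               condition_of_position: Mapping[int, str]) -> str | None:
    """Condition label of the AOI containing the fixation centroid, or None."""
    pos = layout.position_at(fix.x, fix.y)
    if pos is None:
        return None
    return condition_of_position[pos]


def bin_fixations(fixations: Iterable[Fixation], layout: AOILayout,
                  condition_of_position: Mapping[int, str],
                  window: tuple[float, float] = DEFAULT_WINDOW,
                  bin_width: float = DEFAULT_BIN_WIDTH,
                  min_overlap_ms: float = 0.0) -> np.ndarray:
    """Binary (n_bins, n_conditions) occupancy for one trial.

    Condition ``c`` is coded 1 in bin ``b`` iff some fixation assigned to
    ``c`` overlaps the half-open bin [start + b*w, start + (b+1)*w) by more
    than ``min_overlap_ms`` (strictly more than zero by default).
    """
    start, end = window
    span = end - start
    n_bins = span / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"bin width {bin_width} does not divide window length {span}")
    n_bins = int(round(n_bins))
    out = np.zeros((n_bins, len(CONDITIONS)), dtype=np.uint8)
    cidx = {c: k for k, c in enumerate(CONDITIONS)}
    thr = max(min_overlap_ms, 0.0) + 1e-9
    for fix in fixations:
        cond = assign_aoi(fix, layout, condition_of_position)
        if cond is None:
            continue
        lo = int(np.floor((max(fix.onset_ms, start) - start) / bin_width))
        hi = int(np.ceil((min(fix.offset_ms, end) - start) / bin_width))
        for b in range(max(lo, 0), min(hi, n_bins)):
            b0 = start + b * bin_width
            overlap = min(fix.offset_ms, b0 + bin_width) - max(fix.onset_ms, b0)
            if overlap >= thr:
                out[b, cidx[cond]] = 1
    return out


# ---------------------------------------------------------------------------
# The binned fixation tensor


@dataclass
class BinnedFixationTensor:
    """Binary occupancy indexed (participant, trial, bin, condition).

    The common currency of every statistical stage.  ``data`` is float so
    that aggregated variants remain representable; entries of a freshly
    binned tensor are 0/1.
    """

    data: np.ndarray                      # (P, T, B, C)
    participants: list
    trials: list
    groups: np.ndarray                    # (P,) group label per participant
    window: tuple[float, float] = DEFAULT_WINDOW
    bin_width: float = DEFAULT_BIN_WIDTH
    conditions: tuple = CONDITIONS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        p, t, b, c = self.data.shape
        if (p, t, c) != (len(self.participants), len(self.trials),
                         len(self.conditions)):
            raise ValueError("tensor shape inconsistent with axis labels")

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    def bin_starts(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_bins) * self.bin_width

    def bin_centers(self) -> np.ndarray:
        return self.bin_starts() + self.bin_width / 2

    def condition_index(self, condition: str) -> int:
        return self.conditions.index(condition)

    def participant_proportions(self) -> np.ndarray:
        """Across-trial mean occupancy, shape (P, B, C)."""
        return np.nanmean(self.data, axis=1)

    def group_mask(self, group: str) -> np.ndarray:
        mask = self.groups == group
        if not mask.any():
            raise ValueError(f"no participants in group {group!r}")
        return mask

    def select_group(self, group: str) -> "BinnedFixationTensor":
        mask = self.group_mask(group)
        return BinnedFixationTensor(
            self.data[mask], [p for p, m in zip(self.participants, mask) if m],
            list(self.trials), self.groups[mask], self.window, self.bin_width,
            self.conditions)

    def to_long_frame(self) -> pd.DataFrame:
        p, t, b, c = self.data.shape
        idx = np.indices((p, t, b, c)).reshape(4, -1)
        return pd.DataFrame({
            "participant_id": np.asarray(self.participants, object)[idx[0]],
            "group": self.groups[idx[0]],
            "trial_id": np.asarray(self.trials, object)[idx[1]],
            "bin": idx[2],
            "condition": np.asarray(self.conditions, object)[idx[3]],
            "value": self.data.reshape(-1),
        })

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame,
                        window: tuple[float, float] = DEFAULT_WINDOW,
                        bin_width: float = DEFAULT_BIN_WIDTH
                        ) -> "BinnedFixationTensor":
        participants = list(dict.fromkeys(df["participant_id"]))
        trials = list(dict.fromkeys(df["trial_id"]))
        bins = int(df["bin"].max()) + 1
        pmap = {p: i for i, p in enumerate(participants)}
        tmap = {t: i for i, t in enumerate(trials)}
        cmap = {c: i for i, c in enumerate(CONDITIONS)}
        data = np.full((len(participants), len(trials), bins, len(CONDITIONS)),
                       np.nan)
        data[df["participant_id"].map(pmap), df["trial_id"].map(tmap),
             df["bin"], df["condition"].map(cmap)] = df["value"]
        groups = df.drop_duplicates("participant_id").set_index(
            "participant_id")["group"].reindex(participants).to_numpy()
        return cls(data, participants, trials, groups, window, bin_width)

    @classmethod
    def from_csv(cls, path, **kw) -> "BinnedFixationTensor":
        return cls.from_long_frame(pd.read_csv(path, comment="#", float_precision="round_trip"), **kw)


def preprocess_cohort(tables: Sequence[GazeTable], designs: pd.DataFrame,
                      layout: AOILayout | None = None,
                      params: FixationParams | None = None,
                      window: tuple[float, float] = DEFAULT_WINDOW,
                      bin_width: float = DEFAULT_BIN_WIDTH,
                      min_overlap_ms: float = 0.0) -> BinnedFixationTensor:
    """Fixation-classify and bin a whole cohort into one tensor.

    ``designs`` is the long design table (one row per trial x position)
    giving each trial's position -> condition mapping.
    """
    params = params or FixationParams()
    cond_of_pos = {
        tid: dict(zip(sub["position"], sub["condition"]))
        for tid, sub in designs.groupby("trial_id")
    }
    trial_ids = sorted(cond_of_pos)
    n_bins = int(round((window[1] - window[0]) / bin_width))
    data = np.zeros((len(tables), len(trial_ids), n_bins, len(CONDITIONS)))
    groups = []
    participants = []
    tmap = {t: i for i, t in enumerate(trial_ids)}
    for pi, table in enumerate(tables):
        lay = layout or default_layout(table.geometry)
        participants.append(table.participant_id)
        groups.append(table.group)
        fixations = detect_fixations(table, params)
        by_trial: dict = {}
        for f in fixations:
            by_trial.setdefault(f.trial_id, []).append(f)
        for tid, fxs in by_trial.items():
            if tid not in tmap:
                raise KeyError(f"trial {tid!r} absent from design table")
            data[pi, tmap[tid]] = bin_fixations(
                fxs, lay, cond_of_pos[tid], window, bin_width, min_overlap_ms)
    return BinnedFixationTensor(data, participants, trial_ids,
                                np.array(groups, object), window, bin_width)
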