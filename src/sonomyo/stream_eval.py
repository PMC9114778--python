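"""Real-time prediction streams, grasp-selection metrics, and the virtual hand.

During functional use the classifier emits one grasp prediction per frame,
and the prosthetic hand snaps to a preset configuration whenever the
(delayed) prediction changes.  Two indirect misclassification indicators
summarize a stream:

* **transient bouts** — maximal runs of identical predictions shorter than
  5 frames; a run of exactly 5 frames is *not* transient.  Deliberate grasp
  switches at the tasks' pick-and-place pace produce long runs, so short
  runs flag classifier flicker.
* **percent-point** — the percentage of frames classified POINT during
  tasks in which POINT is never useful.

End-to-end latency is modeled only as a configurable constant delay between
a prediction and the corresponding hand command (default 0.532 s); it
shifts the hand trajectory but leaves the stream metrics unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthgen import AcquisitionRecord, GraspLabel

DEFAULT_LATENCY_S = 0.532

#: Preset hand configurations commanded by each grasp.  REST keeps thumb,
#: index and middle partially extended with ring/little closed (so the
#: closed fingers cannot sweep blocks); transitions are preset, not
#: classifier-controlled.
HAND_CONFIGURATIONS: dict[GraspLabel, str] = {
    GraspLabel.REST: "REST_CONFIG",
    GraspLabel.TRIPOD: "TRIPOD_CONFIG",
    GraspLabel.POINT: "POINT_CONFIG",
}


@dataclass(frozen=True)
class PredictionStream:
    """Per-frame grasp predictions with timing."""

    predictions: tuple[GraspLabel, ...]
    timestamps_s: tuple[float, ...]
    latency_s: float = DEFAULT_LATENCY_S

    def __post_init__(self) -> None:
        if len(self.predictions) != len(self.timestamps_s):
            raise ValueError("predictions and timestamps must align")
        ts = np.asarray(self.timestamps_s)
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.latency_s < 0:
            raise ValueError("latency must be nonnegative")

    @property
    def command_timestamps_s(self) -> tuple[float, ...]:
        """When each prediction reaches the hand."""
        return tuple(t + self.latency_s for t in self.timestamps_s)


@dataclass(frozen=True)
class StreamMetrics:
    """Grasp-selection efficiency summary of one prediction stream."""

    n_frames: int
    n_transient_bouts: int
    pct_point: float
    run_lengths: tuple[tuple[GraspLabel, int], ...]

    def as_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "n_transient_bouts": self.n_transient_bouts,
            "pct_point": self.pct_point,
        }


def stream_classify(
    classifier,
    acquisitions: AcquisitionRecord | list[AcquisitionRecord],
    latency_s: float = DEFAULT_LATENCY_S,
) -> PredictionStream:
    """Classify every frame of one or more acquisitions in time order.

    Multiple acquisitions are concatenated on a common clock (each record's
    timestamps offset past the previous record's end).  Predictions are raw
    per-frame decisions; no smoothing or debouncing is applied.
    """
    if hasattr(acquisitions, "frames"):  # single record or scripted sequence
        acquisitions = [acquisitions]
    if not acquisitions or not any(r.n_frames for r in acquisitions):
        raise ValueError("need at least one frame to classify")
    preds: list[GraspLabel] = []
    times: list[float] = []
    offset = 0.0
    for rec in acquisitions:
        X = np.stack([f.pixels.astype(float).ravel() / 255.0 for f in rec.frames])
        labels = classifier.predict_features(X)
        preds.extend(GraspLabel(int(v)) for v in labels)
        times.extend(offset + t for t in rec.timestamps_s)
        # advance the clock one frame period past this record
        dt = (
            rec.timestamps_s[1] - rec.timestamps_s[0]
            if rec.n_frames > 1
            else 1.0
        )
        offset = times[-1] + dt
    return PredictionStream(tuple(preds), tuple(times), latency_s)


def run_length_encode(predictions) -> list[tuple[GraspLabel, int]]:
    """Maximal runs of identical consecutive labels; concatenating the runs
    reconstructs the input."""
    preds = list(predictions)
    if not preds:
        raise ValueError("cannot encode an empty prediction list")
    runs: list[tuple[GraspLabel, int]] = []
    current, count = preds[0], 1
    for p in preds[1:]:
        if p == current:
            count += 1
        else:
            runs.append((current, count))
            current, count = p, 1
    runs.append((current, count))
    return runs


def count_transient_bouts(predictions, min_len: int = 5) -> int:
    """Number of maximal runs strictly shorter than ``min_len`` frames.

    Runs at the stream boundaries count like interior runs; a run of
    exactly ``min_len`` frames is not transient.
    """
    return sum(1 for _, length in run_length_encode(predictions) if length < min_len)


def percent_point(predictions) -> float:
    """Percentage of frames classified POINT."""
    preds = list(predictions)
    if not preds:
        raise ValueError("cannot score an empty prediction list")
    return 100.0 * sum(1 for p in preds if p == GraspLabel.POINT) / len(preds)


def percent_label(predictions, label: GraspLabel) -> float:
    """Percentage of frames carrying ``label``."""
    preds = list(predictions)
    if not preds:
        raise ValueError("cannot score an empty prediction list")
    return 100.0 * sum(1 for p in preds if p == label) / len(preds)


def stream_metrics(stream: PredictionStream | list, min_len: int = 5) -> StreamMetrics:
    """All stream metrics of a prediction stream (or bare label list)."""
    preds = stream.predictions if isinstance(stream, PredictionStream) else stream
    runs = run_length_encode(preds)
    return StreamMetrics(
        n_frames=len(list(preds)),
        n_transient_bouts=sum(1 for _, n in runs if n < min_len),
        pct_point=percent_point(preds),
        run_lengths=tuple(runs),
    )


def hand_trajectory(stream: PredictionStream) -> list[tuple[float, str]]:
    """Sequence of (time, hand configuration) the virtual hand assumes.

    The hand starts in REST_CONFIG at the first command time and changes
    configuration exactly when the delayed prediction changes; the number
    of changes equals the number of runs minus one (plus an initial
    transition if the stream does not start at REST).
    """
    cmd_times = stream.command_timestamps_s
    trajectory: list[tuple[float, str]] = []
    state = "REST_CONFIG"
    trajectory.append((cmd_times[0], state))
    prev = None
    for t, p in zip(cmd_times, stream.predictions):
        cfg = HAND_CONFIGURATIONS[p]
        if prev is None:
            if cfg != state:
                trajectory.append((t, cfg))
                state = cfg
        elif p != prev:
            trajectory.append((t, cfg))
            state = cfg
        prev = p
    return trajectory
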