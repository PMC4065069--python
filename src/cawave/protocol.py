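"""Theta-burst stimulation (TBS) schedule model.

A theta-burst stimulus is a sequence of short high-frequency pulse trains
delivered at theta-rhythm spacing.  The default protocol used throughout the
package is 8 trains of 8 pulses, each train lasting 40 ms (200 Hz within a
train) with trains starting every 2 s, delivered after a 20 s baseline.  All
"time since stimulation onset" bookkeeping in the analysis modules is anchored
here.

Train spacing follows the start-to-start convention: the total stimulus
duration is ``(n_trains - 1) * inter_train_start_interval + train_duration``,
which for the default protocol gives 14.04 s.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = [
    "StimProtocol",
    "build_protocol",
    "pulse_rate",
    "frame_to_time_since_onset",
]


@dataclass(frozen=True)
class StimProtocol:
    """A periodic pulse-train stimulation schedule.

    Parameters
    ----------
    n_trains
        Number of pulse trains.
    pulses_per_train
        Pulses delivered within one train.
    train_duration
        Duration of a single train in seconds.
    inter_train_start_interval
        Start-to-start spacing of consecutive trains in seconds.
    onset_time
        Time of the first train relative to recording start, in seconds
        (the pre-stimulus baseline length).
    """

    n_trains: int = 8
    pulses_per_train: int = 8
    train_duration: float = 0.04
    inter_train_start_interval: float = 2.0
    onset_time: float = 20.0

    def __post_init__(self) -> None:
        if int(self.n_trains) != self.n_trains or self.n_trains < 1:
            raise ValueError(f"n_trains must be a positive integer, got {self.n_trains}")
        if int(self.pulses_per_train) != self.pulses_per_train or self.pulses_per_train < 1:
            raise ValueError(
                f"pulses_per_train must be a positive integer, got {self.pulses_per_train}"
            )
        if self.train_duration <= 0:
            raise ValueError(f"train_duration must be > 0, got {self.train_duration}")
        if self.inter_train_start_interval <= 0:
            raise ValueError(
                "inter_train_start_interval must be > 0, got "
                f"{self.inter_train_start_interval}"
            )
        if self.train_duration > self.inter_train_start_interval:
            raise ValueError(
                "train_duration must not exceed inter_train_start_interval "
                f"({self.train_duration} > {self.inter_train_start_interval})"
            )
        if self.onset_time < 0:
            raise ValueError(f"onset_time must be >= 0, got {self.onset_time}")

    @property
    def total_pulses(self) -> int:
        return self.n_trains * self.pulses_per_train

    @property
    def pulse_rate(self) -> float:
        """Intra-train pulse rate in Hz."""
        return self.pulses_per_train / self.train_duration

    @property
    def total_duration(self) -> float:
        """Stimulus duration in seconds, start-to-start convention."""
        return (self.n_trains - 1) * self.inter_train_start_interval + self.train_duration

    @property
    def offset_time(self) -> float:
        """Time the stimulus completes, relative to recording start (s)."""
        return self.onset_time + self.total_duration

    def train_start_times(self) -> list[float]:
        """Start time of each train, in seconds from recording start."""
        return [
            self.onset_time + i * self.inter_train_start_interval
            for i in range(self.n_trains)
        ]

    def to_dict(self) -> dict:
        """Serialize using the config-file key names."""
        return {
            "n_trains": self.n_trains,
            "pulses_per_train": self.pulses_per_train,
            "train_duration_s": self.train_duration,
            "inter_train_start_s": self.inter_train_start_interval,
            "onset_s": self.onset_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimProtocol":
        return cls(
            n_trains=int(d.get("n_trains", 8)),
            pulses_per_train=int(d.get("pulses_per_train", 8)),
            train_duration=float(d.get("train_duration_s", 0.04)),
            inter_train_start_interval=float(d.get("inter_train_start_s", 2.0)),
            onset_time=float(d.get("onset_s", 20.0)),
        )


def build_protocol(
    n_trains: int,
    pulses_per_train: int,
    train_duration: float,
    inter_train_start_interval: float,
    onset_time: float,
) -> StimProtocol:
    """Construct a validated :class:`StimProtocol`.

    Raises
    ------
    ValueError
        If any count is non-positive, a duration is non-positive, or the
        train duration exceeds the train spacing.  The offending field is
        named in the message.
    """
    return StimProtocol(
        n_trains=n_trains,
        pulses_per_train=pulses_per_train,
        train_duration=train_duration,
        inter_train_start_interval=inter_train_start_interval,
        onset_time=onset_time,
    )


def pulse_rate(p: StimProtocol) -> float:
    """Intra-train pulse rate of a protocol, in Hz."""
    return p.pulse_rate


def frame_to_time_since_onset(
    frame_index: int, frame_interval: float, p: StimProtocol
) -> float:
    """Convert a frame index to seconds since stimulation onset.

    Negative values indicate baseline frames acquired before the stimulus.
    """
    if frame_index < 0:
        raise ValueError(f"frame_index must be >= 0, got {frame_index}")
    return frame_index * frame_interval - p.onset_time
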