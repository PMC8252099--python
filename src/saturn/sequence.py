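"""Sequence-level domain types and protocol construction.

The SATURN acquisition interleaves three kinds of magnetization preparation in
front of a single-shot multi-gradient-echo readout:

* an unprepared image (full recovery, infinite saturation delay),
* T2-prepared images (composite 90-MLEV-270 module of duration ``T2p``),
* saturation-prepared images (WET pulse, saturation delay ``TS``).

A full protocol consists of 7 contrasts read out at 5 echo times, i.e. 35
magnitude images.  Images without saturation preparation are preceded by a rest
period (default 4 s) so that the fit may assume full longitudinal recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

SCHEMA_VERSION = 1

#: Symbolic "no saturation pulse was played" delay.  Encoded as IEEE infinity in
#: memory (the fit evaluates the recovery factor exactly as 1) and as the string
#: ``"inf"`` on disk.
INFINITE_TS = math.inf

PrepKind = Literal["none", "t2prep", "saturation"]


class ProtocolError(ValueError):
    """Raised for physically or structurally invalid protocol definitions."""


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth relaxation constants of a voxel or phantom compartment.

    All times in milliseconds.  ``T2star`` may be set independently of ``T2``
    (simulation sweeps treat it as a free axis), but ``T2 <= T1`` is enforced.
    """

    T1: float
    T2: float
    T2star: float
    M0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("T1", "T2", "T2star", "M0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TissueParams.{name} must be strictly positive")
        if self.T2 > self.T1:
            raise ValueError(f"T2={self.T2} ms exceeds T1={self.T1} ms")


@dataclass(frozen=True)
class ContrastSpec:
    """One prepared contrast of the acquisition.

    ``TS`` is the saturation delay (saturation-pulse end to k-space-center
    excitation) in ms, infinite for images without a saturation pulse.
    ``rest_before`` is the free-relaxation rest period preceding the image.
    """

    index: int
    prep: PrepKind
    TS: float
    T2p: float
    rest_before: float
    navigated: bool = True

    def __post_init__(self) -> None:
        if self.prep == "none":
            if not math.isinf(self.TS) or self.T2p != 0:
                raise ProtocolError("unprepared contrast requires TS=inf, T2p=0")
        elif self.prep == "t2prep":
            if not math.isinf(self.TS) or not self.T2p > 0:
                raise ProtocolError("t2prep contrast requires TS=inf, T2p>0")
        elif self.prep == "saturation":
            if not (math.isfinite(self.TS) and self.TS > 0) or self.T2p != 0:
                raise ProtocolError("saturation contrast requires finite TS>0, T2p=0")
        else:  # pragma: no cover - Literal guards this
            raise ProtocolError(f"unknown prep kind {self.prep!r}")
        if self.rest_before > 0 and self.prep == "saturation":
            raise ProtocolError("rest periods only precede images without saturation")
        if self.rest_before < 0:
            raise ProtocolError("rest_before must be >= 0")


@dataclass(frozen=True)
class SaturnProtocol:
    """Ordered list of prepared contrasts plus readout timing.

    Times in ms, heart rate in bpm.  The readout train acquires
    ``n_kspace_lines`` excitations at repetition time ``TR``; under centric
    reordering the k-space center is the first excitation, so image contrast
    reflects the magnetization at the train start.
    """

    contrasts: tuple[ContrastSpec, ...]
    echo_times: tuple[float, ...]
    TR: float = 10.3
    flip_angle: float = 20.0
    n_kspace_lines: int = 36
    centric: bool = True
    heart_rate: float = 60.0
    TSmin: float = 7.0
    TSmax: float = 600.0
    rest_period: float = 4000.0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, float)
        if te.size < 1 or np.any(np.diff(te) <= 0):
            raise ProtocolError("echo_times must be strictly increasing")
        if te[0] < 0 or te[-1] > self.TR:
            raise ProtocolError("echo times must lie within [0, TR]")
        if not (30.0 <= self.heart_rate <= 200.0):
            raise ProtocolError("heart_rate outside the supported 30-200 bpm range")
        if not (0 < self.TSmin < self.TSmax):
            raise ProtocolError("require 0 < TSmin < TSmax")
        if self.TSmax >= self.rr_interval:
            raise ProtocolError(
                f"TSmax={self.TSmax} ms must be shorter than the RR interval "
                f"({self.rr_interval:.1f} ms)"
            )
        if self.trigger_delay + self.readout_duration > self.rr_interval:
            raise ProtocolError(
                "readout does not fit into the cardiac cycle: trigger delay "
                f"{self.trigger_delay:.1f} ms + train {self.readout_duration:.1f} ms "
                f"exceeds RR {self.rr_interval:.1f} ms"
            )

    # -- derived timing ---------------------------------------------------
    @property
    def rr_interval(self) -> float:
        """RR interval in ms for the fixed simulated heart rate."""
        return 60000.0 / self.heart_rate

    @property
    def readout_duration(self) -> float:
        return self.n_kspace_lines * self.TR

    @property
    def trigger_delay(self) -> float:
        """Time from beat start to the first readout excitation (ms).

        The longest saturation delay plays at the beat start (systole), so the
        trigger delay must accommodate ``TSmax``; likewise the longest T2-prep
        module must finish before the trigger.
        """
        longest_t2p = max((c.T2p for c in self.contrasts), default=0.0)
        return max(self.TSmax, longest_t2p)

    @property
    def n_samples(self) -> int:
        return len(self.contrasts) * len(self.echo_times)

    def sample_coordinates(self) -> np.ndarray:
        """(n_samples, 4) array of (contrast_index, TS, T2p, TE)."""
        rows = [
            (c.index, c.TS, c.T2p, te)
            for c in self.contrasts
            for te in self.echo_times
        ]
        return np.asarray(rows, float)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "units": {"time": "ms", "heart_rate": "bpm", "flip_angle": "deg"},
            "contrasts": [
                {
                    "index": c.index,
                    "prep": c.prep,
                    "TS": "inf" if math.isinf(c.TS) else c.TS,
                    "T2p": c.T2p,
                    "rest_before": c.rest_before,
                    "navigated": c.navigated,
                }
                for c in self.contrasts
            ],
            "echo_times": list(self.echo_times),
            "TR": self.TR,
            "flip_angle": self.flip_angle,
            "n_kspace_lines": self.n_kspace_lines,
            "centric": self.centric,
            "heart_rate": self.heart_rate,
            "TSmin": self.TSmin,
            "TSmax": self.TSmax,
            "rest_period": self.rest_period,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SaturnProtocol":
        if d.get("schema_version", 1) != SCHEMA_VERSION:
            raise ProtocolError(f"unsupported schema version {d.get('schema_version')}")
        contrasts = tuple(
            ContrastSpec(
                index=int(c["index"]),
                prep=c["prep"],
                TS=math.inf if c["TS"] in ("inf", None) else float(c["TS"]),
                T2p=float(c["T2p"]),
                rest_before=float(c["rest_before"]),
                navigated=bool(c.get("navigated", True)),
            )
            for c in d["contrasts"]
        )
        return cls(
            contrasts=contrasts,
            echo_times=tuple(float(t) for t in d["echo_times"]),
            TR=float(d["TR"]),
            flip_angle=float(d["flip_angle"]),
            n_kspace_lines=int(d["n_kspace_lines"]),
            centric=bool(d["centric"]),
            heart_rate=float(d["heart_rate"]),
            TSmin=float(d["TSmin"]),
            TSmax=float(d["TSmax"]),
            rest_period=float(d["rest_period"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SaturnProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SaturnProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SignalSeries:
    """Magnitude samples with their (TS, T2p, TE) coordinates.

    A full acquisition yields 35 samples (7 contrasts x 5 echoes).  ``TS`` uses
    IEEE infinity for images without saturation preparation.
    """

    contrast_index: np.ndarray
    TS: np.ndarray
    T2p: np.ndarray
    TE: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.magnitude)
        for name in ("contrast_index", "TS", "T2p", "TE", "magnitude"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (n,):
                raise ValueError("all SignalSeries fields must be 1-D of equal length")
            setattr(self, name, arr)
        if np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.magnitude)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "contrast_index": self.contrast_index.astype(int),
                "TS_ms": self.TS,
                "T2p_ms": self.T2p,
                "TE_ms": self.TE,
                "magnitude": self.magnitude,
            }
        )

    @classmethod
    def from_frame(cls, df) -> "SignalSeries":
        return cls(
            contrast_index=df["contrast_index"].to_numpy(float),
            TS=df["TS_ms"].to_numpy(float),
            T2p=df["T2p_ms"].to_numpy(float),
            TE=df["TE_ms"].to_numpy(float),
            magnitude=df["magnitude"].to_numpy(float),
        )


@dataclass
class GatingOutcome:
    """Bookkeeping of the navigator accept-reject scheme for one acquisition."""

    accepted_beats: int
    rejected_beats: int
    total_duration: float  # seconds
    per_contrast_attempts: list[int]
    effective_rest_ms: list[float]

    @property
    def efficiency(self) -> float:
        return self.accepted_beats / (self.accepted_beats + self.rejected_beats)


def default_echo_times(n: int = 5, te_min: float = 1.0, te_max: float = 8.5) -> tuple[float, ...]:
    """Linearly spaced echo times in the published 1.0-8.5 ms range."""
    return tuple(np.linspace(te_min, te_max, n))


def build_saturn_protocol(
    heart_rate: float = 60.0,
    TSmin: float = 7.0,
    TSmax: float | str = "auto",
    rest_period: float = 4000.0,
    t2prep_durations: Sequence[float] = (25.0, 50.0),
    echo_times: Sequence[float] | None = None,
    TR: float = 10.3,
    flip_angle: float = 20.0,
    n_kspace_lines: int = 36,
    centric: bool = True,
    systole_offset: float = 400.0,
    allow_single_t2prep: bool = False,
) -> SaturnProtocol:
    """Construct the 7-contrast protocol in the canonical order.

    Order: (1) unprepared, (2)+(3) T2-prepared with the given durations,
    (4)/(6) saturation at ``TSmin``, (5)/(7) saturation at ``TSmax``.  Rest
    periods precede every image without saturation preparation.

    ``TSmax="auto"`` resolves to ``RR - systole_offset`` so that the saturation
    pulse of the long-delay images plays at the start of systole and the
    readout still sits in end-diastole.
    """
    if not (30.0 <= heart_rate <= 200.0):
        raise ProtocolError("heart_rate outside the supported 30-200 bpm range")
    rr = 60000.0 / heart_rate
    if TSmax == "auto":
        TSmax = rr - systole_offset
    TSmax = float(TSmax)
    if TSmax >= rr:
        raise ProtocolError("TSmax must be shorter than the RR interval")
    if not (0 < TSmin < TSmax):
        raise ProtocolError("require 0 < TSmin < TSmax")
    durations = tuple(float(d) for d in t2prep_durations)
    if len(durations) < 2 and not allow_single_t2prep:
        raise ProtocolError(
            "fewer than 2 T2-prep durations makes T2 unidentifiable; "
            "pass allow_single_t2prep=True to override"
        )
    if echo_times is None:
        echo_times = default_echo_times()

    contrasts = [ContrastSpec(1, "none", INFINITE_TS, 0.0, rest_period)]
    idx = 2
    for d in durations:
        contrasts.append(ContrastSpec(idx, "t2prep", INFINITE_TS, d, rest_period))
        idx += 1
    for ts in (TSmin, TSmax, TSmin, TSmax):
        contrasts.append(ContrastSpec(idx, "saturation", ts, 0.0, 0.0))
        idx += 1

    return SaturnProtocol(
        contrasts=tuple(contrasts),
        echo_times=tuple(float(t) for t in echo_times),
        TR=TR,
        flip_angle=flip_angle,
        n_kspace_lines=n_kspace_lines,
        centric=centric,
        heart_rate=heart_rate,
        TSmin=TSmin,
        TSmax=TSmax,
        rest_period=rest_period,
    )


def simulate_gating(
    protocol: SaturnProtocol,
    acceptance: float | Sequence[bool],
    seed: int | None = None,
) -> GatingOutcome:
    """Simulate the navigator accept-reject scheme and the resulting scan time.

    Unprepared and saturation-prepared images are re-attempted on the next
    heartbeat after a rejection.  For T2-prepared images the preparation plays
    only on an accepted navigator, so rejections extend the effective rest
    period instead of repeating it.  ``acceptance`` is either a per-navigator
    acceptance probability in (0, 1] or an explicit boolean trace.
    """
    rr = protocol.rr_interval
    if isinstance(acceptance, (int, float)):
        p = float(acceptance)
        if not (0.0 < p <= 1.0):
            raise ValueError("acceptance probability must lie in (0, 1]")
        rng = np.random.default_rng(seed)

        def nav() -> bool:
            return bool(rng.random() < p)

    else:
        trace = iter(list(acceptance))

        def nav() -> bool:
            try:
                return bool(next(trace))
            except StopIteration:
                raise ValueError("acceptance trace exhausted before scan completed")

    t = 0.0
    accepted = rejected = 0
    attempts_per_contrast: list[int] = []
    effective_rest: list[float] = []
    for c in protocol.contrasts:
        t += c.rest_before
        attempts = 0
        extra_rest = 0.0
        while True:
            attempts += 1
            if nav():
                accepted += 1
                t += rr  # imaging beat
                break
            rejected += 1
            t += rr  # wasted beat; for rest-prepared images it extends the rest
            if c.prep != "saturation":
                extra_rest += rr
        attempts_per_contrast.append(attempts)
        effective_rest.append(c.rest_before + extra_rest)

    return GatingOutcome(
        accepted_beats=accepted,
        rejected_beats=rejected,
        total_duration=t / 1000.0,
        per_contrast_attempts=attempts_per_contrast,
        effective_rest_ms=effective_rest,
    )
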