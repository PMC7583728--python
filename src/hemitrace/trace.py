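"""Uniformly sampled whole-cell current records.

A :class:`Trace` is the universal input of the analysis: a current record in
picoamperes sampled at a fixed rate, carrying the step potential ``vm`` (mV)
needed to express current steps as unitary conductances (gamma = di/Vm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Trace", "read_trace", "write_trace"]


@dataclass
class Trace:
    """A uniformly sampled current record.

    Parameters
    ----------
    samples
        Current in pA, one value per sample.
    sampling_rate
        Samples per second (Hz), > 0.
    vm
        Step (membrane) potential in mV during the sweep. Needed to convert
        current steps to conductances; may be 0 only for operations that do
        not require it.
    t0
        Time of the first sample in seconds.
    metadata
        Free-form condition labels (cell line, condition, trace id ...).
    """

    samples: np.ndarray
    sampling_rate: float
    vm: float = 0.0
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Time of each sample in seconds (``t0 + i / sampling_rate``)."""
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    def time_to_index(self, t: float, clip: bool = True) -> int:
        """Nearest sample index for time ``t`` (clipped to the trace by default)."""
        i = int(round((t - self.t0) * self.sampling_rate))
        if clip:
            i = min(max(i, 0), self.samples.size - 1)
        elif not 0 <= i < self.samples.size:
            raise IndexError(f"time {t} s outside trace span")
        return i

    def index_to_time(self, i: int) -> float:
        return self.t0 + i / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "Trace":
        """Copy of this trace with new samples but identical sampling metadata."""
        return replace(self, samples=np.asarray(samples, dtype=float))


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as two-column delimited text (time_s, current_pA).

    Sampling metadata is stored in ``#``-prefixed header lines so the file
    round-trips through :func:`read_trace`.
    """
    path = Path(path)
    header = [
        f"sampling_rate_hz={trace.sampling_rate!r}",
        f"vm_mv={trace.vm!r}",
        f"t0_s={trace.t0!r}",
    ]
    header += [f"meta.{k}={v}" for k, v in sorted(trace.metadata.items())]
    data = np.column_stack([trace.times, trace.samples])
    np.savetxt(path, data, fmt="%.9g", delimiter="\t",
               header="\n".join(header + ["time_s\tcurrent_pA"]))


def read_trace(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace`.

    Plain two-column files without a metadata header are accepted too; the
    sampling rate is then inferred from the time column and ``vm`` is 0.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    data = np.loadtxt(path, delimiter=None)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, current)")
    times, samples = data[:, 0], data[:, 1]
    if "sampling_rate_hz" in meta:
        rate = float(meta["sampling_rate_hz"])
    else:
        dt = np.diff(times)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError(f"{path}: non-uniform time column")
        rate = 1.0 / dt[0]
    extra = {k[5:]: v for k, v in meta.items() if k.startswith("meta.")}
    return Trace(
        samples=samples,
        sampling_rate=rate,
        vm=float(meta.get("vm_mv", 0.0)),
        t0=float(meta.get("t0_s", times[0] if times.size else 0.0)),
        metadata=extra,
    )
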