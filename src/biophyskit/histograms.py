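"""Containers for time-correlated single photon counting (TCSPC) data.

A :class:`TCSPCHistogram` holds one channelized decay together with the
instrument response function (IRF) measured on the same time grid; a
:class:`PolarizedDecays` pairs the two polarized components I_vv(t) and
I_vh(t) that anisotropy analysis consumes.  Counts are photon counts per
channel; noise-free simulations store the (real-valued) expected counts in
the same container.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TCSPCHistogram",
    "PolarizedDecays",
    "read_decay",
    "write_decay",
    "read_polarized",
    "write_polarized",
]

_MIN_CHANNELS = 64


@dataclass
class TCSPCHistogram:
    """Channelized photon-count decay plus its instrument response.

    Parameters
    ----------
    channel_width : float
        Channel width in ns, > 0.
    counts : ndarray
        Photon counts per channel (non-negative; real-valued for
        noise-free expectations).
    irf_counts : ndarray
        IRF histogram on the same grid.
    background : float
        Expected background counts per channel (default 0).
    """

    channel_width: float
    counts: np.ndarray
    irf_counts: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.irf_counts = np.asarray(self.irf_counts, dtype=float)
        if self.channel_width <= 0:
            raise ValueError("channel_width must be positive")
        if self.counts.ndim != 1 or self.irf_counts.ndim != 1:
            raise ValueError("counts and irf_counts must be 1-D")
        if len(self.counts) != len(self.irf_counts):
            raise ValueError("counts and irf_counts must share the grid")
        if len(self.counts) < _MIN_CHANNELS:
            raise ValueError(f"need at least {_MIN_CHANNELS} channels")
        if np.any(self.counts < 0) or np.any(self.irf_counts < 0):
            raise ValueError("counts must be non-negative")
        if self.background < 0:
            raise ValueError("background must be non-negative")

    @property
    def n_channels(self) -> int:
        return len(self.counts)

    @property
    def times(self) -> np.ndarray:
        """Channel midpoint times in ns."""
        return (np.arange(self.n_channels) + 0.5) * self.channel_width

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def irf_peak_channel(self) -> int:
        return int(np.argmax(self.irf_counts))

    def with_counts(self, counts: np.ndarray) -> "TCSPCHistogram":
        return replace(self, counts=np.asarray(counts, dtype=float))


@dataclass
class PolarizedDecays:
    """Vertically/horizontally polarized decay pair sharing one grid and IRF.

    ``g_factor`` is the detection-balance ratio G multiplying I_vh when the
    total intensity and anisotropy are reconstructed.
    """

    ivv: TCSPCHistogram
    ivh: TCSPCHistogram
    g_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.g_factor <= 0:
            raise ValueError("g_factor must be positive")
        if self.ivv.n_channels != self.ivh.n_channels:
            raise ValueError("polarized components must share the grid")
        if self.ivv.channel_width != self.ivh.channel_width:
            raise ValueError("polarized components must share channel width")
        if not np.array_equal(self.ivv.irf_counts, self.ivh.irf_counts):
            raise ValueError("polarized components must share the IRF")

    @property
    def channel_width(self) -> float:
        return self.ivv.channel_width

    @property
    def times(self) -> np.ndarray:
        return self.ivv.times


# ---------------------------------------------------------------------------
# Delimited-text readers/writers.  Decays are stored as three columns
# (time_ns, counts, irf) and polarized pairs as four columns
# (time_ns, ivv, ivh, irf), with a one-line '#' header carrying metadata.
# ---------------------------------------------------------------------------


def write_decay(path, hist: TCSPCHistogram) -> None:
    header = (
        f"time_ns counts irf  channel_width_ns={hist.channel_width!r} "
        f"background={hist.background!r}"
    )
    data = np.column_stack([hist.times, hist.counts, hist.irf_counts])
    np.savetxt(path, data, header=header)


def _header_value(path, key: str, default: float | None = None) -> float:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if token.startswith(key + "="):
                    return float(token.split("=", 1)[1])
    if default is None:
        raise ValueError(f"header key {key!r} not found in {path}")
    return default


def read_decay(path) -> TCSPCHistogram:
    data = np.loadtxt(path)
    t = data[:, 0]
    width = _header_value(path, "channel_width_ns", float(np.diff(t).mean()))
    background = _header_value(path, "background", 0.0)
    return TCSPCHistogram(
        channel_width=width,
        counts=data[:, 1],
        irf_counts=data[:, 2],
        background=background,
    )


def write_polarized(path, pol: PolarizedDecays) -> None:
    header = (
        f"time_ns ivv ivh irf  g_factor={pol.g_factor!r} "
        f"channel_width_ns={pol.channel_width!r} "
        f"background={pol.ivv.background!r}"
    )
    data = np.column_stack(
        [pol.times, pol.ivv.counts, pol.ivh.counts, pol.ivv.irf_counts]
    )
    np.savetxt(path, data, header=header)


def read_polarized(path) -> PolarizedDecays:
    data = np.loadtxt(path)
    t = data[:, 0]
    width = _header_value(path, "channel_width_ns", float(np.diff(t).mean()))
    g = _header_value(path, "g_factor", 1.0)
    background = _header_value(path, "background", 0.0)
    ivv = TCSPCHistogram(width, data[:, 1], data[:, 3], background)
    ivh = TCSPCHistogram(width, data[:, 2], data[:, 3], background)
    return PolarizedDecays(ivv=ivv, ivh=ivh, g_factor=g)
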