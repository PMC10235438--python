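"""ΔF/F₀, population calcium-transient synchrony, and nuclear/cytoplasmic ratio.

Synchrony criterion: a transient counts as a synchronous network event when
the population ΔF/F peak is at least one tenth of the reference transient —
the first calcium transient evoked by bicuculline at the end of the
recording, which reflects a full network action-potential burst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .trace_io import Trace

__all__ = [
    "RoiTraceSet",
    "SynchronyResult",
    "CellRatio",
    "dff",
    "reference_peak",
    "detect_synchronous_events",
    "nuc_cyto_ratio",
    "write_roi_table",
    "load_roi_table",
]


@dataclass(frozen=True)
class RoiTraceSet:
    """Fluorescence traces of all ROIs (cell somata) in one imaging field."""

    traces: tuple[Trace, ...]
    background: float | np.ndarray = 0.0
    bic_marker: int | None = None  # sample index where bicuculline is added

    def __post_init__(self) -> None:
        traces = tuple(self.traces)
        if not traces:
            raise ValueError("need at least one ROI")
        object.__setattr__(self, "traces", traces)
        dt0, n0 = traces[0].dt, traces[0].n
        for t in traces[1:]:
            if t.dt != dt0 or t.n != n0:
                raise ValueError("all ROI traces must share fps and length")

    @property
    def fps(self) -> float:
        return 1.0 / self.traces[0].dt

    @property
    def n_rois(self) -> int:
        return len(self.traces)


@dataclass(frozen=True)
class SynchronyResult:
    event_times: np.ndarray          # s
    event_amplitudes: np.ndarray     # population dF/F peak per event
    frequency_per_min: float
    reference_peak: float
    criterion_ratio: float = 0.1


@dataclass(frozen=True)
class CellRatio:
    nuclear_mean: float
    cytoplasmic_mean: float

    @property
    def ratio(self) -> float:
        return self.nuclear_mean / self.cytoplasmic_mean


def dff(
    trace: Trace,
    background: float | np.ndarray = 0.0,
    f0_method: str = "rolling_percentile",
    window: float = 60.0,
    percentile: float = 10.0,
    f0_window: tuple[float, float] = (0.0, 30.0),
) -> Trace:
    """Convert a raw fluorescence trace to ΔF/F₀ = (F − F₀)/F₀.

    F is the background-subtracted fluorescence.  F₀ is either a rolling
    ``percentile`` (default 10th over a 60 s window — robust to sparse
    transients) or the mean over a fixed ``f0_window``.  Raises if F₀ is not
    strictly positive anywhere, which indicates background over-subtraction.
    """
    if trace.role != "fluorescence":
        raise TypeError("dff expects a fluorescence trace")
    f = trace.samples - background
    if f0_method == "rolling_percentile":
        size = max(3, int(round(window / trace.dt)))
        f0 = ndimage.percentile_filter(f, percentile, size=size, mode="nearest")
    elif f0_method == "fixed_window":
        i0, i1 = (trace.index_at(t) for t in f0_window)
        f0 = np.full_like(f, f[i0:max(i1, i0 + 1)].mean())
    else:
        raise ValueError(f"unknown f0_method {f0_method!r}")
    if np.any(f0 <= 0):
        raise ValueError("F0 <= 0: background over-subtraction or empty ROI")
    return Trace((f - f0) / f0, dt=trace.dt, units="dF/F", role="fluorescence",
                 lowpass_cutoff=trace.lowpass_cutoff)


def _population_dff(rois: RoiTraceSet, **dff_kwargs) -> Trace:
    stack = np.stack([dff(t, rois.background, **dff_kwargs).samples for t in rois.traces])
    return Trace(stack.mean(axis=0), dt=rois.traces[0].dt,
                 units="dF/F", role="fluorescence")


def reference_peak(rois: RoiTraceSet, min_prominence: float = 0.05, **dff_kwargs) -> float:
    """Population ΔF/F peak of the first transient after bicuculline.

    Serves as the normaliser for the synchrony criterion.  Raises when the
    marker is missing or no transient follows it.
    """
    if rois.bic_marker is None:
        raise ValueError("RoiTraceSet has no bicuculline segment marker")
    pop = _population_dff(rois, **dff_kwargs).samples
    seg = pop[rois.bic_marker:]
    peaks, props = find_peaks(seg, prominence=min_prominence)
    if peaks.size == 0:
        raise ValueError("no calcium transient found after the bicuculline marker")
    return float(seg[peaks[0]])


def detect_synchronous_events(
    rois: RoiTraceSet,
    reference: float,
    ratio: float = 0.1,
    min_separation: float = 2.0,
    amplitude_mode: str = "population_mean",
    **dff_kwargs,
) -> SynchronyResult:
    """Detect synchronous network calcium events in the unstimulated segment.

    Candidate transients are peaks of the across-ROI mean ΔF/F trace
    (prominence-based, at least ``min_separation`` s apart); a candidate is
    accepted iff its amplitude is ≥ ``ratio`` × ``reference``.  With
    ``amplitude_mode="per_cell_peaks"`` the amplitude is instead the mean of
    per-ROI peaks within ±1 s of the candidate (alternative reading of the
    population-peak criterion).  Frequency is events per minute of the
    unstimulated recording.
    """
    if reference <= 0:
        raise ValueError("reference peak must be positive")
    end = rois.bic_marker if rois.bic_marker is not None else rois.traces[0].n
    dt = rois.traces[0].dt
    if end * dt < 60.0:
        raise ValueError("unstimulated segment shorter than 60 s")
    pop = _population_dff(rois, **dff_kwargs).samples[:end]
    distance = max(1, int(round(min_separation / dt)))
    threshold = ratio * reference
    peaks, _ = find_peaks(pop, prominence=0.5 * threshold, distance=distance)
    if amplitude_mode == "population_mean":
        amps = pop[peaks]
    elif amplitude_mode == "per_cell_peaks":
        half = max(1, int(round(1.0 / dt)))
        per_roi = np.stack([dff(t, rois.background, **dff_kwargs).samples[:end]
                            for t in rois.traces])
        amps = np.array([
            per_roi[:, max(0, p - half):p + half + 1].max(axis=1).mean() for p in peaks
        ])
    else:
        raise ValueError(f"unknown amplitude_mode {amplitude_mode!r}")
    keep = amps >= threshold
    minutes = end * dt / 60.0
    return SynchronyResult(
        event_times=peaks[keep] * dt,
        event_amplitudes=amps[keep],
        frequency_per_min=float(keep.sum() / minutes),
        reference_peak=reference,
        criterion_ratio=ratio,
    )


def write_roi_table(rois: RoiTraceSet, path) -> None:
    """Write ROI traces as tidy columns (time, roi_id, F, background)."""
    import pandas as pd

    dt = rois.traces[0].dt
    n = rois.traces[0].n
    bg = np.broadcast_to(np.asarray(rois.background, float), (n,))
    frames = [pd.DataFrame({"time": np.arange(n) * dt, "roi_id": j,
                            "F": t.samples, "background": bg})
              for j, t in enumerate(rois.traces)]
    header = f"# fps: {1.0 / dt!r}\n# bic_marker: {rois.bic_marker}\n"
    with open(path, "w") as f:
        f.write(header)
        pd.concat(frames).to_csv(f, index=False)


def load_roi_table(path) -> RoiTraceSet:
    """Load a tidy ROI table written by :func:`write_roi_table`."""
    import pandas as pd

    import io

    fps = marker = None
    lines = open(path).read().splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, val = line[1:].partition(":")
        key, val = key.strip(), val.strip()
        if key == "fps":
            fps = float(val)
        elif key == "bic_marker":
            marker = None if val == "None" else int(val)
    table = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    if fps is None:
        raise ValueError(f"{path}: missing '# fps:' header")
    traces = []
    bg = 0.0
    for _, grp in table.groupby("roi_id"):
        traces.append(Trace(grp["F"].to_numpy(), dt=1.0 / fps,
                            units="AU", role="fluorescence"))
        bg = grp["background"].to_numpy()
        if np.all(bg == bg[0]):
            bg = float(bg[0])
    return RoiTraceSet(tuple(traces), background=bg, bic_marker=marker)


def nuc_cyto_ratio(
    image: np.ndarray,
    soma_mask: np.ndarray | None = None,
    soma_dilation_px: int = 12,
) -> CellRatio:
    """Nuclear-to-cytoplasmic mean-intensity ratio of a marker channel.

    ``image`` is a two-channel array ``(2, H, W)``: channel 0 the marker of
    interest, channel 1 the nuclear stain (Hoechst).  The nucleus is defined
    by the nuclear stain: Otsu threshold, holes filled, largest connected
    component.  The cytoplasm is the soma region minus the nucleus; when no
    soma mask is supplied, the soma is approximated by dilating the nucleus
    by ``soma_dilation_px`` pixels.
    """
    from scipy.ndimage import binary_dilation, binary_fill_holes
    from skimage.filters import threshold_otsu
    from skimage.measure import label
    from skimage.morphology import disk

    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("expected a (2, H, W) two-channel image")
    marker, nuc_stain = image[0], image[1]
    mask = nuc_stain > threshold_otsu(nuc_stain)
    mask = binary_fill_holes(mask)
    labels = label(mask)
    if labels.max() == 0:
        raise ValueError("empty nucleus mask")
    mask = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1
    if soma_mask is None:
        soma_mask = binary_dilation(mask, structure=disk(soma_dilation_px))
    cyto = soma_mask & ~mask
    if not cyto.any():
        raise ValueError("empty cytoplasm mask")
    return CellRatio(nuclear_mean=float(marker[mask].mean()),
                     cytoplasmic_mean=float(marker[cyto].mean()))
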