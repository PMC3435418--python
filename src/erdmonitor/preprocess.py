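"""Epoching, detrending, montage selection and the spherical-spline surface
Laplacian.

The canonical preprocessing order is: cut epochs, drop channels outside the
montage, linear detrend, then surface-Laplacian re-reference — channel
removal happens before any signal-processing step so that the Laplacian is
computed on the reduced electrode set only.  Use :func:`preprocess` to get
this order; the individual steps are exposed for testing and custom flows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .containers import ContinuousRecording, EpochSet
from .layout import LAPLACIAN_C3, ElectrodeLayout, MontageSpec, montage_spec

__all__ = [
    "epoch",
    "detrend_linear",
    "select_montage",
    "surface_laplacian",
    "laplacian_operator",
    "hjorth_c3",
    "preprocess",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (-1.5, 6.0)


def epoch(recording: ContinuousRecording, window=DEFAULT_WINDOW) -> EpochSet:
    """Cut one epoch per cue event, relative to cue onset.

    Trials whose window would fall outside the recording are dropped with a
    log entry.  The sample count is exactly ``round(window length × rate)``.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValueError(f"empty epoch window {window}")
    fs = recording.sample_rate_hz
    n_samp = int(round((t1 - t0) * fs))
    times = t0 + np.arange(n_samp) / fs

    cues = recording.cues()
    rows, labels, blocks, seqs = [], [], [], []
    for _, ev in cues.iterrows():
        start = int(round((ev["onset_s"] + t0) * fs))
        stop = start + n_samp
        if start < 0 or stop > recording.n_samples:
            logger.warning(
                "dropping trial (block %s seq %s trial %s): window outside recording",
                ev["block"], ev["sequence"], ev["trial"],
            )
            continue
        rows.append(recording.data[:, start:stop])
        labels.append(ev["condition"])
        blocks.append(ev["block"])
        seqs.append(ev["sequence"])
    if not rows:
        raise ValueError("no epochs could be cut from the recording")
    return EpochSet(
        np.stack(rows), times, recording.labels, np.array(labels),
        np.array(blocks), np.array(seqs), fs,
    )


def detrend_linear(epochs: EpochSet) -> EpochSet:
    """Remove the least-squares line from every channel of every epoch."""
    if epochs.data.shape[-1] < 2:
        raise ValueError("need at least 2 samples per epoch to detrend")
    data = scipy.signal.detrend(epochs.data, axis=-1, type="linear")
    return EpochSet(
        data, epochs.times, epochs.channels, epochs.labels,
        epochs.block, epochs.sequence, epochs.sample_rate_hz,
    )


def select_montage(epochs: EpochSet, montage: str | MontageSpec) -> EpochSet:
    """Keep only the montage's member channels, in the montage's order."""
    if isinstance(montage, str):
        layout_like = type("L", (), {"labels": epochs.channels})  # name resolution only
        spec = montage_spec(montage, layout=layout_like if montage == "all64" else None)
    else:
        spec = montage
    lut = {c: i for i, c in enumerate(epochs.channels)}
    missing = [c for c in spec.members if c not in lut]
    if missing:
        raise ValueError(f"montage {spec.name!r} members missing from data: {missing}")
    idx = [lut[c] for c in spec.members]
    return EpochSet(
        epochs.data[:, idx, :], epochs.times, tuple(spec.members), epochs.labels,
        epochs.block, epochs.sequence, epochs.sample_rate_hz,
    )


# ---------------------------------------------------------------------------
# Spherical-spline surface Laplacian (Perrin et al. 1989 construction)
# ---------------------------------------------------------------------------

def _gh_kernels(cosang: np.ndarray, m: int, n_legendre: int) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the spline kernel g and its surface-Laplacian counterpart h.

    g(x)  =  1/(4π) Σ_n (2n+1) / (n(n+1))^m     P_n(x)
    h(x)  = −1/(4π) Σ_n (2n+1) / (n(n+1))^(m−1) P_n(x)

    h is obtained from g term by term via Δ Y_n = −n(n+1) Y_n on the unit
    sphere.  The series is summed with the Legendre recurrence through
    ``numpy.polynomial.legendre``.
    """
    n = np.arange(1, n_legendre + 1, dtype=float)
    base = (2 * n + 1) / (4 * np.pi)
    cg = np.concatenate([[0.0], base / (n * (n + 1)) ** m])
    ch = np.concatenate([[0.0], -base / (n * (n + 1)) ** (m - 1)])
    x = np.clip(cosang, -1.0, 1.0)
    return (
        np.polynomial.legendre.legval(x, cg),
        np.polynomial.legendre.legval(x, ch),
    )


def laplacian_operator(
    positions: np.ndarray, m: int = 4, n_legendre: int = 50, smoothing: float = 1e-5
) -> np.ndarray:
    """Matrix L such that ``L @ v`` is the spherical-spline surface Laplacian
    of the potentials ``v`` at the electrode sites.

    The spline coefficients solve ``(G + λI) c + d·1 = v`` with ``Σc = 0``
    (λ = *smoothing*); the Laplacian is then ``H c``.  Positions must be
    distinct unit vectors; the Laplacian is in potential units per unit
    solid head radius squared.
    """
    P = np.asarray(positions, dtype=float)
    n_ch = P.shape[0]
    if n_ch < 4:
        raise ValueError("surface Laplacian needs at least 4 electrodes")
    cosang = P @ P.T
    off = cosang - np.eye(n_ch)
    if np.any(off > 1.0 - 1e-10):
        raise ValueError(
            "spline system is rank deficient (duplicate electrode positions)"
        )
    G, H = _gh_kernels(cosang, m, n_legendre)
    A = np.zeros((n_ch + 1, n_ch + 1))
    A[:n_ch, :n_ch] = G + smoothing * np.eye(n_ch)
    A[:n_ch, n_ch] = 1.0
    A[n_ch, :n_ch] = 1.0
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "spline system is rank deficient (duplicate electrode positions?)"
        )
    Ainv = np.linalg.inv(A)
    T = Ainv[:n_ch, :n_ch]  # maps v -> spline coefficients c
    return H @ T


def surface_laplacian(
    epochs: EpochSet,
    layout: ElectrodeLayout,
    m: int = 4,
    n_legendre: int = 50,
    smoothing: float = 1e-5,
) -> EpochSet:
    """Surface-Laplacian re-reference every epoch.

    The operator is built once from the positions of the channels present in
    *epochs* (looked up in *layout*) and applied as a linear map, so the
    transform is linear in the input and invariant to a common reference
    offset across channels.
    """
    sub = layout.subset(epochs.channels)
    L = laplacian_operator(sub.positions, m=m, n_legendre=n_legendre, smoothing=smoothing)
    data = np.einsum("ij,tjs->tis", L, epochs.data)
    return EpochSet(
        data, epochs.times, epochs.channels, epochs.labels,
        epochs.block, epochs.sequence, epochs.sample_rate_hz,
    )


def hjorth_c3(epochs: EpochSet) -> EpochSet:
    """Hjorth-style local Laplacian at C3: C3 minus the mean of its four
    surrounding electrodes.  Provided for comparison with the spline
    derivation."""
    center, *neighbors = LAPLACIAN_C3
    missing = [c for c in LAPLACIAN_C3 if c not in epochs.channels]
    if missing:
        raise ValueError(f"Hjorth C3 needs channels {LAPLACIAN_C3}, missing {missing}")
    x = epochs.channel(center) - np.mean(
        [epochs.channel(c) for c in neighbors], axis=0
    )
    return EpochSet(
        x[:, None, :], epochs.times, (center,), epochs.labels,
        epochs.block, epochs.sequence, epochs.sample_rate_hz,
    )


def preprocess(
    recording: ContinuousRecording,
    layout: ElectrodeLayout,
    montage: str | MontageSpec = "set9",
    window=DEFAULT_WINDOW,
    laplacian: str = "spline",
) -> EpochSet:
    """Canonical pipeline: epoch → montage selection → detrend → Laplacian.

    For the ``laplacianC3`` montage the result is reduced to the single
    derived C3 channel (``laplacian='hjorth'`` switches to the Hjorth
    difference); for every other montage all member channels are returned,
    spline-Laplacian referenced.  ``laplacian='none'`` skips re-referencing.
    """
    name = montage if isinstance(montage, str) else montage.name
    epochs = epoch(recording, window=window)
    epochs = select_montage(epochs, montage)
    epochs = detrend_linear(epochs)
    if laplacian == "none":
        return epochs
    if name == "laplacianC3":
        if laplacian == "hjorth":
            return hjorth_c3(epochs)
        lap = surface_laplacian(epochs, layout)
        return select_montage(lap, MontageSpec("laplacianC3-derived", ("C3",)))
    if laplacian != "spline":
        raise ValueError(f"unknown laplacian option {laplacian!r}")
    return surface_laplacian(epochs, layout)
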