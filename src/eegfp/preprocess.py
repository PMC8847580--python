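"""Signal preprocessing: min-max scaling, Gram-Schmidt orthogonalization,
and the sliding/sampling-window augmentation that turns a recording into
model input tensors.

Pipeline order is normalize -> orthogonalize -> window.  Each channel is
scaled over the full recording; orthogonalization (when enabled) removes the
components of each channel lying in the span of the previously ordered
channels; the sampling window then cuts overlapping eta x T x |C| inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateSignalError,
    InsufficientLengthError,
    ShapeError,
)
from .signal_io import EegRecording

__all__ = [
    "WindowParams",
    "ModelInput",
    "minmax_normalize",
    "orthogonalize",
    "orthogonal_channel_stack",
    "gamma",
    "sliding_segments",
    "enumerate_input_offsets",
    "build_input_array",
    "build_inputs",
]

# relative tolerance for orthogonality assertions (double precision)
ORTHO_RTOL = 1e-8

# relative norm below which an orthogonalized residual is treated as zero
# (an exact duplicate of an earlier channel) and excluded from the basis
_ZERO_RESIDUAL_RTOL = 1e-10


@dataclass(frozen=True)
class WindowParams:
    """Augmentation parameters.

    ``T``: sliding-window length (samples); ``delta``: sliding step;
    ``eta``: number of sliding windows per input; ``Delta``: sampling step
    between consecutive inputs.  The derived per-input signal length is
    ``gamma = (eta - 1) * delta + T``.
    """

    T: int = 160
    delta: int = 4
    eta: int = 20
    Delta: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.delta < self.T):
            raise ShapeError(
                f"sliding step delta={self.delta} must satisfy 0 < delta < T={self.T}"
            )
        if self.eta < 1:
            raise ShapeError(f"eta must be >= 1, got {self.eta}")
        if self.Delta < 1:
            raise ShapeError(f"Delta must be >= 1, got {self.Delta}")

    @property
    def gamma(self) -> int:
        return (self.eta - 1) * self.delta + self.T

    def to_dict(self) -> dict:
        return {"T": self.T, "delta": self.delta,
                "eta": self.eta, "Delta": self.Delta}


@dataclass(frozen=True)
class ModelInput:
    """One eta x T x |C| input tensor with its provenance."""

    data: np.ndarray  # (eta, T, n_channels)
    subject_id: str
    offset: int  # sample offset of the sampling window within the recording


def minmax_normalize(u: np.ndarray) -> np.ndarray:
    """Min-max scale a channel signal to [0, 1].

    Raises :class:`DegenerateSignalError` for constant signals — a flat
    channel carries no information and usually means a broken electrode.
    """
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 1 or u.size < 2:
        raise ShapeError("signal must be a 1-D vector of length >= 2")
    lo = u.min()
    hi = u.max()
    if not hi > lo:
        raise DegenerateSignalError(
            f"constant signal (value {lo!r}) cannot be min-max scaled"
        )
    return (u - lo) / (hi - lo)


def orthogonalize(u_hat: np.ndarray, basis: list[np.ndarray] | tuple) -> np.ndarray:
    """Remove from ``u_hat`` its projections onto each vector of ``basis``.

    ``basis`` must be pairwise orthogonal (built by earlier calls of this
    function); an empty basis returns ``u_hat`` unchanged — the first
    selected channel is never orthogonalized.
    """
    u_hat = np.asarray(u_hat, dtype=np.float64)
    v = u_hat.copy()
    for b in basis:
        b = np.asarray(b, dtype=np.float64)
        if b.shape != u_hat.shape:
            raise ShapeError(
                f"basis vector length {b.shape} != signal length {u_hat.shape}"
            )
        denom = float(b @ b)
        if denom == 0.0:
            raise ZeroDivisionError(
                "zero vector in orthogonal basis (duplicate channel residual?)"
            )
        v -= (float(b @ v) / denom) * b
    return v


def orthogonal_channel_stack(channels: np.ndarray) -> np.ndarray:
    """Sequential Gram-Schmidt over rows of ``channels`` (in row order).

    Residuals whose norm collapses below ``_ZERO_RESIDUAL_RTOL`` of the
    original channel norm (exact duplicates of earlier channels) are kept in
    the output as (near-)zero rows but excluded from the working basis, so
    later channels do not divide by ~0.
    """
    channels = np.asarray(channels, dtype=np.float64)
    out = np.empty_like(channels)
    basis: list[np.ndarray] = []
    for i, row in enumerate(channels):
        res = orthogonalize(row, basis)
        out[i] = res
        norm0 = np.linalg.norm(row)
        if np.linalg.norm(res) > _ZERO_RESIDUAL_RTOL * max(norm0, 1.0):
            basis.append(res)
    return out


def gamma(params: WindowParams) -> int:
    """Per-input signal length: ``(eta - 1) * delta + T`` samples."""
    return params.gamma


def sliding_segments(signal: np.ndarray, params: WindowParams) -> np.ndarray:
    """Cut ``eta`` overlapping ``T``-length segments from the head of ``signal``.

    Row ``r`` is ``signal[r*delta : r*delta + T]``; consecutive rows overlap
    by ``T - delta`` samples.  Returns an ``(eta, T)`` matrix.
    """
    signal = np.asarray(signal, dtype=np.float64)
    g = params.gamma
    if signal.shape[-1] < g:
        raise InsufficientLengthError(
            f"signal of length {signal.shape[-1]} shorter than gamma={g}"
        )
    starts = np.arange(params.eta) * params.delta
    idx = starts[:, None] + np.arange(params.T)[None, :]
    return signal[idx]


def enumerate_input_offsets(n_samples: int, params: WindowParams) -> np.ndarray:
    """Start offsets of every sampling window: 0, Delta, 2*Delta, ...

    while ``offset + gamma <= n_samples``; the count is
    ``floor((n_samples - gamma) / Delta) + 1``.
    """
    g = params.gamma
    if n_samples < g:
        raise InsufficientLengthError(
            f"record of {n_samples} samples shorter than gamma={g}"
        )
    count = (n_samples - g) // params.Delta + 1
    return np.arange(count) * params.Delta


def _processed_channels(recording: EegRecording, channels, orthogonalize_flag,
                        rescale=False) -> np.ndarray:
    stack = np.stack([minmax_normalize(recording.channel(c)) for c in channels])
    if orthogonalize_flag and len(channels) > 1:
        stack = orthogonal_channel_stack(stack)
        if rescale:
            lo = stack.min(axis=1, keepdims=True)
            hi = stack.max(axis=1, keepdims=True)
            span = np.where(hi > lo, hi - lo, 1.0)
            stack = (stack - lo) / span
    return stack


def build_input_array(recording: EegRecording, channels, params: WindowParams,
                      orthogonalize_flag: bool = False,
                      rescale: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized input construction.

    Returns ``(X, offsets)`` where ``X`` has shape
    ``(n_inputs, eta, T, |C|)`` and ``offsets`` gives each input's sampling
    window start.  Channels are min-max scaled over the full recording, then
    (optionally) Gram-Schmidt orthogonalized in the given channel order, then
    windowed.  ``rescale`` re-scales orthogonalized channels back to [0, 1]
    (off by default; the model consumes orthogonalized signals as-is).
    """
    channels = list(channels)
    stack = _processed_channels(recording, channels, orthogonalize_flag, rescale)
    offsets = enumerate_input_offsets(recording.n_samples, params)
    starts = offsets[:, None] + np.arange(params.eta)[None, :] * params.delta
    idx = starts[:, :, None] + np.arange(params.T)[None, None, :]
    # (C, n_inputs, eta, T) -> (n_inputs, eta, T, C)
    X = stack[:, idx].transpose(1, 2, 3, 0)
    return np.ascontiguousarray(X), offsets


def build_inputs(recording: EegRecording, channels, params: WindowParams,
                 orthogonalize_flag: bool = False,
                 rescale: bool = False) -> list[ModelInput]:
    """All augmented inputs of a recording as :class:`ModelInput` objects."""
    X, offsets = build_input_array(
        recording, channels, params, orthogonalize_flag, rescale
    )
    return [
        ModelInput(data=X[i], subject_id=recording.subject_id, offset=int(off))
        for i, off in enumerate(offsets)
    ]
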