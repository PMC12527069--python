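"""Single LSTM cell written gate-by-gate.

This is the textbook four-gate cell with separate weight matrices per
gate:

    i_t = sigmoid(W_i x_t + W_hi h_{t-1} + b_i)      (input gate)
    f_t = sigmoid(W_f x_t + W_fi h_{t-1} + b_f)      (forget gate)
    o_t = sigmoid(W_o x_t + W_oi h_{t-1} + b_o)      (output gate)
    g_t = tanh   (W_c x_t + W_hc h_{t-1} + b_c)      (candidate state)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

It exists as an executable statement of the recurrence and as the
independent second route against the fused batched implementation in
:mod:`ecgkit.nn.layers`; the two share no code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._exceptions import ValidationError


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LSTMCellWeights:
    """Per-gate weights: ``W_*`` act on the input, ``W_h*``/``W_*i`` on the
    previous hidden state.  Shapes: input matrices (H, F), recurrent
    matrices (H, H), biases (H,)."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    W_hi: np.ndarray
    W_fi: np.ndarray
    W_oi: np.ndarray
    W_hc: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        H, F = np.shape(self.W_i)
        for name in ("W_f", "W_o", "W_c"):
            if np.shape(getattr(self, name)) != (H, F):
                raise ValidationError(f"{name} must have shape {(H, F)}")
        for name in ("W_hi", "W_fi", "W_oi", "W_hc"):
            if np.shape(getattr(self, name)) != (H, H):
                raise ValidationError(f"{name} must have shape {(H, H)}")
        for name in ("b_i", "b_f", "b_o", "b_c"):
            if np.shape(getattr(self, name)) != (H,):
                raise ValidationError(f"{name} must have shape {(H,)}")

    @property
    def hidden_size(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_i.shape[1]

    @classmethod
    def random(cls, input_size: int, hidden_size: int, rng: np.random.Generator,
               scale: float = 0.5) -> "LSTMCellWeights":
        def m(r, c):
            return rng.normal(0.0, scale, size=(r, c))
        H, F = hidden_size, input_size
        return cls(
            W_i=m(H, F), W_f=m(H, F), W_o=m(H, F), W_c=m(H, F),
            W_hi=m(H, H), W_fi=m(H, H), W_oi=m(H, H), W_hc=m(H, H),
            b_i=rng.normal(0, scale, H), b_f=rng.normal(0, scale, H),
            b_o=rng.normal(0, scale, H), b_c=rng.normal(0, scale, H),
        )


def lstm_cell_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, w: LSTMCellWeights
) -> tuple[np.ndarray, np.ndarray]:
    """One recurrence step; returns ``(h_t, c_t)``."""
    x_t = np.asarray(x_t, dtype=float).ravel()
    h_prev = np.asarray(h_prev, dtype=float).ravel()
    c_prev = np.asarray(c_prev, dtype=float).ravel()
    H = w.hidden_size
    if x_t.size != w.input_size or h_prev.size != H or c_prev.size != H:
        raise ValidationError(
            f"shape mismatch: x {x_t.size} (want {w.input_size}), "
            f"h {h_prev.size}, c {c_prev.size} (want {H})"
        )
    i_t = _sigmoid(w.W_i @ x_t + w.W_hi @ h_prev + w.b_i)
    f_t = _sigmoid(w.W_f @ x_t + w.W_fi @ h_prev + w.b_f)
    o_t = _sigmoid(w.W_o @ x_t + w.W_oi @ h_prev + w.b_o)
    g_t = np.tanh(w.W_c @ x_t + w.W_hc @ h_prev + w.b_c)
    c_t = f_t * c_prev + i_t * g_t
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


def fused_from_cell(w: LSTMCellWeights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack per-gate matrices into the fused (W, U, b) layout of
    :class:`ecgkit.nn.layers.LSTM` (gate order i, f, g, o; W is (F, 4H))."""
    W = np.concatenate([w.W_i, w.W_f, w.W_c, w.W_o], axis=0).T
    U = np.concatenate([w.W_hi, w.W_fi, w.W_hc, w.W_oi], axis=0).T
    b = np.concatenate([w.b_i, w.b_f, w.b_c, w.b_o])
    return W, U, b


def cell_from_fused(W: np.ndarray, U: np.ndarray, b: np.ndarray) -> LSTMCellWeights:
    """Inverse of :func:`fused_from_cell`."""
    H = W.shape[1] // 4
    Wi, Wf, Wc, Wo = (W.T[k * H:(k + 1) * H] for k in range(4))
    Ui, Uf, Uc, Uo = (U.T[k * H:(k + 1) * H] for k in range(4))
    bi, bf, bc, bo = (b[k * H:(k + 1) * H] for k in range(4))
    return LSTMCellWeights(
        W_i=Wi, W_f=Wf, W_o=Wo, W_c=Wc,
        W_hi=Ui, W_fi=Uf, W_oi=Uo, W_hc=Uc,
        b_i=bi, b_f=bf, b_o=bo, b_c=bc,
    )
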