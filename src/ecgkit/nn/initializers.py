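"""He-normal (Kaiming) initialization for the network layer set."""

from __future__ import annotations

import math

import numpy as np

from .layers import Conv1d, Dense, LSTM, Sequential


def kaiming_init(net: Sequential, seed: int) -> Sequential:
    """Draw every weight matrix from N(0, 2/fan_in) and zero the biases.

    fan_in is the number of inputs feeding one unit: channels x kernel taps
    for convolutions, input features for dense layers, and the source
    dimensionality for each LSTM weight block (input size for W, hidden
    size for the recurrent U).  The draw order is fixed by layer position,
    so a given seed always produces identical weights.
    """
    rng = np.random.default_rng(seed)
    for layer in net.layers:
        if isinstance(layer, (Conv1d, Dense)):
            sd = math.sqrt(2.0 / layer.fan_in)
            w = layer.params["W"]
            w[...] = rng.normal(0.0, sd, size=w.shape)
            layer.params["b"][...] = 0.0
        elif isinstance(layer, LSTM):
            sd_w = math.sqrt(2.0 / layer.input_size)
            sd_u = math.sqrt(2.0 / layer.hidden_size)
            layer.params["W"][...] = rng.normal(0.0, sd_w, size=layer.params["W"].shape)
            layer.params["U"][...] = rng.normal(0.0, sd_u, size=layer.params["U"].shape)
            layer.params["b"][...] = 0.0
    return net
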