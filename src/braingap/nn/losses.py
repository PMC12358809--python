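"""Loss functions returning (scalar loss, gradient w.r.t. the model output)."""

from __future__ import annotations

import numpy as np


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch for integer class labels."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    return float(loss), (d / n).astype(np.float32)


def mae(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error for a 1-output regression head."""
    pred = pred.reshape(-1)
    r = pred - np.asarray(y, dtype=np.float32)
    loss = float(np.abs(r).mean())
    d = (np.sign(r) / r.size).astype(np.float32)
    return loss, d.reshape(-1, 1)
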