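"""Gradient-weighted class activation maps for the CNN-LSTM.

The map is computed at a time-distributed convolution layer (by default
the first conv of the penultimate conv block): channel weights are the
spatial means of the class-logit gradient per frame, the weighted
activation sum is rectified, normalized to [0, 1] over the whole video and
bilinearly upsampled to the requested output size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = ["GradCAMMap", "grad_cam"]


@dataclass
class GradCAMMap:
    """Per-frame heatmaps, upsampled; values in [0, 1], global max 1
    (or all-zero when every gradient is rectified away)."""

    maps: np.ndarray          # (T, out_px, out_px)
    target_layer: str
    class_index: int


def grad_cam(
    model,
    video: np.ndarray,
    class_index: int = 1,
    target_layer: str | None = None,
    out_px: int = 101,
) -> GradCAMMap:
    """Grad-CAM heatmaps of one video, shape (T, H, W, C) matching the model.

    The gradient of the chosen class logit is taken with respect to the
    target layer's activations; dropout is inactive (evaluation mode).
    """
    name = target_layer or model.spec.penultimate_conv1
    layer = model.layer(name)  # raises LayerNotFoundError if absent
    layer.capture = True
    try:
        logits = model.forward_logits(video[None].astype(np.float32), train=False)
        dlogits = np.zeros_like(logits)
        dlogits[0, class_index] = 1.0
        model.backward_from_logits(dlogits)
        acts = layer.last_output          # (T, h, w, ch)
        grads = layer.last_output_grad
    finally:
        layer.capture = False
        layer.last_output = None
        layer.last_output_grad = None
    weights = grads.mean(axis=(1, 2))     # (T, ch)
    cam = np.maximum(
        (acts * weights[:, None, None, :]).sum(axis=-1), 0.0
    )
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    maps = np.stack(
        [
            resize(frame, (out_px, out_px), order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
            for frame in cam
        ]
    )
    if peak > 0:
        top = maps.max()
        if top > 0:
            maps = maps / top
    return GradCAMMap(maps=maps.astype(np.float32), target_layer=name,
                      class_index=class_index)
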