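"""Convolutional architecture construction and shape arithmetic.

All three pipeline arrangements share a frame-wise convolutional classifier
operating on a fixed-width spectrogram window (112 frequency rows):

* three sets of [convolution, CCCP pooling, 2x2 stride-2 max-pool] with 16
  channels each (filter sizes 5x5, 5x5, 4x4); a CCCP (cascaded cross-channel
  parametric pooling) layer is a 1x1 convolution acting as a learned
  cross-channel activation;
* a fourth convolutional layer with 240 channels whose 11x9 filter collapses
  the remaining frequency rows and covers roughly one note (the 9-frame width
  is exactly what reduces a 96-frame input window to a single output frame);
* for the wide-window arrangement, an additional convolutional layer whose
  temporal width (25) reduces the fourth layer's output on a 288-frame window
  to a single frame, letting the network integrate syntax context spanning
  about three successive notes;
* a 1x1 softmax convolution producing the output classes.

The narrow window is 96 frames; with 1-ms frames and a 16-ms analysis window
that is a 111-ms receptive field. The wide window is 288 frames (303 ms).
Output count is the number of note classes n for the boundary-detection-first
arrangement and 3n+1 (three sub-divisions per class plus silence) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .signal_features import SpectrogramParams

__all__ = ["LayerSpec", "ArchitectureSpec", "build_architecture",
           "receptive_field_ms", "ARRANGEMENTS"]

ARRANGEMENTS = ("BD_LC_GS", "LC_BDGS", "LCGS_BDGS")

NARROW_WINDOW = 96
WIDE_WINDOW = 288


class UnknownArrangementError(ValueError):
    pass


class InvalidArchitectureError(ValueError):
    pass


@dataclass(frozen=True)
class LayerSpec:
    kind: Literal["convolution", "cccp", "maxpool", "softmax_convolution"]
    channels: int = 0  # 0 for maxpool
    filter_height: int = 1
    filter_width: int = 1
    stride: tuple[int, int] = (1, 1)
    activation: Literal["relu", "softmax", "none"] = "none"
    inserted: bool = False  # wide-window syntax-integration layer

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        if self.kind == "maxpool":
            return h // 2, w // 2
        oh = h - self.filter_height + 1
        ow = w - self.filter_width + 1
        if oh <= 0 or ow <= 0:
            raise InvalidArchitectureError(
                f"filter {self.filter_height}x{self.filter_width} exceeds input {h}x{w}"
            )
        return oh, ow


def _conv(ch, hf, wf, act="relu", **kw):
    return LayerSpec("convolution", ch, hf, wf, activation=act, **kw)


def _cccp(ch):
    return LayerSpec("cccp", ch, 1, 1, activation="relu")


def _pool():
    return LayerSpec("maxpool", 0, 2, 2, stride=(2, 2))


@dataclass(frozen=True)
class ArchitectureSpec:
    arrangement: str
    input_height: int
    input_width: int
    n_note_classes: int
    layers: tuple[LayerSpec, ...]
    n_outputs: int

    def __post_init__(self) -> None:
        h, w = self.shape_trace()[-1]
        if (h, w) != (1, 1):
            raise InvalidArchitectureError(
                f"layers compose to {h}x{w}, not 1x1, on "
                f"{self.input_height}x{self.input_width} input"
            )

    def shape_trace(self, height: int | None = None,
                    width: int | None = None) -> list[tuple[int, int]]:
        """Spatial (rows, frames) shape after each layer."""
        h = self.input_height if height is None else height
        w = self.input_width if width is None else width
        trace = [(h, w)]
        for layer in self.layers:
            h, w = layer.out_shape(h, w)
            trace.append((h, w))
        return trace

    @property
    def temporal_stride(self) -> int:
        s = 1
        for layer in self.layers:
            if layer.kind == "maxpool":
                s *= layer.stride[1]
        return s

    @property
    def center_offset(self) -> int:
        """Index of the labeled frame within the input window."""
        return self.input_width // 2


def build_architecture(arrangement: str, n_note_classes: int,
                       input_height: int = 112) -> ArchitectureSpec:
    """Construct the layer stack for one of the three arrangements.

    The fourth convolution's filter height and width are derived from the
    shape trace: the height collapses all remaining frequency rows and the
    width is whatever reduces a narrow (96-frame) window to one output frame.
    For the wide-window arrangement an extra layer is inserted whose width
    reduces the remaining 288-frame trace to one frame.
    """
    if arrangement not in ARRANGEMENTS:
        raise UnknownArrangementError(arrangement)
    if n_note_classes < 2:
        raise ValueError("need at least 2 note classes")
    n = n_note_classes

    sets = [
        _conv(16, 5, 5), _cccp(16), _pool(),
        _conv(16, 5, 5), _cccp(16), _pool(),
        _conv(16, 4, 4), _cccp(16), _pool(),
    ]
    h, w = input_height, NARROW_WINDOW
    for layer in sets:
        h, w = layer.out_shape(h, w)
    conv4 = _conv(240, h, w)  # 11 x 9 at defaults

    if arrangement == "BD_LC_GS":
        n_outputs, input_width, extra = n, NARROW_WINDOW, []
    elif arrangement == "LC_BDGS":
        n_outputs, input_width, extra = 3 * n + 1, NARROW_WINDOW, []
    else:  # LCGS_BDGS
        n_outputs, input_width = 3 * n + 1, WIDE_WINDOW
        hw, ww = input_height, WIDE_WINDOW
        for layer in sets + [conv4]:
            hw, ww = layer.out_shape(hw, ww)
        extra = [_conv(240, 1, ww, inserted=True)]  # width 25 at defaults

    layers = tuple(
        sets + [conv4] + extra
        + [LayerSpec("softmax_convolution", n_outputs, 1, 1, activation="softmax")]
    )
    return ArchitectureSpec(
        arrangement=arrangement,
        input_height=input_height,
        input_width=input_width,
        n_note_classes=n,
        layers=layers,
        n_outputs=n_outputs,
    )


def receptive_field_ms(window_frames: int,
                       params: SpectrogramParams | None = None) -> float:
    """Duration of audio seen by one input window.

    ``window_frames - 1`` hops plus one analysis window: 111 ms for 96 frames
    and 303 ms for 288 frames at the default 32 kHz / 512 / 32 parameters.
    """
    params = params or SpectrogramParams()
    return (window_frames - 1) * params.frame_ms + params.fft_size / params.sample_rate * 1000.0
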