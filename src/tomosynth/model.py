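"""The hybrid 2.5D encoder-decoder mapping projection patch-stacks to
per-pixel tissue-class probabilities over a sagittal slice.

The encoder runs strided 3x3x3 convolutions over the (view, row, column)
stack, shrinking the view and strip axes into channels while downsampling
rows toward the output row resolution.  A row-wise dense bottleneck turns
each encoder row feature vector into that row's seed block of the 2D
(row, depth) decoder, which then upsamples to the output slice.  Adaptive
skip connections flatten the view/width axes of matching-row encoder
features into channels, project them with a 1x1 (dense) adapter and
broadcast them along the synthesized depth axis.  A final per-pixel linear
head + softmax yields air/soft/bone probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .nn import ConvNd, Dense, ReLU, Upsample2d, softmax, softmax_backward


def _ceil_div(n: int, s: int) -> int:
    return -(-n // s)


@dataclass(frozen=True)
class ModelConfig:
    input_shape: tuple = (60, 2048, 31)          # (views, rows, strip width)
    output_shape: tuple = (512, 512)             # (rows_out, depth_out)
    encoder_channels: tuple = (8, 16, 24, 32, 48, 64)
    encoder_strides: tuple = ((2, 2, 2), (2, 2, 2), (2, 2, 2),
                              (2, 2, 2), (2, 2, 2), (2, 2, 1))
    decoder_channels: tuple = (48, 32, 24, 16)
    seed_channels: int = 8
    input_offset: float = 1.0                    # fixed affine input normalization
    input_scale: float = 1.0
    param_budget: int = 1_300_000

    def __post_init__(self):
        if len(self.encoder_channels) != len(self.encoder_strides):
            raise ValueError("one stride tuple per encoder stage")
        rows_out, depth_out = self.output_shape
        kd = len(self.decoder_channels)
        seed_rows = rows_out // 2**kd
        if seed_rows * 2**kd != rows_out or depth_out % 2**kd:
            raise ValueError("output shape must be divisible by 2**n_decoder_stages")
        if self.encoder_shapes()[-1][2] != seed_rows:
            raise ValueError(
                f"encoder stride schedule yields {self.encoder_shapes()[-1][2]} rows, "
                f"but the decoder seed needs {seed_rows}")

    def encoder_shapes(self) -> list:
        """(C, V, R, W) after each encoder stage (input stage excluded)."""
        v, r, w = self.input_shape
        shapes = []
        for c, (sv, sr, sw) in zip(self.encoder_channels, self.encoder_strides):
            v, r, w = _ceil_div(v, sv), _ceil_div(r, sr), _ceil_div(w, sw)
            shapes.append((c, v, r, w))
        return shapes

    @property
    def seed_shape(self) -> tuple:
        kd = len(self.decoder_channels)
        return (self.seed_channels, self.output_shape[0] // 2**kd,
                self.output_shape[1] // 2**kd)

    def skip_sources(self) -> list:
        """For each decoder stage, the encoder stage index feeding its skip
        (rows must match the decoder stage's output rows), or None."""
        enc = self.encoder_shapes()
        out = []
        kd = len(self.decoder_channels)
        for j in range(kd):
            target_rows = self.output_shape[0] // 2**kd * 2 ** (j + 1)
            match = None
            for i, (_, _, r, _) in enumerate(enc):
                if r == target_rows:
                    match = i
            out.append(match)
        return out


def audit_parameter_count(cfg: ModelConfig) -> int:
    """Independent arithmetic audit of the trainable parameter count:
    kernel volume x in x out + biases per layer, summed from the config
    alone (no arrays are instantiated)."""
    total = 0
    in_ch = 1
    for out_ch in cfg.encoder_channels:
        total += 27 * in_ch * out_ch + out_ch
        in_ch = out_ch
    c_f, v_f, _, w_f = cfg.encoder_shapes()[-1]
    seed_ch, _, seed_depth = cfg.seed_shape
    total += (c_f * v_f * w_f) * (seed_ch * seed_depth) + seed_ch * seed_depth
    enc = cfg.encoder_shapes()
    in_ch = seed_ch
    for out_ch, src in zip(cfg.decoder_channels, cfg.skip_sources()):
        total += 9 * in_ch * out_ch + out_ch
        if src is not None:
            c, v, _, w = enc[src]
            total += (c * v * w) * out_ch + out_ch
        in_ch = out_ch
    total += in_ch * 3 + 3          # per-pixel linear head
    return total


@dataclass
class SlicePrediction:
    """(rows_out, depth_out, 3) per-pixel class probabilities."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs)
        if self.probs.ndim != 3 or self.probs.shape[-1] != 3:
            raise ValueError("probs must be (rows, depth, 3)")
        sums = self.probs.sum(axis=-1)
        if np.any(self.probs < 0) or np.any(np.abs(sums - 1) > 1e-5):
            raise ValueError("probabilities must be a per-pixel simplex")


class SliceSegmenter:
    """Forward/backward network over one sagittal slice's patch stack."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
        self.encoder = []
        in_ch = 1
        for i, (out_ch, stride) in enumerate(zip(cfg.encoder_channels, cfg.encoder_strides)):
            self.encoder.append((ConvNd(rng, in_ch, out_ch, stride, 3, f"enc{i}"), ReLU()))
            in_ch = out_ch
        c_f, v_f, _, w_f = cfg.encoder_shapes()[-1]
        seed_ch, _, seed_depth = cfg.seed_shape
        self.bottleneck = Dense(rng, c_f * v_f * w_f, seed_ch * seed_depth, "bottleneck")
        enc_shapes = cfg.encoder_shapes()
        self.decoder, self.skips = [], []
        in_ch = seed_ch
        for j, (out_ch, src) in enumerate(zip(cfg.decoder_channels, cfg.skip_sources())):
            self.decoder.append((Upsample2d(), ConvNd(rng, in_ch, out_ch, (1, 1), 2, f"dec{j}"),
                                 ReLU()))
            if src is not None:
                c, v, _, w = enc_shapes[src]
                self.skips.append((src, Dense(rng, c * v * w, out_ch, f"skip{j}")))
            else:
                self.skips.append((None, None))
            in_ch = out_ch
        self.head = Dense(rng, in_ch, 3, "head")
        self._cache = None
        self._enc_grads: dict = {}

    # -- parameters ----------------------------------------------------------

    @property
    def params(self) -> list:
        ps = []
        for conv, _ in self.encoder:
            ps += conv.params
        ps += self.bottleneck.params
        for (_, conv, _), (src, adapter) in zip(self.decoder, self.skips):
            ps += conv.params
            if adapter is not None:
                ps += adapter.params
        ps += self.head.params
        return ps

    def num_parameters(self) -> int:
        return sum(p.size for p in self.params)

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, views, rows, width) -> probs (B, rows_out, depth_out, 3)."""
        cfg = self.cfg
        if x.shape[1:] != tuple(cfg.input_shape):
            raise ValueError(f"input shape {x.shape[1:]} != {cfg.input_shape}")
        h = ((np.asarray(x, dtype=np.float64) - cfg.input_offset)
             / cfg.input_scale)[:, None]                      # (B,1,V,R,W)
        enc_feats = []
        for conv, act in self.encoder:
            h = act.forward(conv.forward(h))
            enc_feats.append(h)
        B = h.shape[0]
        seed_ch, seed_rows, seed_depth = cfg.seed_shape
        rowvec = np.moveaxis(h, 3, 1).reshape(B, seed_rows, -1)   # (B,R,C*V*W)
        seed = self.bottleneck.forward(rowvec)                    # (B,R,seed_ch*seed_depth)
        d = np.moveaxis(seed.reshape(B, seed_rows, seed_ch, seed_depth), 2, 1)
        skip_caches = []
        for (up, conv, act), (src, adapter) in zip(self.decoder, self.skips):
            d = conv.forward(up.forward(d))
            if adapter is not None:
                e = enc_feats[src]                                # (B,C,V,R,W)
                rv = np.moveaxis(e, 3, 1).reshape(B, e.shape[3], -1)
                s = adapter.forward(rv)                           # (B,R,Cout)
                d = d + np.moveaxis(s, 2, 1)[..., None]           # broadcast over depth
                skip_caches.append(e.shape)
            else:
                skip_caches.append(None)
            d = act.forward(d)
        feat = np.moveaxis(d, 1, -1)                              # (B,Ro,Do,C)
        logits = self.head.forward(feat)
        probs = softmax(logits, axis=-1)
        self._cache = (probs, skip_caches, B)
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/dprobs."""
        probs, skip_caches, B = self._cache
        dlogits = softmax_backward(probs, dprobs, axis=-1)
        dfeat = self.head.backward(dlogits)
        d = np.moveaxis(dfeat, -1, 1)
        for (up, conv, act), (src, adapter), eshape in zip(
                reversed(self.decoder), reversed(self.skips), reversed(skip_caches)):
            d = act.backward(d)
            if adapter is not None:
                ds = d.sum(axis=-1)                               # (B,C,R)
                drv = adapter.backward(np.moveaxis(ds, 1, 2))     # (B,R,C*V*W)
                c, v, r, w = eshape[1], eshape[2], eshape[3], eshape[4]
                de = np.moveaxis(drv.reshape(B, r, c, v, w), 1, 3)
                self._enc_grad_inject(src, de)
            d = up.backward(conv.backward(d))
        seed_ch, seed_rows, seed_depth = self.cfg.seed_shape
        dseed = np.moveaxis(d, 1, 2).reshape(B, seed_rows, seed_ch * seed_depth)
        drow = self.bottleneck.backward(dseed)
        c_f, v_f, _, w_f = self.cfg.encoder_shapes()[-1]
        dh = np.moveaxis(drow.reshape(B, seed_rows, c_f, v_f, w_f), 1, 3)
        # walk the encoder backwards, adding any injected skip gradients
        for i in range(len(self.encoder) - 1, -1, -1):
            conv, act = self.encoder[i]
            dh = dh + self._enc_grads.pop(i, 0.0)
            dh = conv.backward(act.backward(dh))
        self._enc_grads = {}

    def _enc_grad_inject(self, stage: int, grad: np.ndarray) -> None:
        self._enc_grads[stage] = self._enc_grads.get(stage, 0.0) + grad

    # -- inference -----------------------------------------------------------

    def predict_slice(self, patch_values: np.ndarray) -> SlicePrediction:
        """Deterministic inference for one patch stack (views, rows, width)."""
        probs = self.forward(np.asarray(patch_values)[None])
        return SlicePrediction(probs[0])


def build_model(cfg: ModelConfig, seed: int = 0) -> SliceSegmenter:
    model = SliceSegmenter(cfg, seed=seed)
    actual = model.num_parameters()
    if actual > cfg.param_budget:
        raise ValueError(f"model has {actual} parameters, exceeding the declared "
                         f"budget {cfg.param_budget}")
    return model


def save_checkpoint(model: SliceSegmenter, path, extra: dict | None = None) -> None:
    """Self-describing checkpoint: weights + embedded config (npz)."""
    arrays = {f"param_{i}_{p.name}": p.value for i, p in enumerate(model.params)}
    meta = {"config": asdict(model.cfg)}
    if extra:
        meta["extra"] = extra
    arrays["meta_yaml"] = np.frombuffer(
        yaml.safe_dump(_plain(meta)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> SliceSegmenter:
    with np.load(path) as data:
        meta = yaml.safe_load(bytes(data["meta_yaml"]).decode())
        cfg_d = meta["config"]
        for key in ("input_shape", "output_shape", "encoder_channels",
                    "decoder_channels"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg_d["encoder_strides"] = tuple(tuple(s) for s in cfg_d["encoder_strides"])
        cfg = ModelConfig(**cfg_d)
        model = SliceSegmenter(cfg, seed=0)
        for i, p in enumerate(model.params):
            p.value[...] = data[f"param_{i}_{p.name}"]
    return model


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
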