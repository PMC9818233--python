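"""Residual-network classifier (18-layer layout, 2-class head).

The basic residual block computes y = sigma(F(x) + shortcut(x)), where F
is two 3x3 convolutions with batch normalization and a ReLU between.  The
identity shortcut adds no parameters and requires equal input/output
shapes; when the dimensions change (first block of stages 2+, stride 2)
the shortcut is either a learned 1x1 projection W_s x (default) or a
parameter-free stride-2 subsampling with zero-padded channels.

The full 18-layer spec is the paper-scale default (7x7/2 stem with 64
filters, 3x3/2 max-pool, four stages of two blocks with 64/128/256/512
filters, global average pooling, fully connected softmax head).  A
reduced "tiny" spec (16-filter stem, two stages, 64x64 input) ships for
desk-scale end-to-end training on CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2d,
    Param,
    ReLU,
    Sequential,
    softmax,
)


class PretrainedWeightsUnavailable(RuntimeError):
    pass


@dataclass(frozen=True)
class ResidualBlockSpec:
    input_channels: int
    output_channels: int
    stride: int = 1
    shortcut: str = "identity"  # identity | projection | pad

    def __post_init__(self) -> None:
        if self.shortcut == "identity" and (
            self.input_channels != self.output_channels or self.stride != 1
        ):
            raise ValueError(
                "identity shortcut requires equal input/output dimensions; "
                f"got {self.input_channels}->{self.output_channels} stride {self.stride}"
            )
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")


@dataclass(frozen=True)
class ResNetSpec:
    """Layer-by-layer architecture description."""

    stem_channels: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_pool: bool = True            # 3x3 max-pool stride 2 after the stem
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    num_classes: int = 2
    input_hw: tuple[int, int] = (224, 224)
    shortcut_mode: str = "projection"  # projection | pad for dimension changes
    norm_passthrough: bool = False     # identity norms, for algebraic tests

    def block_specs(self) -> list[ResidualBlockSpec]:
        specs = []
        cin = self.stem_channels
        for si, cout in enumerate(self.stage_channels):
            for bi in range(self.blocks_per_stage):
                stride = 2 if (si > 0 and bi == 0) else 1
                if cin == cout and stride == 1:
                    shortcut = "identity"
                else:
                    shortcut = self.shortcut_mode
                specs.append(ResidualBlockSpec(cin, cout, stride, shortcut))
                cin = cout
        return specs


def resnet18_spec(num_classes: int = 2) -> ResNetSpec:
    return ResNetSpec(num_classes=num_classes)


def resnet_tiny_spec(num_classes: int = 2) -> ResNetSpec:
    """Desk-scale variant: 16-filter stem, stages (16, 32), 64x64 input."""
    return ResNetSpec(
        stem_channels=16,
        stage_channels=(16, 32),
        input_hw=(64, 64),
        num_classes=num_classes,
    )


class _PadShortcut(Layer):
    """Parameter-free dimension increase: stride-s subsample + zero channels."""

    def __init__(self, cin: int, cout: int, stride: int) -> None:
        self.cin, self.cout, self.stride = cin, cout, stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        y = x[:, :, :: self.stride, :: self.stride]
        pad = self.cout - self.cin
        return np.pad(y, ((0, 0), (0, pad), (0, 0), (0, 0)))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._shape)
        gx[:, :, :: self.stride, :: self.stride] = gy[:, : self.cin]
        return gx


class _Identity(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy


class BasicBlock(Layer):
    """y = sigma(F(x, {W_i}) + shortcut(x)); F = conv-bn-relu-conv-bn."""

    def __init__(
        self,
        spec: ResidualBlockSpec,
        rng: np.random.Generator,
        norm_passthrough: bool = False,
        name: str = "block",
    ) -> None:
        self.spec = spec
        cin, cout, s = spec.input_channels, spec.output_channels, spec.stride
        self.conv1 = Conv2d(cin, cout, 3, stride=s, padding=1, rng=rng, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(cout, passthrough=norm_passthrough, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, padding=1, rng=rng, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(cout, passthrough=norm_passthrough, name=f"{name}.bn2")
        if spec.shortcut == "identity":
            self.shortcut: Layer = _Identity()
        elif spec.shortcut == "projection":
            self.shortcut = Sequential(
                Conv2d(cin, cout, 1, stride=s, rng=rng, name=f"{name}.proj"),
                BatchNorm2d(cout, passthrough=norm_passthrough, name=f"{name}.proj_bn"),
            )
        elif spec.shortcut == "pad":
            self.shortcut = _PadShortcut(cin, cout, s)
        else:
            raise ValueError(f"unknown shortcut kind {spec.shortcut!r}")
        self.relu_out = ReLU()

    def params(self) -> list[Param]:
        out = (
            self.conv1.params() + self.bn1.params()
            + self.conv2.params() + self.bn2.params()
        )
        return out + self.shortcut.params()

    def children(self) -> list[Layer]:
        return [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2,
                self.shortcut, self.relu_out]

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for l in (self.bn1, self.bn2, self.shortcut):
            l.set_training(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected {self.spec.input_channels} channels, got {x.shape[1]}"
            )
        f = self.bn2.forward(self.conv2.forward(
            self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        ))
        s = self.shortcut.forward(x)
        if f.shape != s.shape:
            raise ValueError(
                f"residual branch {f.shape} and shortcut {s.shape} dimensions differ; "
                "identity shortcuts require equal input/output shapes"
            )
        return self.relu_out.forward(f + s)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gy)
        gf = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(g)))
        ))
        gs = self.shortcut.backward(g)
        return gf + gs


class ResNetModel(Layer):
    """Trainable realization of a ResNetSpec; maps RGB images to logits."""

    def __init__(self, spec: ResNetSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        stem_pad = spec.stem_kernel // 2
        stem: list[Layer] = [
            Conv2d(3, spec.stem_channels, spec.stem_kernel, stride=spec.stem_stride,
                   padding=stem_pad, rng=rng, name="stem"),
            BatchNorm2d(spec.stem_channels, passthrough=spec.norm_passthrough, name="stem_bn"),
            ReLU(),
        ]
        if spec.stem_pool:
            stem.append(MaxPool2d(3, stride=2, padding=1))
        blocks = [
            BasicBlock(bs, rng, spec.norm_passthrough, name=f"block{i}")
            for i, bs in enumerate(spec.block_specs())
        ]
        self.backbone = Sequential(*stem, *blocks)
        self.pool = GlobalAvgPool()
        self.head = Linear(spec.stage_channels[-1], spec.num_classes, rng=rng, name="head")

    # -- Layer protocol -------------------------------------------------
    def params(self) -> list[Param]:
        return self.backbone.params() + self.head.params()

    def children(self) -> list[Layer]:
        return [self.backbone, self.pool, self.head]

    def batchnorms(self) -> list[BatchNorm2d]:
        from .layers import iter_layers

        return [l for l in iter_layers(self) if isinstance(l, BatchNorm2d)]

    def recalibrate_batchnorm(self, images: np.ndarray, batch_size: int = 64) -> None:
        """Precise-BN: recompute running statistics with forward passes over
        ``images`` at the current weights (training-mode normalization)."""
        bns = self.batchnorms()
        if not bns:
            return
        self.set_training(True)
        for bn in bns:
            bn.begin_stat_accumulation()
        for i in range(0, images.shape[0], batch_size):
            self.forward(images[i : i + batch_size])
        for bn in bns:
            bn.finalize_stat_accumulation()

    def capture_state(self) -> list[np.ndarray]:
        """Snapshot of all weights plus batch-norm running statistics."""
        out = [p.value.copy() for p in self.params()]
        for bn in self.batchnorms():
            out += [bn.running_mean.copy(), bn.running_var.copy()]
        return out

    def restore_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state):
            p.value[...] = v
        rest = state[len(ps) :]
        for bn, (m, v) in zip(self.batchnorms(), zip(rest[0::2], rest[1::2])):
            bn.running_mean = m.copy()
            bn.running_var = v.copy()

    def backbone_params(self) -> list[Param]:
        return self.backbone.params()

    def set_training(self, mode: bool) -> None:
        self.training = mode
        self.backbone.set_training(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.backbone.forward(np.asarray(x, dtype=np.float64))
        return self.head.forward(self.pool.forward(h))

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        return self.backbone.backward(
            self.pool.backward(self.head.backward(glogits))
        )

    # -- inference ------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities (N, num_classes); rows sum to 1."""
        self.set_training(False)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return np.argmax(self.predict_proba(x, batch_size), axis=1)

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{i}:{p.name}": p.value for i, p in enumerate(self.params())}

    def load_state(self, arrays: list[np.ndarray]) -> None:
        ps = self.params()
        if len(arrays) != len(ps):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model has {len(ps)}")
        for p, a in zip(ps, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch for {p.name}: {p.value.shape} vs {a.shape}")
            p.value[...] = a


def build_model(
    spec: ResNetSpec,
    pretrained_backbone: bool = False,
    seed: int = 0,
    backbone_weights: str | None = None,
) -> ResNetModel:
    """Build a model; optionally load externally supplied backbone weights.

    The classification head is always randomly initialized.  Requesting a
    pretrained backbone without supplying a weights file raises
    PretrainedWeightsUnavailable.
    """
    model = ResNetModel(spec, seed=seed)
    if pretrained_backbone:
        if backbone_weights is None:
            raise PretrainedWeightsUnavailable(
                "no backbone weights file supplied; for offline operation build "
                "with pretrained_backbone=False, or pass backbone_weights="
                "<path to a checkpoint with matching backbone layout>"
            )
        with np.load(backbone_weights) as z:
            arrays = [z[k] for k in sorted(z.files, key=lambda k: int(k.split(":")[0]))]
        bps = model.backbone_params()
        if len(arrays) < len(bps):
            raise ValueError("backbone weights file has too few arrays")
        for p, a in zip(bps, arrays):
            if p.value.shape != a.shape:
                raise ValueError(
                    f"backbone weight shape mismatch for {p.name}: "
                    f"{p.value.shape} vs {a.shape}"
                )
            p.value[...] = a
    return model


def save_checkpoint(model: ResNetModel, path: str) -> None:
    """Single-file container: spec + weights + init seed."""
    meta = json.dumps({"spec": asdict(model.spec), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path: str) -> ResNetModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        spec_d = meta["spec"]
        spec_d["stage_channels"] = tuple(spec_d["stage_channels"])
        spec_d["input_hw"] = tuple(spec_d["input_hw"])
        spec = ResNetSpec(**spec_d)
        model = ResNetModel(spec, seed=meta["seed"])
        keys = [k for k in z.files if k != "__meta__"]
        arrays = [z[k] for k in sorted(keys, key=lambda k: int(k.split(":")[0]))]
        model.load_state(arrays)
    return model
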