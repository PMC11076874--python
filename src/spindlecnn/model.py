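"""The spindle classifier: a five-block 1-D CNN for 3 s, 100 Hz windows.

Architecture (input 1 × 300): five Conv→BatchNorm→ReLU blocks with average
pooling (size 2, stride 2) after blocks 2 and 4, so the temporal grid is
downsampled by exactly 4 (300 → 150 → 75) before a two-layer fully-connected
head (hidden ReLU layer, then a 2-way softmax). Blocks 1–2 extract local
oscillatory features, blocks 3–4 compose them at half resolution, block 5
abstracts once more, and the head classifies spindle vs non-spindle. The
softmax spindle-class probability (index 1) is the score used for ROC/AUC.

Channel counts, kernel sizes and head width are configurable through
:class:`CNNSpec`; the defaults (16, 16, 32, 32, 64 channels, kernels
7, 7, 5, 5, 3, hidden 64) train in minutes on one CPU at ~10⁴ windows.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn

__all__ = ["CNNSpec", "TrainedModel", "build_model", "forward",
           "save_model", "load_model"]

N_BLOCKS = 5
POOL_AFTER = (2, 4)


@dataclass(frozen=True)
class CNNSpec:
    """Architecture description; fully determines all parameter shapes."""

    channels: tuple[int, ...] = (16, 16, 32, 32, 64)
    kernels: tuple[int, ...] = (7, 7, 5, 5, 3)
    pool_after: tuple[int, ...] = POOL_AFTER
    hidden: int = 64
    n_classes: int = 2
    input_len: int = 300
    in_channels: int = 1

    def __post_init__(self) -> None:
        if len(self.channels) != N_BLOCKS or len(self.kernels) != N_BLOCKS:
            raise ValueError(f"exactly {N_BLOCKS} conv blocks required")
        if tuple(self.pool_after) != POOL_AFTER:
            raise ValueError(f"pooling stages must follow blocks {POOL_AFTER}")
        if self.input_len % 4 != 0:
            raise ValueError("input_len must be divisible by 4 (two 2x pools)")
        if any(k % 2 == 0 for k in self.kernels):
            raise ValueError("kernel sizes must be odd")

    @property
    def flat_features(self) -> int:
        return self.channels[-1] * (self.input_len // 4)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CNNSpec":
        d = json.loads(s)
        for key in ("channels", "kernels", "pool_after"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrainedModel:
    """A (possibly trained) network plus its spec and provenance."""

    spec: CNNSpec
    net: nn.Network
    provenance: dict = field(default_factory=dict)

    def conv_block_layers(self, block: int) -> list[str]:
        """Layer names making up conv block ``block`` (1-based)."""
        if not 1 <= block <= N_BLOCKS:
            raise ValueError(f"block must be in 1..{N_BLOCKS}")
        return [f"conv{block}", f"bn{block}"]

    def head_layers(self) -> list[str]:
        return ["fc1", "fc2"]

    def state(self) -> dict[str, np.ndarray]:
        return self.net.state()


def build_model(spec: CNNSpec, seed: int) -> TrainedModel:
    """Initialize the network deterministically from ``seed``."""
    rng = np.random.default_rng(seed)
    layers: list[tuple[str, nn.Layer]] = []
    in_ch = spec.in_channels
    for b, (out_ch, k) in enumerate(zip(spec.channels, spec.kernels), start=1):
        layers.append((f"conv{b}", nn.Conv1d(in_ch, out_ch, k, rng)))
        layers.append((f"bn{b}", nn.BatchNorm1d(out_ch)))
        layers.append((f"relu{b}", nn.ReLU()))
        if b in spec.pool_after:
            layers.append((f"pool{b}", nn.AvgPool1d()))
        in_ch = out_ch
    layers.append(("flatten", nn.Flatten()))
    layers.append(("fc1", nn.Linear(spec.flat_features, spec.hidden, rng)))
    layers.append(("relu_fc", nn.ReLU()))
    layers.append(("fc2", nn.Linear(spec.hidden, spec.n_classes, rng)))
    return TrainedModel(spec=spec, net=nn.Network(layers),
                        provenance={"init_seed": int(seed)})


def forward(model: TrainedModel, batch: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch, in evaluation mode.

    Accepts (n, input_len) or (n, 1, input_len); returns (n, n_classes) rows
    summing to 1. The spindle probability is column 1.
    """
    x = np.asarray(batch, dtype=np.float32)
    if x.ndim == 2:
        x = x[:, None, :]
    if x.ndim != 3 or x.shape[1] != model.spec.in_channels:
        raise ValueError("batch must be (n, 1, input_len)")
    if x.shape[2] != model.spec.input_len:
        raise ValueError(
            f"window length {x.shape[2]} does not match the expected "
            f"{model.spec.input_len} samples"
        )
    logits = model.net.forward(x, training=False)
    return nn.softmax(logits.astype(np.float64))


def save_model(model: TrainedModel, path) -> None:
    """Single-archive container: spec + provenance as JSON, parameters as
    named arrays addressable by ``layer.param``."""
    state = {f"param::{k}": v for k, v in model.net.state().items()}
    np.savez(
        path,
        spec_json=np.array(model.spec.to_json()),
        provenance_json=np.array(json.dumps(model.provenance)),
        **state,
    )


def load_model(path, expected_spec: CNNSpec | None = None) -> TrainedModel:
    """Load a saved model; rejects archives whose spec mismatches
    ``expected_spec`` and corrupted/foreign files."""
    try:
        with np.load(path, allow_pickle=False) as archive:
            spec = CNNSpec.from_json(str(archive["spec_json"]))
            provenance = json.loads(str(archive["provenance_json"]))
            state = {
                k.removeprefix("param::"): archive[k]
                for k in archive.files
                if k.startswith("param::")
            }
    except (KeyError, ValueError, OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"not a valid model archive: {path} ({exc})") from exc
    if expected_spec is not None and spec != expected_spec:
        raise ValueError(
            f"archive spec {spec} incompatible with expected {expected_spec}"
        )
    model = build_model(spec, seed=0)
    model.net.load_state(state)
    model.provenance = provenance
    return model
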