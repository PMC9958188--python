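"""Single-file model checkpoints: weights + config + versioned header."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..errors import ScoringShapeError
from .models import NetworkConfig, ScoringModel, build_3dcnn, build_4dcnn

FORMAT_VERSION = 1


def save_checkpoint(model: ScoringModel, path: str | Path) -> None:
    header = {
        "format_version": FORMAT_VERSION,
        "kind": model.kind,
        "config": model.config.to_dict(),
    }
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    with open(path, "wb") as fh:  # avoid np.savez's implicit .npz suffix
        np.savez(
            fh,
            __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            **arrays,
        )


def load_checkpoint(path: str | Path) -> ScoringModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]).decode())
        if header.get("format_version") != FORMAT_VERSION:
            raise ScoringShapeError(
                f"unsupported checkpoint format {header.get('format_version')}"
            )
        config = NetworkConfig.from_dict(header["config"])
        builder = build_4dcnn if header["kind"] == "4d" else build_3dcnn
        model = builder(config)
        state = {
            k[len("state/"):]: npz[k] for k in npz.files if k.startswith("state/")
        }
    model.load_state_dict(state)
    return model
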