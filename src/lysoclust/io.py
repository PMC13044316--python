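"""TIFF/CSV/config input-output.

Label masks are written as 16-bit TIFF (erroring rather than overflowing),
intensity images as 32-bit float, stacks as multi-page TIFF in plane order.
Run configuration is a flat-ish YAML document mirroring the CLI flags 1:1;
unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    return tifffile.imread(str(path))


def write_image(path: str | Path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.floating):
        out = image.astype(np.float32)
    else:
        if image.min() < 0 or image.max() > np.iinfo(np.uint16).max:
            raise ValueError(
                f"label/intensity values outside uint16 range: "
                f"[{image.min()}, {image.max()}]")
        out = image.astype(np.uint16)
    tifffile.imwrite(str(path), out)


def write_label_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("label mask must be integer-typed")
    write_image(path, mask)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips through YAML."""

    presets: list[dict] = field(default_factory=lambda: [
        {"name": "dispersed", "condition": "control"},
        {"name": "clustered", "condition": "treated"},
    ])
    n_cells: int = 30
    experiments: int = 3
    cells_per_scene: int = 4
    seed: int = 0
    out_dir: str = "lysoclust_run"
    min_radius: float = 3.0
    max_radius: float = 6.0
    expand_px: int = 1
    test: str = "anova-tukey"
    control: str | None = None
    stats_level: str = "cell"
    log_level: str = "INFO"
    write_images: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
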