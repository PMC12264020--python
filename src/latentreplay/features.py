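"""Optional real-data boundary: image folders + a pluggable extractor.

The continual-learning pipeline operates entirely on latent vectors.  For
real data, a frozen backbone turns each cell image into one such vector;
this module defines that plug-in contract without shipping any backbone.
An extractor is any callable mapping an (H, W, 3) uint8 array (images are
resized to 256 x 256 before the call) to a 1-d feature vector of fixed
length.  Labels come from class subdirectory names, sorted, so the layout
is the usual  root/<class_name>/*.{png,jpg}.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np

from .datasets import LatentDataset, ValidationError

IMAGE_SIZE = (256, 256)
_EXTENSIONS = {".png", ".jpg", ".jpeg"}


def extract_features(
    image_dir: str | Path,
    extractor: Callable[[np.ndarray], np.ndarray],
    domain_id: str | None = None,
) -> LatentDataset:
    """Run a frozen extractor over a class-per-subdirectory image folder."""
    try:
        from PIL import Image
    except ImportError as exc:  # pragma: no cover
        raise ImportError("image mode requires pillow") from exc

    image_dir = Path(image_dir)
    class_dirs = sorted(d for d in image_dir.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValidationError(f"{image_dir}: no class subdirectories")
    rows, labels = [], []
    dim: int | None = None
    for cls_idx, cls_dir in enumerate(class_dirs):
        for img_path in sorted(cls_dir.iterdir()):
            if img_path.suffix.lower() not in _EXTENSIONS:
                continue
            img = Image.open(img_path).convert("RGB").resize(IMAGE_SIZE)
            vec = np.asarray(extractor(np.asarray(img)), dtype=float).ravel()
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ValidationError(
                    f"extractor output dimension changed: {vec.size} != {dim} "
                    f"at {img_path}"
                )
            rows.append(vec)
            labels.append(cls_idx)
    if not rows:
        raise ValidationError(f"{image_dir}: no images found")
    return LatentDataset(
        domain_id or image_dir.name, "train", np.vstack(rows), np.array(labels)
    )
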