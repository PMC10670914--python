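"""Pluggable feature-extraction interface.

Real embedding extraction needs a pretrained CNN backbone and its
weights, which this package deliberately does not ship.  An adapter is
any callable mapping an image path to a 1-D feature vector; this module
only handles the folder layout ``root/<class_name>/<file>.png|jpg`` and
assembles the resulting :class:`~swarmlayer.data.FeatureTable`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .data import FeatureTable

__all__ = ["extract", "IMAGE_SUFFIXES"]

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def extract(
    image_folder,
    adapter: Callable[[Path], Sequence[float]],
    class_names: Sequence[str] = ("normal", "oscc"),
) -> FeatureTable:
    """Build a feature table from ``root/<class_name>/<image>`` folders.

    ``class_names`` orders the labels: the first name maps to label 0
    (Normal), the second to label 1 (the positive class).  ``adapter``
    is called once per image and must return a fixed-length vector.
    """
    root = Path(image_folder)
    if len(class_names) != 2:
        raise ValueError("exactly two class names are required")
    rows, labels = [], []
    for label, name in enumerate(class_names):
        folder = root / name
        if not folder.is_dir():
            raise FileNotFoundError(f"class folder not found: {folder}")
        for img in sorted(folder.iterdir()):
            if img.suffix.lower() in IMAGE_SUFFIXES:
                rows.append(np.asarray(adapter(img), dtype=float))
                labels.append(label)
    if not rows:
        raise ValueError(f"no images found under {root}")
    dims = {len(r) for r in rows}
    if len(dims) != 1:
        raise ValueError(f"adapter returned inconsistent dimensions: {sorted(dims)}")
    return FeatureTable(np.vstack(rows), np.asarray(labels))
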