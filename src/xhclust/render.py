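"""Label-map export: plain-text PGM grids and false-color PNG renderings."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .cluster import ClusterMap
from .errors import FormatError

__all__ = ["save_label_pgm", "load_label_pgm", "render_cluster_map", "PALETTE"]

# deterministic palette indexed by cluster id (1-based); 0 (unlabelled) is black
PALETTE = np.array([
    (0, 0, 0),        # unlabelled / masked
    (31, 119, 180),   # 1
    (255, 127, 14),   # 2
    (44, 160, 44),    # 3
    (214, 39, 40),    # 4
    (148, 103, 189),  # 5
    (140, 86, 75),    # 6
    (227, 119, 194),  # 7
    (127, 127, 127),  # 8
    (188, 189, 34),   # 9
    (23, 190, 207),   # 10
], dtype=np.uint8)


def save_label_pgm(cluster_map: ClusterMap, path) -> None:
    """Write a label grid as ASCII PGM (P2); 0 marks unlabelled pixels."""
    labels = cluster_map.labels
    rows, cols = labels.shape
    maxval = max(int(labels.max()), 1)
    lines = [f"P2", f"# xhclust labels k={cluster_map.k} image={cluster_map.image_id}",
             f"{cols} {rows}", f"{maxval}"]
    lines.extend(" ".join(str(v) for v in row) for row in labels)
    Path(path).write_text("\n".join(lines) + "\n")


def load_label_pgm(path) -> ClusterMap:
    tokens: list[str] = []
    k = None
    image_id = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            for part in line[1:].split():
                if part.startswith("k="):
                    k = int(part[2:])
                if part.startswith("image="):
                    image_id = part[6:]
            continue
        tokens.extend(line.split())
    if not tokens or tokens[0] != "P2":
        raise FormatError("not an ASCII PGM (P2) label map")
    cols, rows = int(tokens[1]), int(tokens[2])
    values = np.array(tokens[4:4 + rows * cols], dtype=np.int32).reshape(rows, cols)
    return ClusterMap(labels=values, k=k if k is not None else int(values.max()),
                      image_id=image_id)


def render_cluster_map(cluster_map: ClusterMap, path=None) -> np.ndarray:
    """False-color the label grid with the fixed palette; optionally save PNG."""
    labels = np.asarray(cluster_map.labels)
    idx = np.clip(labels, 0, len(PALETTE) - 1)
    rgb = PALETTE[idx]
    if path is not None:
        Image.fromarray(rgb, mode="RGB").save(Path(path))
    return rgb
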