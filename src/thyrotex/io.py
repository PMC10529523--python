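"""On-disk dataset layout for synthetic phantoms.

Each nodule is stored as a 16-bit grayscale PNG image, an 8-bit 0/255
nodule mask PNG, and an 8-bit label-mask PNG (0 background / 128 solid /
255 cystic), alongside ``truth.csv`` (nodule_id, cystic_fraction_true,
pixel_spacing_mm) and the resolved run configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import LABEL_CYSTIC, LABEL_SOLID, SyntheticNodule

__all__ = ["write_dataset", "read_dataset", "read_mask_png", "write_mask_png"]

_LABEL_TO_PNG = {0: 0, LABEL_SOLID: 128, LABEL_CYSTIC: 255}


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


def write_dataset(nodules: Sequence[SyntheticNodule], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for nodule in nodules:
        stem = nodule.nodule_id
        iio.imwrite(
            out / f"{stem}_image.png",
            np.round(np.clip(nodule.image, 0, 1) * 65535).astype(np.uint16),
        )
        write_mask_png(out / f"{stem}_mask.png", nodule.nodule_mask)
        labels_png = np.zeros(nodule.label_mask.shape, dtype=np.uint8)
        for lab, val in _LABEL_TO_PNG.items():
            labels_png[nodule.label_mask == lab] = val
        iio.imwrite(out / f"{stem}_labels.png", labels_png)
        rows.append(
            {
                "nodule_id": stem,
                "cystic_fraction_true": nodule.cystic_fraction_true,
                "pixel_spacing_mm": nodule.pixel_spacing_mm,
            }
        )
    pd.DataFrame(rows).to_csv(out / "truth.csv", index=False)
    return out


def read_dataset(in_dir: str | Path) -> list[SyntheticNodule]:
    in_dir = Path(in_dir)
    truth = pd.read_csv(in_dir / "truth.csv")
    nodules = []
    for row in truth.itertuples():
        stem = row.nodule_id
        image = np.asarray(iio.imread(in_dir / f"{stem}_image.png"), float) / 65535.0
        mask = read_mask_png(in_dir / f"{stem}_mask.png")
        labels_png = np.asarray(iio.imread(in_dir / f"{stem}_labels.png"))
        label_mask = np.zeros(labels_png.shape, dtype=np.uint8)
        label_mask[labels_png == 128] = LABEL_SOLID
        label_mask[labels_png == 255] = LABEL_CYSTIC
        nodules.append(
            SyntheticNodule(
                image=image,
                pixel_spacing_mm=float(row.pixel_spacing_mm),
                nodule_mask=mask,
                label_mask=label_mask,
                cystic_fraction_true=float(row.cystic_fraction_true),
                nodule_id=str(stem),
            )
        )
    return nodules
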