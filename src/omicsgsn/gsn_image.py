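"""Gene-similarity-network (GSN) images: template fitting and RGB rendering.

The 2-D gene embedding is frozen into a pixel template: each gene gets a
center pixel and a circular zone of fixed radius.  A sample is rendered by
filling each gene's zone with the sample's three omic values for that gene
— red = gene expression, green = DNA methylation, blue = CNA — each scaled
to 0..255.  Pixels outside every zone keep the background color, so a
sample contributes no color beyond the zone radius around a gene site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .io_preprocess import MultiOmicsDataset, ValidationError


@dataclass
class GSNTemplate:
    """Fixed gene positions and zone radius within a width x height canvas."""

    width: int
    height: int
    gene_ids: list[str]
    gene_centers: np.ndarray  # (n_genes, 2) float (row, col)
    radius: float
    background: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.gene_centers = np.asarray(self.gene_centers, dtype=float)
        if self.gene_centers.shape != (len(self.gene_ids), 2):
            raise ValidationError("gene_centers shape does not match gene_ids")
        r, c = self.gene_centers[:, 0], self.gene_centers[:, 1]
        if ((r < self.radius) | (r > self.height - self.radius)).any() or (
            (c < self.radius) | (c > self.width - self.radius)
        ).any():
            raise ValidationError("a gene center lies closer than `radius` to the border")

    def zone_masks(self) -> np.ndarray:
        """Boolean (n_genes, height, width): pixels within each gene's zone."""
        rr, cc = np.mgrid[0 : self.height, 0 : self.width]
        d2 = (
            (rr[None] - self.gene_centers[:, 0, None, None]) ** 2
            + (cc[None] - self.gene_centers[:, 1, None, None]) ** 2
        )
        return d2 <= self.radius**2

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "width": self.width,
            "height": self.height,
            "radius": self.radius,
            "background": list(self.background),
            "genes": {
                g: [float(r), float(c)]
                for g, (r, c) in zip(self.gene_ids, self.gene_centers)
            },
            "gene_order": self.gene_ids,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GSNTemplate":
        d = json.loads(Path(path).read_text())
        order = d["gene_order"]
        return cls(
            width=d["width"], height=d["height"], gene_ids=list(order),
            gene_centers=np.array([d["genes"][g] for g in order], dtype=float),
            radius=d["radius"], background=tuple(d["background"]),
        )


@dataclass
class RGBImage:
    """height x width x 3 uint8 image; R=expression, G=methylation, B=CNA."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("pixels must be (height, width, 3)")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValidationError("channel intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    def save_png(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path, format="PNG")


def fit_template(
    embedding,
    width: int = 64,
    height: int = 64,
    radius: float = 4.0,
    margin: float = 2.0,
    background: tuple[int, int, int] = (0, 0, 0),
) -> GSNTemplate:
    """Affinely map embedding coordinates into the pixel rectangle.

    The map preserves aspect ratio (one isotropic scale), centers the
    layout inside the rectangle inset by ``radius + margin`` on every
    side, and is invariant to translations of the embedding.  Embedding x
    maps to pixel column, embedding y to pixel row.  A degenerate layout
    (single gene, or all genes coincident) maps to the image center.
    """
    inset = radius + margin
    if width <= 2 * inset or height <= 2 * inset:
        raise ValidationError("image too small for the requested radius and margin")
    coords = np.asarray(embedding.coords, dtype=float)
    if coords.shape[0] < 1:
        raise ValidationError("need at least one gene")
    x, y = coords[:, 0], coords[:, 1]
    extent_x = x.max() - x.min()
    extent_y = y.max() - y.min()
    span_c = width - 2 * inset
    span_r = height - 2 * inset
    if extent_x == 0 and extent_y == 0:
        centers = np.tile([height / 2.0, width / 2.0], (coords.shape[0], 1))
    else:
        scale = min(
            span_c / extent_x if extent_x > 0 else np.inf,
            span_r / extent_y if extent_y > 0 else np.inf,
        )
        cols = (x - (x.min() + x.max()) / 2.0) * scale + width / 2.0
        rows = (y - (y.min() + y.max()) / 2.0) * scale + height / 2.0
        centers = np.column_stack([rows, cols])
    return GSNTemplate(
        width=width, height=height, gene_ids=list(embedding.point_ids),
        gene_centers=centers, radius=radius, background=background,
    )


def render_sample(
    template: GSNTemplate,
    expr_vals: np.ndarray,
    meth_vals: np.ndarray,
    cna_vals: np.ndarray,
    blend: str = "max",
) -> RGBImage:
    """Paint each gene zone with the sample's three omic values.

    Channel intensity is ``round(255 * value)``; overlapping zones combine
    channel-wise per ``blend`` ("max" or "mean"); pixels outside all zones
    take the template background.
    """
    vals = np.stack([
        np.asarray(expr_vals, float),
        np.asarray(meth_vals, float),
        np.asarray(cna_vals, float),
    ], axis=1)  # (n_genes, 3)
    if vals.shape[0] != len(template.gene_ids):
        raise ValidationError("value vectors do not match the template gene count")
    if not np.isfinite(vals).all() or (vals < 0).any() or (vals > 1).any():
        raise ValidationError("omic values must lie in [0, 1]")
    if blend not in ("max", "mean"):
        raise ValidationError(f"unknown blend mode {blend!r}")

    masks = template.zone_masks()  # (g, h, w)
    intensities = np.rint(255.0 * vals)  # (g, 3)
    h, w = template.height, template.width
    covered = masks.any(axis=0)
    if blend == "max":
        layered = masks[..., None] * intensities[:, None, None, :]
        img = layered.max(axis=0)
    else:
        total = (masks[..., None] * intensities[:, None, None, :]).sum(axis=0)
        count = masks.sum(axis=0)[..., None]
        img = np.divide(total, count, out=np.zeros((h, w, 3)), where=count > 0)
        img = np.rint(img)
    bg = np.array(template.background, dtype=float)
    img = np.where(covered[..., None], img, bg[None, None, :])
    return RGBImage(pixels=img.astype(np.uint8))


def render_dataset(
    dataset: MultiOmicsDataset,
    template: GSNTemplate,
    blend: str = "max",
    out_dir: str | Path | None = None,
) -> list[tuple[str, RGBImage]]:
    """Render one RGB image per sample, optionally writing PNGs + a manifest.

    Rendering is deterministic; re-running writes byte-identical PNGs.
    """
    if dataset.gene_ids != template.gene_ids:
        raise ValidationError("dataset genes do not match the template")
    images: list[tuple[str, RGBImage]] = []
    for j, sid in enumerate(dataset.sample_ids):
        img = render_sample(
            template,
            dataset.expression.values[:, j],
            dataset.methylation.values[:, j],
            dataset.cna.values[:, j],
            blend=blend,
        )
        images.append((sid, img))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for sid, img in images:
            fname = f"{sid}.png"
            try:
                img.save_png(out / fname)
            except OSError as exc:
                raise OSError(f"failed writing image for sample {sid}: {exc}") from exc
            manifest.append({
                "sample_id": sid,
                "file": fname,
                "label": int(dataset.labels[sid]),
                "class": dataset.class_names[dataset.labels[sid]],
            })
        (out / "manifest.json").write_text(json.dumps({
            "blend": blend,
            "width": template.width,
            "height": template.height,
            "radius": template.radius,
            "samples": manifest,
        }, indent=1))
    return images


def image_stack(images: list[tuple[str, RGBImage]]) -> tuple[list[str], np.ndarray]:
    """Stack rendered images into (sample_ids, float array scaled to [0, 1])."""
    ids = [sid for sid, _ in images]
    arr = np.stack([img.pixels for _, img in images]).astype(np.float64) / 255.0
    return ids, arr
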