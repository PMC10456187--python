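"""Prototype export for AU-conditioned renderers, plus a stub renderer.

A prototype leaves the package as two self-describing text artifacts: the
prototype JSON (catalog, dominant, complementary, threshold, binary
vector, provenance) and a flat AU-activation CSV (``au_id,intensity`` for
every catalog AU — the prototype's active AUs at the export intensity, all
others at 0.0), which an adapter for any AU-conditioned generative
renderer can translate into its own dialect.

The stub renderer draws a deterministic schematic (one labeled glyph per
active AU on a fixed canvas) so the end-to-end pipeline can be smoke-tested
without a GAN; nothing upstream ever depends on its output.  An adapter to
a real renderer (pretrained generator plus face cropping/alignment) is an
optional plugin outside the tested surface.
"""

from __future__ import annotations

import csv
from pathlib import Path

from PIL import Image, ImageDraw

from .catalog import StimulusVector
from .estimate import MentalPrototype

__all__ = ["export_prototype", "read_activation_csv", "stub_render"]


def export_prototype(
    prototype: MentalPrototype, intensity: float, path: str | Path
) -> tuple[Path, Path]:
    """Write ``<path>.json`` and ``<path>.csv``; returns both paths.

    ``intensity`` in (0, 1] is applied to every active AU (activation is
    binary upstream; intensity is purely an export-time rendering knob).
    """
    if not 0.0 < intensity <= 1.0:
        raise ValueError(f"intensity must be in (0, 1], got {intensity}")
    if not prototype.active_ids:
        raise ValueError("prototype has an empty active set; nothing to export")
    base = Path(path)
    json_path = base.with_suffix(".json")
    csv_path = base.with_suffix(".csv")
    prototype.to_json(json_path)
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["au_id", "intensity"])
        for au in prototype.catalog.au_ids:
            writer.writerow([au, intensity if au in prototype.active_ids else 0.0])
    return json_path, csv_path


def read_activation_csv(path: str | Path) -> dict[int, float]:
    """au_id → intensity mapping from an exported activation CSV."""
    out: dict[int, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["au_id", "intensity"]:
            raise ValueError(f"expected header [au_id, intensity], got {header}")
        for row in reader:
            out[int(row[0])] = float(row[1])
    return out


_CANVAS = (320, 320)
_GRID = 4


def stub_render(vector: StimulusVector, path: str | Path) -> Path:
    """Deterministic schematic render: one labeled glyph per active AU.

    Byte-stable for identical input (fixed canvas, no timestamps); suitable
    only for pipeline smoke tests, never for perception.
    """
    img = Image.new("RGB", _CANVAS, "white")
    draw = ImageDraw.Draw(img)
    draw.rectangle([4, 4, _CANVAS[0] - 5, _CANVAS[1] - 5], outline="black")
    cell = _CANVAS[0] // _GRID
    for slot, au in enumerate(sorted(vector.active_ids)):
        row, col = divmod(slot, _GRID)
        x, y = 10 + col * cell, 10 + row * cell
        draw.ellipse([x, y, x + cell - 24, y + cell - 24], outline="black", width=2)
        draw.text((x + 8, y + 24), f"AU{au}", fill="black")
    out = Path(path)
    img.save(out, format="PNG")
    return out
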