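"""GeoJSON exchange for named polygon sets (protected areas, regions)."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from shapely.geometry import mapping, shape

from .errors import FormatError

logger = logging.getLogger(__name__)


def write_protected_areas(polygons, path: str | Path) -> None:
    """Write ``[(name, Polygon), ...]`` as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": mapping(poly),
        }
        for name, poly in polygons
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_protected_areas(path: str | Path) -> list[tuple[str, object]]:
    """Read a FeatureCollection of (Multi)Polygons into ``[(name, geom), ...]``.

    Invalid geometries are skipped with a logged warning rather than
    aborting the overlay.
    """
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for i, feature in enumerate(payload.get("features", [])):
        name = str(feature.get("properties", {}).get("name", f"feature_{i}"))
        try:
            geom = shape(feature["geometry"])
        except Exception as exc:  # malformed geometry dict
            logger.warning("skipping %s: unreadable geometry (%s)", name, exc)
            continue
        if geom.is_empty or not geom.is_valid:
            logger.warning("skipping %s: invalid or empty geometry", name)
            continue
        out.append((name, geom))
    return out
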