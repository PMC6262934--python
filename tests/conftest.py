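import numpy as np
import pandas as pd
import pytest

from orchidatlas.synth import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A small but fully featured study system: all contamination types,
    a reserve network, and two speciose genera with narrow rainfall niches."""
    return SyntheticConfig(
        seed=7,
        extent=(0.0, 0.0, 20.0, 20.0),
        raster_cellsize=0.5,
        n_genera=8,
        species_per_genus=(4, 12),
        records_per_species=(4, 40),
        n_narrow_ap_genera=2,
        n_protected_areas=12,
        protected_fraction_target=0.2,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_frame(small_dataset) -> pd.DataFrame:
    """Cleaned occurrence table of the small dataset."""
    from orchidatlas.cleaning import apply_filters, frame_to_records, records_to_frame

    records = frame_to_records(small_dataset.occurrences)
    clean, _ = apply_filters(records, small_dataset.config.country)
    return records_to_frame(clean)


def make_frame(rows: list[dict]) -> pd.DataFrame:
    """Occurrence frame from partial row dicts, defaults filled in."""
    from orchidatlas.synth import OCCURRENCE_COLUMNS

    defaults = {
        "record_id": None,
        "scientificName": "Genus01 species001",
        "genus": "Genus01",
        "family": "Orchidaceae",
        "decimalLatitude": 1.0,
        "decimalLongitude": 1.0,
        "country": "Australia",
        "cultivated": 0,
        "hybrid": 0,
        "establishmentMeans": "native",
    }
    full = []
    for i, row in enumerate(rows):
        d = dict(defaults, record_id=f"r{i:04d}")
        d.update(row)
        full.append(d)
    return pd.DataFrame(full, columns=OCCURRENCE_COLUMNS)
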