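"""Layout serialization: element CSV plus a YAML sidecar of metadata."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .geometry import Condition, ElementSpec, StimulusLayout


def save_layout(layout: StimulusLayout, csv_path: str | Path) -> None:
    """Write elements as CSV and condition/seed metadata as a .yaml sidecar."""
    csv_path = Path(csv_path)
    rows = [
        {
            "element_id": i,
            "role": e.role,
            "x_deg": e.x_deg,
            "y_deg": e.y_deg,
            "orientation_deg": e.orientation_deg,
        }
        for i, e in enumerate(layout.elements)
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    meta = {
        "eccentricity_deg": layout.condition.eccentricity_deg,
        "spacing_deg": layout.condition.spacing_deg,
        "wiggle_deg": layout.condition.wiggle_deg,
        "side": layout.side,
        "grass_pitch_deg": layout.grass_pitch_deg,
        "rng_seed": layout.rng_seed,
        "radial_tolerance_deg": layout.radial_tolerance_deg,
    }
    csv_path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_layout(csv_path: str | Path) -> StimulusLayout:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = yaml.safe_load(csv_path.with_suffix(".yaml").read_text())
    elements = [
        ElementSpec(r.x_deg, r.y_deg, r.orientation_deg, r.role)
        for r in df.itertuples()
    ]
    return StimulusLayout(
        condition=Condition(
            meta["eccentricity_deg"], meta["spacing_deg"], meta["wiggle_deg"]
        ),
        side=meta["side"],
        elements=elements,
        grass_pitch_deg=meta["grass_pitch_deg"],
        rng_seed=meta["rng_seed"],
        radial_tolerance_deg=meta.get("radial_tolerance_deg", 0.0),
    )
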