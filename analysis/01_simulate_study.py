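#!/usr/bin/env python
"""Generate the synthetic survey and describe what it contains.

Writes the city footprints as GeoJSON and a per-city summary table
(area, covariates, observation count, true melanism fraction).
"""

import json

import shapely

from _common import get_study, outdir


def main() -> None:
    study = get_study()
    out = outdir()

    features = []
    for land in study.landscapes:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "city_id": land.city_id,
                    "area_ha": round(land.area_ha, 1),
                    "forest_pct": round(land.forest_pct, 2),
                    "winter_temp": round(land.winter_temp, 2),
                },
                "geometry": json.loads(shapely.to_geojson(land.footprint, indent=None)),
            }
        )
    (out / "footprints.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )

    per_city = (
        study.observations.groupby("city_id")
        .agg(n_obs=("obs_id", "size"), melanic_fraction=("melanic", "mean"))
        .reset_index()
    )
    per_city.to_csv(out / "simulated_per_city.csv", index=False)

    n = len(study.observations)
    print(f"Simulated {n} observations across {len(study.landscapes)} cities")
    print(
        f"per-city counts: median {int(per_city.n_obs.median())}, "
        f"range {per_city.n_obs.min()}-{per_city.n_obs.max()}"
    )
    print(
        f"overall melanism fraction: {study.observations.melanic.mean():.3f}; "
        f"vote records: {len(study.votes)} rows over {len(study.images)} images"
    )
    print(f"wrote {out / 'footprints.geojson'} and simulated_per_city.csv")


if __name__ == "__main__":
    main()
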