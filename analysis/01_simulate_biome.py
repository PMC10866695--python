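#!/usr/bin/env python
"""Generate the default synthetic biome and write its layers + ground truth.

Produces the 10^5-pixel rainfall-conditioned tree-cover field, the
disturbance layers (droughts, roads, protection, deforestation) and the
1981-2020 climate cubes that every later analysis step consumes, plus a
ground-truth JSON so downstream recovery can be judged.
"""

import json
from pathlib import Path

import numpy as np

import biomeshift as bs
from biomeshift import io as bio

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
RASTER_OUT = ROOT / "scratch" / "synthetic"  # rasters are bulky; keep them out of results
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RASTER_OUT.mkdir(parents=True, exist_ok=True)
    biome = bs.SyntheticBiomeConfig(seed=SEED)
    grid = biome.grid
    axis = bs.generate_axis_field(biome)
    tree = bs.generate_tree_cover(biome, axis)
    dist = bs.generate_disturbances(bs.SyntheticDisturbanceConfig(seed=SEED + 1), grid)
    pcube, tcube, climate_truth = bs.generate_climate_cube(
        bs.SyntheticClimateConfig(seed=SEED + 2), grid
    )

    bio.write_raster(RASTER_OUT / "tree_cover.asc", tree, grid)
    bio.write_raster(RASTER_OUT / "annual_rainfall.asc", axis, grid)
    bio.write_raster(RASTER_OUT / "drought_counts.asc", dist.drought_counts.astype(float), grid)
    bio.write_raster(RASTER_OUT / "protected.asc", dist.protected.astype(float), grid)
    bio.write_raster(RASTER_OUT / "deforested.asc", dist.deforested.astype(float), grid)
    bio.write_roads_geojson(RASTER_OUT / "roads.geojson", dist.roads)
    truth = {"biome": biome.ground_truth(), "climate": climate_truth}
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2))

    band = (axis > biome.true_lower_threshold) & (axis < biome.true_upper_threshold)
    print(f"grid: {grid.rows}x{grid.cols} = {grid.n_pixels} pixels")
    print(f"tree cover mean {tree.mean():.1f}%, range {tree.min():.1f}-{tree.max():.1f}%")
    print(f"bistable rainfall band holds {band.mean():.1%} of pixels")
    print(f"protected {dist.protected.mean():.1%}, deforested {dist.deforested.mean():.1%}, "
          f"near-road {dist.road_near.mean():.1%}")
    print(f"mean drought count {dist.drought_counts.mean():.2f} events")
    print(f"rasters written to {RASTER_OUT}; ground truth to {OUT / 'ground_truth.json'}")


if __name__ == "__main__":
    main()
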