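{
  "type": "FeatureCollection",
  "note": "Synthetic simplified digitization of a Whittaker-style biome diagram. Coordinates are (mean annual temperature degC, total annual precipitation cm). Boundaries are idealized rectangles, not traced from any published figure; intended for testing and as a template users replace with their own digitization.",
  "features": [
    {"type": "Feature", "properties": {"name": "tundra"}, "geometry": {"type": "Polygon", "coordinates": [[[-15, 0], [-5, 0], [-5, 25], [-15, 25], [-15, 0]]]}},
    {"type": "Feature", "properties": {"name": "boreal_forest"}, "geometry": {"type": "Polygon", "coordinates": [[[-5, 0], [3, 0], [3, 100], [-5, 100], [-5, 0]]]}},
    {"type": "Feature", "properties": {"name": "temperate_grassland_desert"}, "geometry": {"type": "Polygon", "coordinates": [[[3, 0], [22, 0], [22, 25], [3, 25], [3, 0]]]}},
    {"type": "Feature", "properties": {"name": "woodland_shrubland"}, "geometry": {"type": "Polygon", "coordinates": [[[3, 25], [22, 25], [22, 60], [3, 60], [3, 25]]]}},
    {"type": "Feature", "properties": {"name": "temperate_seasonal_forest"}, "geometry": {"type": "Polygon", "coordinates": [[[3, 60], [22, 60], [22, 150], [3, 150], [3, 60]]]}},
    {"type": "Feature", "properties": {"name": "temperate_rainforest"}, "geometry": {"type": "Polygon", "coordinates": [[[3, 150], [22, 150], [22, 300], [3, 300], [3, 150]]]}},
    {"type": "Feature", "properties": {"name": "subtropical_desert"}, "geometry": {"type": "Polygon", "coordinates": [[[22, 0], [30, 0], [30, 50], [22, 50], [22, 0]]]}},
    {"type": "Feature", "properties": {"name": "tropical_seasonal_forest_savanna"}, "geometry": {"type": "Polygon", "coordinates": [[[22, 50], [30, 50], [30, 150], [22, 150], [22, 50]]]}},
    {"type": "Feature", "properties": {"name": "tropical_rainforest"}, "geometry": {"type": "Polygon", "coordinates": [[[22, 150], [30, 150], [30, 450], [22, 450], [22, 150]]]}}
  ]
}
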