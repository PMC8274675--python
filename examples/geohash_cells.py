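"""Geohash cells: encoding, decoding and physical size.

A geohash maps a latitude/longitude box to a short base-32 string; each
extra character splits the box 32-fold, and a point's longer code always
starts with its shorter one. The dashboard uses 6-digit cells (~1.22 km x
610 m on the equator) for coarse maps and 7-digit cells (~153 m squares)
for the school-proximity and municipality analyses; width shrinks with
cos(latitude) away from the equator.
"""

from geobehave import GeoPoint, cell_dimensions, decode_geohash, encode_geohash

for precision in (6, 7):
    for lat, lon, where in ((0.0001, 22.95, "equator"), (40.64, 22.95, "lat 40.6")):
        code = encode_geohash(GeoPoint(lat, lon), precision)
        w, h = cell_dimensions(code)
        print(f"precision {precision} @ {where:>8}: code {code!r:>11}  "
              f"width {w:7.1f} m  height {h:6.1f} m")

cell = decode_geohash("swbb5b5")
print(f"\ndecode('swbb5b5'): lat [{cell.south:.5f}, {cell.north:.5f}], "
      f"lon [{cell.west:.5f}, {cell.east:.5f}], centre ({cell.center.lat:.5f}, {cell.center.lon:.5f})")
print("nesting: the 7-digit code starts with the 6-digit code of the same point")
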