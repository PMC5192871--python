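"""From a field mosaic to a noded boundary-line network.

Dissolves a 2x2 block of fields so each shared boundary appears once,
shows Douglas-Peucker generalization, and splits crossing lines at their
intersections so every segment can be attributed individually.
"""

from shapely.geometry import LineString, Polygon

from hedgelines import generalize, polygons_to_network, split_segments
from hedgelines.network import LinearNetwork, assign_ids

fields = [Polygon([(i, j), (i + 1, j), (i + 1, j + 1), (i, j + 1)])
          for i in range(2) for j in range(2)]
net = polygons_to_network(fields)
print(f"2x2 field block -> {len(net)} boundary segments, "
      f"total length {net.total_length():.0f} (each shared edge once)")

wiggly = LinearNetwork(assign_ids([
    LineString([(0, 0), (1, 0.05), (2, -0.05), (3, 0)])]))
smooth = generalize(wiggly, tolerance=0.1)
print(f"generalization: {len(wiggly.segments[0].coords)} vertices -> "
      f"{len(smooth.segments[0].coords)}, "
      f"length {wiggly.total_length():.3f} -> {smooth.total_length():.3f}")

crossing = LinearNetwork(assign_ids([
    LineString([(0, 0), (2, 2)]), LineString([(0, 2), (2, 0)])]))
noded = split_segments(crossing)
print(f"two crossing lines -> {len(noded)} segments meeting at the junction")
print()
print("A noded network (segments meeting only at endpoints) is the unit of")
print("attribution: every field boundary gets its own height statistics.")
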