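"""Forward registration: pick feature points on a mesh, emit a tracking model.

Generates an ellipsoid surface (the shape family of a molded tracked prop),
snaps four pick points onto it, and writes the VSK-style XML that makes the
physical object trackable. The file's markers are root-relative, the root is
a free 6-DOF joint, and the marker radius defaults to 0.5.
"""

from mrsim import TrackingModel, place_virtual_markers, validate_model, write_vsk
from mrsim.synthetic import gen_ellipsoid_mesh

mesh = gen_ellipsoid_mesh(60.0, 40.0, 25.0, subdivisions=3)  # semi-axes in mm

picks = [
    [60.0, 0.0, 0.0],     # +x apex
    [0.0, 40.0, 0.0],     # +y apex
    [0.0, 0.0, 25.0],     # +z apex
    [45.6, 20.8, 9.7],    # off-axis point (snapped to the surface)
]
markers = place_virtual_markers(mesh, picks, radius=0.5, min_separation=5.0)
model = TrackingModel(markers, source_mesh_name="ellipsoid")

violations = validate_model(model)
print("validation:", "trackable" if not violations else violations)
print(write_vsk(model, "ellipsoid.vsk"))
print("wrote ellipsoid.vsk")
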