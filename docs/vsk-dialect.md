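# Tracking-model XML dialect

`mrsim` writes and reads a small, fully documented dialect of the VSK-style
subject file that marker-based optical trackers import. The dialect keeps the
four elements a real subject file carries and adds explicit version/units
attributes so files are self-describing and byte-reproducible.

## Schema

```
KinematicModel            root element
  @version                dialect version, currently "1.0"
  @units                  always "mm"
  @source_mesh            optional name of the mesh the markers were picked on
  Parameters              flat list of named scalar parameters
    Parameter @name @value    one per marker coordinate, named <marker>_<axis>
  Segment                 the single rigid root segment
    @name                 default "root"
    @joint                joint kind; "Free" for a rigid tracking model
    @dof                  degrees of freedom; 6 for a free root
  MarkerSet
    Marker @name @segment @position   position = "x y z", root-relative, mm
  Radius @value           marker sphere radius; default 0.5
```

## Rules

- All numbers are serialized with a fixed `%.6f` format; files are UTF-8 with
  LF line endings, so `write -> read -> write` is byte-identical.
- Marker coordinates are always **root-relative**: the root segment sits at
  the model origin, so the file is invariant to where the mesh happens to be
  placed in the world.
- A trackable model needs at least 3 markers in a non-collinear
  configuration; `write_vsk` refuses fewer than 3, `validate_model` reports
  all violations.
- Reads are **lenient**: unknown elements are preserved verbatim in
  `TrackingModel.extras` (never re-written — strict write). A missing
  `Radius` falls back to the documented default 0.5 with a logged warning.
- Multi-segment articulated chains are not modelled; a fixed (zero-DOF)
  inter-segment joint is the only composition supported by consuming code,
  and articulated joints are rejected as unsupported.

## Example

```xml
<?xml version="1.0" encoding="UTF-8"?>
<KinematicModel version="1.0" units="mm">
  <Parameters>
    <Parameter name="M1_x" value="0.000000"/>
    <Parameter name="M1_y" value="0.000000"/>
    <Parameter name="M1_z" value="0.000000"/>
    ...
  </Parameters>
  <Segment name="root" joint="Free" dof="6"/>
  <MarkerSet>
    <Marker name="M1" segment="root" position="0.000000 0.000000 0.000000"/>
    ...
  </MarkerSet>
  <Radius value="0.500000"/>
</KinematicModel>
```
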